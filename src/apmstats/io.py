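"""Readers and writers for the tabular formats used throughout.

Abundance tables are delimited text (tab or comma, auto-detected from the
header line) with proteins as rows and channels as columns.  Layouts are JSON.
Enrichment tables are TSV mirroring the published result-table columns.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ApmsError, LayoutError
from .model import (
    AbundanceMatrix,
    Channel,
    EnrichmentTable,
    InteractorRecord,
    PlexLayout,
    Role,
)

#: Cell contents treated as a missing measurement.
MISSING_SENTINELS = ["", "NA"]


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_layout(path: str | Path) -> PlexLayout:
    """Read a plex layout from a JSON config.

    Expected shape: ``{"channels": [{"id": ..., "role": ..., "replicate": ...}]}``.
    ``replicate`` may be omitted for UNUSED channels (defaults to 1).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "channels" not in doc:
        raise LayoutError(f"{path}: layout JSON must contain a 'channels' list")
    channels = []
    for entry in doc["channels"]:
        try:
            role = Role(entry["role"])
        except (ValueError, KeyError):
            raise LayoutError(
                f"{path}: unknown or missing role {entry.get('role')!r} "
                f"for channel {entry.get('id')!r}"
            ) from None
        channels.append(
            Channel(id=str(entry["id"]), role=role, replicate=int(entry.get("replicate", 1)))
        )
    return PlexLayout(channels)


def write_layout(layout: PlexLayout, path: str | Path) -> None:
    doc = {
        "channels": [
            {"id": c.id, "role": c.role.value, "replicate": c.replicate}
            for c in layout.channels
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_abundance_table(
    path: str | Path,
    layout: PlexLayout,
    bait_id: str,
    id_column: str = "Accession",
    gene_column: str | None = "Gene",
    exclude_ids: Iterable[str] = (),
) -> AbundanceMatrix:
    """Read a protein-by-channel abundance table.

    The protein-id column is the first column whose header equals
    ``id_column``; one column per active layout channel is required.  Empty
    cells and the sentinel ``NA`` load as missing; negative values are
    rejected.  Accessions in ``exclude_ids`` (e.g. a contaminant list) are
    dropped at load.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, na_values=MISSING_SENTINELS, keep_default_na=False, dtype=str
    )
    if id_column not in df.columns:
        raise LayoutError(f"{path}: no protein-id column {id_column!r} in header")
    df = df.set_index(id_column)
    missing_cols = [c for c in layout.active_channels if c not in df.columns]
    if missing_cols:
        raise LayoutError(f"{path}: abundance table lacks layout channel(s): {missing_cols}")

    gene_symbols: dict[str, str] = {}
    if gene_column and gene_column in df.columns:
        gene_symbols = {
            acc: g for acc, g in df[gene_column].items() if isinstance(g, str) and g
        }

    data = df[layout.active_channels].apply(pd.to_numeric, errors="raise")
    excluded = set(exclude_ids)
    if excluded:
        data = data.loc[[p for p in data.index if p not in excluded]]
    neg = data.lt(0)
    if neg.to_numpy().any():
        row = neg.any(axis=1).idxmax()
        col = neg.loc[row].idxmax()
        raise LayoutError(
            f"{path}: negative abundance at protein {row!r}, channel {col!r}"
        )
    return AbundanceMatrix(data=data, bait_id=bait_id, gene_symbols=gene_symbols)


def read_contaminant_list(path: str | Path) -> set[str]:
    """Plain-text contaminant accessions, one per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_abundance_table(
    matrix: AbundanceMatrix, path: str | Path, id_column: str = "Accession"
) -> None:
    df = matrix.data.copy()
    df.index.name = id_column
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


_ENRICHMENT_COLUMNS = [
    "protein",
    "gene",
    "fold_enrichment",
    "p_value",
    "q_value",
    "high_confidence",
]


def write_enrichment_table(table: EnrichmentTable, path: str | Path) -> None:
    """Write an enrichment table as TSV, preserving row order.

    Numeric columns use 6 significant digits.
    """
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(_ENRICHMENT_COLUMNS) + "\n")
            for r in table:
                fh.write(
                    "\t".join(
                        [
                            r.protein_id,
                            r.gene_symbol,
                            _fmt(r.fold_enrichment),
                            _fmt(r.p_value),
                            _fmt(r.q_value),
                            str(r.high_confidence),
                        ]
                    )
                    + "\n"
                )
    except OSError as exc:
        raise ApmsError(f"cannot write enrichment table to {path}: {exc}") from exc


def _fmt(x: float) -> str:
    return "NA" if math.isnan(x) else format(x, ".6g")


def read_enrichment_table(path: str | Path) -> EnrichmentTable:
    df = pd.read_csv(
        path, sep="\t", na_values=MISSING_SENTINELS, keep_default_na=False
    )
    records = [
        InteractorRecord(
            protein_id=str(row["protein"]),
            gene_symbol="" if pd.isna(row["gene"]) else str(row["gene"]),
            fold_enrichment=float(row["fold_enrichment"]),
            p_value=float(row["p_value"]),
            q_value=float(row["q_value"]),
            high_confidence=str(row["high_confidence"]) == "True",
        )
        for _, row in df.iterrows()
    ]
    return EnrichmentTable(records)


def read_pvalue_file(path: str | Path) -> tuple[list[str], list[float]]:
    """Read p-values, one per line, with an optional leading label column."""
    labels: list[str] = []
    values: list[float] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 1:
            labels.append(f"h{i + 1}")
            values.append(float(parts[0]))
        else:
            labels.append(parts[0])
            values.append(float(parts[-1]))
    return labels, values
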