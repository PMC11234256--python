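"""End-to-end discovery pipeline and the heat-map panel annotation helper.

``run_pipeline`` chains the stages in the published order: high-confidence
filtering against the negative control (on raw abundances), bait
normalization, fold enrichment, per-protein homoscedastic t-tests, and the
two-stage BKY FDR procedure, returning a result table sorted by fold
enrichment.  Every run also produces a machine-readable log of parameters
and stage-by-stage counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .errors import ApmsError
from .filtering import FilterMode, FilterRule, high_confidence_filter
from .enrichment import bait_normalize, condition_t_tests, fold_enrichment
from .fdr import bky_two_stage
from .model import AbundanceMatrix, EnrichmentTable, InteractorRecord, PlexLayout


@dataclass
class PipelineConfig:
    """Parameters for one discovery run; everything echoes into the run log."""

    filter_rule: FilterRule = field(default_factory=FilterRule)
    log_transform: bool = False
    q_target: float = 0.10
    family: str = "filtered"  # "filtered" (default) or "all" detected proteins
    grid_step: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.q_target < 1.0):
            raise ApmsError("q_target must lie in (0, 1)")
        if self.family not in ("filtered", "all"):
            raise ApmsError("family must be 'filtered' or 'all'")


def run_pipeline(
    matrix: AbundanceMatrix,
    layout: PlexLayout,
    config: PipelineConfig | None = None,
) -> tuple[EnrichmentTable, dict]:
    """Run the full comparative-interactome analysis.

    Returns the enrichment table (fold enrichment descending, ties by p then
    protein id) and a JSON-serializable run log.  The bait itself is excluded
    from the table and the FDR family: its normalized abundance is
    identically 1, so it carries no comparative information.  Proteins whose
    p-value is undefined (missing replicates) are excluded from the FDR
    family and reported with NaN p and q.
    """
    config = config or PipelineConfig()
    layout.require_runnable()
    matrix.check_layout(layout)

    fres = high_confidence_filter(matrix, layout, config.filter_rule)
    norm = bait_normalize(matrix, layout)
    fe = fold_enrichment(norm, layout)
    tests = condition_t_tests(norm, layout, log_transform=config.log_transform)

    if config.family == "filtered":
        members = sorted(fres.retained - {matrix.bait_id})
    else:
        members = sorted(set(matrix.proteins) - {matrix.bait_id})
    testable = [m for m in members if np.isfinite(tests.loc[m, "p"])]

    q_map: dict[str, float] = {}
    rejected_map: dict[str, bool] = {}
    if testable:
        fdr = bky_two_stage(
            tests.loc[testable, "p"].to_numpy(),
            config.q_target,
            grid_step=config.grid_step,
        )
        q_map = dict(zip(testable, fdr.q_values))
        rejected_map = dict(zip(testable, fdr.rejected))

    records = [
        InteractorRecord(
            protein_id=pid,
            gene_symbol=matrix.gene_symbol(pid),
            fold_enrichment=float(fe[pid]),
            p_value=float(tests.loc[pid, "p"]),
            q_value=float(q_map.get(pid, np.nan)),
            high_confidence=pid in fres.retained,
        )
        for pid in members
    ]
    table = EnrichmentTable(records)

    run_log = {
        "version": __version__,
        "parameters": {
            "filter_rule": {
                "ratio_threshold": config.filter_rule.ratio_threshold,
                "min_passing_channels": config.filter_rule.min_passing_channels,
                "total_experimental_channels": config.filter_rule.total_experimental_channels,
                "strict_inequality": config.filter_rule.strict_inequality,
                "mode": config.filter_rule.mode.value,
            },
            "log_transform": config.log_transform,
            "q_target": config.q_target,
            "family": config.family,
            "bait_id": matrix.bait_id,
        },
        "counts": {
            "proteins_in": len(matrix.proteins),
            "high_confidence": len(fres.retained),
            "family_size": len(testable),
            "rejected": int(sum(rejected_map.values())),
        },
    }
    return table, run_log


def write_run_log(run_log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(run_log, fh, indent=1)
        fh.write("\n")


# --- panel annotation (expression heat-map style) --------------------------

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_annotation(adjusted_p: float) -> str:
    """Significance stars at strict thresholds 0.05 / 0.01 / 0.001."""
    if not (0.0 <= adjusted_p <= 1.0):
        raise ApmsError(f"adjusted p must lie in [0, 1], got {adjusted_p}")
    for thresh, stars in STAR_THRESHOLDS:
        if adjusted_p < thresh:
            return stars
    return ""


@dataclass
class PanelEntry:
    """One gene in one annotated panel of a differential-expression figure."""

    gene: str
    gene_set: str
    log2_fold_change: float
    adjusted_p: float
    stars: str
    found: bool


def annotate_panel(
    de_table: list[tuple[str, float, float]],
    gene_sets: dict[str, list[str]],
) -> list[PanelEntry]:
    """Attach star annotations to gene-set panels of a DE table.

    ``de_table`` rows are (gene, log2 fold change, adjusted p).  Genes listed
    in a set but absent from the table are returned with ``found=False`` and
    NaN statistics.
    """
    lookup: dict[str, tuple[float, float]] = {}
    for row in de_table:
        try:
            gene, lfc, padj = row
        except (TypeError, ValueError):
            raise ApmsError(f"malformed DE-table row: {row!r}") from None
        lookup[str(gene)] = (float(lfc), float(padj))

    entries = []
    for set_name, genes in gene_sets.items():
        for gene in genes:
            if gene in lookup:
                lfc, padj = lookup[gene]
                entries.append(
                    PanelEntry(gene, set_name, lfc, padj, star_annotation(padj), True)
                )
            else:
                entries.append(
                    PanelEntry(gene, set_name, float("nan"), float("nan"), "", False)
                )
    return entries
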