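"""Core data model for a multiplexed (TMT-style) AP-MS comparison.

The experiment quantifies proteins co-purifying with an affinity-tagged bait
across one multiplex run whose channels fall into three roles: wild-type
bait, variant bait, and a no-transfection negative control (cells expressing
no bait at all).  A :class:`PlexLayout` declares which channel plays which
role; an :class:`AbundanceMatrix` holds the raw reporter-ion protein
abundances; downstream stages produce a bait-normalized matrix and finally
an :class:`EnrichmentTable` of per-protein fold enrichments with p- and
q-values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BaitNotFoundError, LayoutError


class Role(str, enum.Enum):
    """Role of a multiplex channel."""

    WT_BAIT = "WT_BAIT"
    VARIANT_BAIT = "VARIANT_BAIT"
    NEGATIVE_CONTROL = "NEGATIVE_CONTROL"
    UNUSED = "UNUSED"


@dataclass(frozen=True)
class Channel:
    """One multiplex channel: identifier, role and biological replicate index."""

    id: str
    role: Role
    replicate: int

    def __post_init__(self) -> None:
        if not self.id:
            raise LayoutError("channel id must be non-empty")
        if self.replicate < 1:
            raise LayoutError(
                f"channel {self.id!r}: replicate index must be >= 1, got {self.replicate}"
            )


@dataclass(frozen=True)
class PlexLayout:
    """Ordered channel assignment for one multiplex run.

    Channels with role ``UNUSED`` are carried for bookkeeping but dropped by
    every downstream operation.  ``(role, replicate)`` pairs must be unique
    among active channels so each biological replicate maps to exactly one
    channel.
    """

    channels: tuple[Channel, ...]

    def __init__(self, channels: Iterable[Channel]):
        object.__setattr__(self, "channels", tuple(channels))
        if not self.channels:
            raise LayoutError("layout must declare at least one channel")
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LayoutError(f"duplicate channel ids: {dupes}")
        seen: set[tuple[Role, int]] = set()
        for c in self.channels:
            if c.role is Role.UNUSED:
                continue
            key = (c.role, c.replicate)
            if key in seen:
                raise LayoutError(
                    f"duplicate (role, replicate) assignment: ({c.role.value}, {c.replicate})"
                )
            seen.add(key)

    def channels_for(self, role: Role) -> list[str]:
        return [c.id for c in self.channels if c.role is role]

    @property
    def wt_channels(self) -> list[str]:
        return self.channels_for(Role.WT_BAIT)

    @property
    def variant_channels(self) -> list[str]:
        return self.channels_for(Role.VARIANT_BAIT)

    @property
    def control_channels(self) -> list[str]:
        return self.channels_for(Role.NEGATIVE_CONTROL)

    @property
    def experimental_channels(self) -> list[str]:
        """WT then variant channels — the channels that contain bait."""
        return self.wt_channels + self.variant_channels

    @property
    def active_channels(self) -> list[str]:
        return [c.id for c in self.channels if c.role is not Role.UNUSED]

    def require_runnable(self) -> None:
        """Check the minimum design for the comparative analysis (>=2 per role)."""
        for role in (Role.WT_BAIT, Role.VARIANT_BAIT, Role.NEGATIVE_CONTROL):
            n = len(self.channels_for(role))
            if n < 2:
                raise LayoutError(
                    f"runnable experiment needs >= 2 {role.value} channels, found {n}"
                )


@dataclass
class AbundanceMatrix:
    """Raw protein-by-channel abundances with a designated bait protein.

    ``data`` is a proteins-by-channels DataFrame of non-negative reals; missing
    measurements are NaN.  ``gene_symbols`` optionally maps protein accession
    to a gene symbol for reporting.
    """

    data: pd.DataFrame
    bait_id: str
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if (self.data.to_numpy() < 0).any():
            bad = np.argwhere(self.data.to_numpy() < 0)[0]
            raise LayoutError(
                f"negative abundance at protein {self.data.index[bad[0]]!r}, "
                f"channel {self.data.columns[bad[1]]!r}"
            )
        if self.bait_id not in self.data.index:
            raise BaitNotFoundError(
                f"bait protein {self.bait_id!r} not present in abundance table"
            )

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    def gene_symbol(self, protein_id: str) -> str:
        return self.gene_symbols.get(protein_id, "")

    def check_layout(self, layout: PlexLayout) -> None:
        missing = [c for c in layout.active_channels if c not in self.data.columns]
        if missing:
            raise LayoutError(f"abundance table lacks layout channel(s): {missing}")


@dataclass
class NormalizedMatrix:
    """Bait-normalized abundances over experimental channels only.

    Each value is abundance(protein, channel) / abundance(bait, channel), so
    the bait row is identically 1 and per-channel pull-down efficiency cancels.
    """

    data: pd.DataFrame
    bait_id: str


@dataclass
class TTestResult:
    """Two-sample t-test outcome (either pooled-variance or Welch)."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n1: int
    n2: int


@dataclass
class InteractorRecord:
    """One row of the comparative-interactome result table."""

    protein_id: str
    gene_symbol: str
    fold_enrichment: float
    p_value: float
    q_value: float
    high_confidence: bool

    def __post_init__(self) -> None:
        for name in ("p_value", "q_value"):
            v = getattr(self, name)
            if not (math.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def sort_records(records: Sequence[InteractorRecord]) -> list[InteractorRecord]:
    """Canonical table order: fold enrichment descending, ties by p then id.

    Undefined (NaN) fold enrichments sort last.
    """

    def key(r: InteractorRecord):
        fe = r.fold_enrichment
        p = r.p_value
        return (
            math.isnan(fe),
            -fe if not math.isnan(fe) else 0.0,
            p if not math.isnan(p) else 2.0,
            r.protein_id,
        )

    return sorted(records, key=key)


@dataclass
class EnrichmentTable:
    """Ordered list of interactor records, sorted in canonical table order."""

    records: list[InteractorRecord]

    def __post_init__(self) -> None:
        self.records = sort_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [r.protein_id for r in self.records],
                "gene": [r.gene_symbol for r in self.records],
                "fold_enrichment": [r.fold_enrichment for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "q_value": [r.q_value for r in self.records],
                "high_confidence": [r.high_confidence for r in self.records],
            }
        )
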