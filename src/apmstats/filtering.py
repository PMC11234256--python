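"""High-confidence interactor filtering against the no-transfection control.

Nonspecific binders stick to the affinity resin whether or not bait is
present, so their signal in the negative-control channels approximates their
signal everywhere.  A protein qualifies as a high-confidence interactor when
its raw abundance exceeds a fold threshold over the averaged negative-control
baseline in enough experimental channels.  Filtering happens on RAW
abundances, before bait normalization: the control channels contain no bait,
so a bait-normalized control value would be meaningless.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import AbundanceMatrix, PlexLayout


class FilterMode(str, enum.Enum):
    #: pass in at least `min_passing_channels` of the experimental channels
    K_OF_N = "K_OF_N"
    #: pass in every experimental channel
    ALL_REPLICATES = "ALL_REPLICATES"


@dataclass(frozen=True)
class FilterRule:
    """Threshold rule for calling high-confidence interactors.

    Defaults encode the published rule: a strictly-more-than-twofold increase
    over the averaged negative control in at least 4 of the 6 experimental
    channels.  ``ALL_REPLICATES`` instead demands the criterion in every
    experimental channel.
    """

    ratio_threshold: float = 2.0
    min_passing_channels: int = 4
    total_experimental_channels: int = 6
    strict_inequality: bool = True
    mode: FilterMode = FilterMode.K_OF_N

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ConfigurationError("ratio_threshold must be > 0")
        if not (1 <= self.min_passing_channels <= self.total_experimental_channels):
            raise ConfigurationError(
                "min_passing_channels must lie in [1, total_experimental_channels]"
            )


@dataclass
class FilterResult:
    """Retained protein ids plus per-protein channel-pass counts.

    The bait is always present in ``pass_counts`` and, if it meets the rule,
    in ``retained``; ``bait_id`` flags it so downstream reporting can treat
    it specially.
    """

    retained: set[str]
    pass_counts: pd.Series
    bait_id: str
    rule: FilterRule = field(repr=False, default=FilterRule())


def negative_control_baseline(matrix: AbundanceMatrix, layout: PlexLayout) -> pd.Series:
    """Per-protein mean abundance over negative-control channels.

    Missing control measurements count as zero: an undetected protein in a
    no-transfection channel contributes no background signal.
    """
    controls = layout.control_channels
    if not controls:
        raise ConfigurationError("layout declares no NEGATIVE_CONTROL channels")
    matrix.check_layout(layout)
    return matrix.data[controls].fillna(0.0).mean(axis=1)


def high_confidence_filter(
    matrix: AbundanceMatrix, layout: PlexLayout, rule: FilterRule | None = None
) -> FilterResult:
    """Apply the fold-over-control rule and return retained proteins.

    A channel passes when abundance exceeds ``ratio_threshold x baseline``
    (strictly, unless ``strict_inequality`` is off).  A zero baseline passes
    whenever the experimental abundance is positive — absence from the
    control is the strongest possible enrichment evidence.  A missing
    experimental abundance fails that channel.
    """
    rule = rule or FilterRule()
    baseline = negative_control_baseline(matrix, layout)
    experimental = layout.experimental_channels
    if rule.total_experimental_channels != len(experimental):
        raise ConfigurationError(
            f"rule expects {rule.total_experimental_channels} experimental channels, "
            f"layout has {len(experimental)}"
        )

    values = matrix.data[experimental].to_numpy()
    thresh = rule.ratio_threshold * baseline.to_numpy()[:, None]
    if rule.strict_inequality:
        passed = values > thresh
    else:
        passed = values >= thresh
    # zero baseline: any positive signal passes (ratio unbounded)
    zero_base = baseline.to_numpy()[:, None] == 0.0
    passed = np.where(zero_base, values > 0.0, passed)
    passed &= ~np.isnan(values)  # missing experimental value fails the channel

    counts = pd.Series(passed.sum(axis=1), index=matrix.data.index, name="pass_count")
    need = len(experimental) if rule.mode is FilterMode.ALL_REPLICATES else rule.min_passing_channels
    retained = set(counts.index[counts >= need])
    return FilterResult(
        retained=retained, pass_counts=counts, bait_id=matrix.bait_id, rule=rule
    )
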