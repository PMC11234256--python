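"""Bait normalization, fold enrichment and the two-sample t-tests.

Dividing each prey's abundance in a channel by the bait's abundance in that
same channel removes channel-to-channel differences in transfection and
pull-down efficiency; the fold enrichment is then the ratio of mean
normalized abundance in the variant condition over the wild-type condition.
With equal replicate counts this equals the ratio of sums.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicatesError, NormalizationError
from .model import AbundanceMatrix, NormalizedMatrix, PlexLayout, TTestResult

log = logging.getLogger(__name__)


def bait_normalize(matrix: AbundanceMatrix, layout: PlexLayout) -> NormalizedMatrix:
    """Divide every protein's abundance by the bait's, per experimental channel.

    Raises :class:`NormalizationError` naming the channel if the bait is zero
    or missing there.  Negative-control channels are dropped (they contain no
    bait).  Missing prey values propagate as missing.
    """
    matrix.check_layout(layout)
    experimental = layout.experimental_channels
    bait = matrix.data.loc[matrix.bait_id, experimental]
    bad = [c for c in experimental if not (bait[c] > 0)]
    if bad:
        raise NormalizationError(
            f"bait {matrix.bait_id!r} has zero or missing abundance in "
            f"experimental channel(s): {bad}"
        )
    data = matrix.data[experimental].div(bait, axis=1)
    return NormalizedMatrix(data=data, bait_id=matrix.bait_id)


def fold_enrichment(norm: NormalizedMatrix, layout: PlexLayout) -> pd.Series:
    """Per-protein fold enrichment: mean(variant) / mean(wild-type).

    Missing values are excluded from each mean.  The result is NaN (undefined,
    logged) when a condition has no non-missing values or the wild-type mean
    is zero; the protein stays in the output either way.
    """
    var_mean = norm.data[layout.variant_channels].mean(axis=1, skipna=True)
    wt_mean = norm.data[layout.wt_channels].mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = var_mean / wt_mean
    fe = fe.where((wt_mean > 0) & var_mean.notna(), np.nan)
    undefined = fe.index[fe.isna()]
    for pid in undefined:
        log.warning("fold enrichment undefined for protein %r", pid)
    fe.name = "fold_enrichment"
    return fe


def _zero_variance_p(mean_a: float, mean_b: float) -> float:
    """Degenerate-variance policy: p=1 when means agree, p=0 otherwise."""
    if math.isclose(mean_a, mean_b, rel_tol=1e-12, abs_tol=1e-300):
        log.info("zero pooled variance with equal means: p set to 1.0")
        return 1.0
    log.info("zero pooled variance with unequal means: p set to 0.0")
    return 0.0


def _prepare(group_a, group_b, log_transform: bool):
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 values per group, got {a.size} and {b.size}"
        )
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise InsufficientReplicatesError(
                "log transform requires strictly positive values"
            )
        a, b = np.log2(a), np.log2(b)
    return a, b


def homoscedastic_t_test(
    group_a, group_b, log_transform: bool = False
) -> TTestResult:
    """Two-sided pooled-variance (equal-variance) two-sample t-test.

    With ``log_transform`` the test runs on log2 of the inputs, appropriate
    for multiplicative (log-normal) abundance noise.  Zero pooled variance
    yields p=1 for equal means and p=0 for unequal means.
    """
    a, b = _prepare(group_a, group_b, log_transform)
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if s2 == 0.0:
        p = _zero_variance_p(a.mean(), b.mean())
        t_stat = 0.0 if p == 1.0 else math.copysign(math.inf, a.mean() - b.mean())
        return TTestResult(t_stat, df, p, n1, n2)
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t_stat), float(df), float(p), n1, n2)


def welch_t_test(group_a, group_b, log_transform: bool = False) -> TTestResult:
    """Two-sided unequal-variance t-test with Welch–Satterthwaite df."""
    a, b = _prepare(group_a, group_b, log_transform)
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        p = _zero_variance_p(a.mean(), b.mean())
        t_stat = 0.0 if p == 1.0 else math.copysign(math.inf, a.mean() - b.mean())
        return TTestResult(t_stat, float(n1 + n2 - 2), p, n1, n2)
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = num / den
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t_stat), float(df), float(p), n1, n2)


def condition_t_tests(
    norm: NormalizedMatrix, layout: PlexLayout, log_transform: bool = False
) -> pd.DataFrame:
    """Vectorized per-protein homoscedastic t-test, variant vs wild-type.

    Returns a DataFrame with columns ``t`` and ``p`` indexed by protein.
    Proteins with any missing or (under log transform) non-positive value in
    either condition get NaN p — callers decide how to treat them.  The
    zero-variance policy matches :func:`homoscedastic_t_test`.
    """
    a = norm.data[layout.variant_channels].to_numpy(dtype=float)
    b = norm.data[layout.wt_channels].to_numpy(dtype=float)
    ok = ~np.isnan(a).any(axis=1) & ~np.isnan(b).any(axis=1)
    if log_transform:
        ok &= (np.nan_to_num(a, nan=-1.0) > 0).all(axis=1)
        ok &= (np.nan_to_num(b, nan=-1.0) > 0).all(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a, b = np.log2(a), np.log2(b)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per condition")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows trip scipy's precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    # zero pooled variance -> scipy NaN; apply the stated policy
    s2 = ((n1 - 1) * np.nanvar(a, axis=1, ddof=1) + (n2 - 1) * np.nanvar(b, axis=1, ddof=1))
    degenerate = ok & (s2 == 0.0)
    if degenerate.any():
        equal_means = np.isclose(np.nanmean(a, axis=1), np.nanmean(b, axis=1))
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
        t_stat = np.where(degenerate, np.where(equal_means, 0.0, np.inf), t_stat)
    p = np.where(ok, p, np.nan)
    t_stat = np.where(ok, t_stat, np.nan)
    return pd.DataFrame({"t": t_stat, "p": p}, index=norm.data.index)
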