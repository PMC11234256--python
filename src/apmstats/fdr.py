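"""Step-up false-discovery-rate procedures.

Implements the classic Benjamini–Hochberg (BH) step-up adjustment and the
adaptive two-stage step-up procedure of Benjamini, Krieger and Yekutieli
(BKY).  The two-stage procedure first runs BH at the deflated level
q' = q/(1+q) to estimate the number of true null hypotheses
(m0 = m - r1, where r1 is the stage-one rejection count), then reruns the
BH step-up at level q' with m0 in place of m, which recovers power when
many hypotheses are non-null.

q-values for the two-stage procedure are defined operationally: the smallest
desired-FDR level (on a fine grid) at which the procedure rejects the
hypothesis.  Because the rejection set grows monotonically with the level,
this search is exact and self-consistent with the rejection decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ApmsError

__all__ = [
    "FdrResult",
    "bh_adjust",
    "bky_two_stage",
    "q_values_by_search",
    "bky_scaled_qvalues",
]


def _validated(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ApmsError("p-values must be a non-empty 1-D sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ApmsError("all p-values must lie in [0, 1]")
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, returned in input order.

    Sort ascending, multiply p_(k) by m/k, enforce monotone non-increase
    from the largest rank down, cap at 1.
    """
    p = _validated(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    adj = p[order] * m / ranks
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _stepup_count(p_sorted: np.ndarray, thresholds: np.ndarray) -> int:
    """Largest k with p_(k) <= threshold_k (0 if none) — the step-up rule."""
    hits = np.nonzero(p_sorted <= thresholds)[0]
    return int(hits[-1]) + 1 if hits.size else 0


def _suffix_min(x: np.ndarray) -> np.ndarray:
    return np.minimum.accumulate(x[::-1])[::-1]


def bky_decisions(p_values, q_target: float) -> tuple[np.ndarray, int, int]:
    """Two-stage BKY rejection decisions at a single desired-FDR level.

    Returns ``(rejected, r1, m0_hat)`` with ``rejected`` in input order.
    Stage-one edge cases follow the original procedure: r1 = 0 accepts
    everything, r1 = m rejects everything.
    """
    p = _validated(p_values)
    if not (0.0 < q_target < 1.0):
        raise ApmsError(f"q_target must lie in (0, 1), got {q_target}")
    m = p.size
    q_prime = q_target / (1.0 + q_target)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)

    r1 = _stepup_count(ps, ranks * q_prime / m)
    if r1 == 0:
        n_rej = 0
    elif r1 == m:
        n_rej = m
    else:
        m0 = m - r1
        n_rej = _stepup_count(ps, ranks * q_prime / m0)
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:n_rej]] = True
    return rejected, r1, m - r1


def q_values_by_search(
    p_values, grid_step: float = 1e-4, extra_levels=()
) -> np.ndarray:
    """q-values: the smallest grid level at which BKY rejects each hypothesis.

    The grid is ``{grid_step, 2*grid_step, ...} u extra_levels`` restricted to
    (0, 1); hypotheses never rejected on the grid get q = 1.  The sweep is
    exact: stage-one rejection counts are piecewise constant in the level, so
    levels are grouped by r1 and each group is resolved in closed form —
    identical to scanning the grid level by level.
    """
    p = _validated(p_values)
    if grid_step <= 0:
        raise ApmsError("grid_step must be positive")
    m = p.size
    levels = np.arange(grid_step, 1.0, grid_step)
    extra = np.asarray(list(extra_levels), dtype=float)
    if extra.size:
        if ((extra <= 0) | (extra >= 1)).any():
            raise ApmsError("extra levels must lie in (0, 1)")
        levels = np.union1d(levels, extra)
    qp = levels / (1.0 + levels)

    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)

    # r1(level) via suffix minima of the stage-one step-up statistics
    g1 = _suffix_min(ps * m / ranks)
    r1_per_level = np.searchsorted(g1, qp, side="right")

    q_sorted = np.full(m, np.inf)
    for r1 in np.unique(r1_per_level):
        if r1 == 0:
            continue
        group = np.nonzero(r1_per_level == r1)[0]
        if r1 == m:
            q_sorted = np.minimum(q_sorted, levels[group[0]])
            continue
        m0 = m - r1
        # hypothesis at rank k is rejected at level l iff min_{j>=k} p_(j)*m0/j <= q'(l)
        g2 = _suffix_min(ps * m0 / ranks)
        pos = np.searchsorted(qp[group], g2, side="left")
        inside = pos < group.size
        cand = np.where(inside, levels[group[np.minimum(pos, group.size - 1)]], np.inf)
        q_sorted = np.minimum(q_sorted, cand)

    q_sorted = np.where(np.isinf(q_sorted), 1.0, q_sorted)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone in p rank
    out = np.empty(m)
    out[order] = q_sorted
    return out


def bky_scaled_qvalues(p_values, q_target: float = 0.10) -> np.ndarray:
    """Closed-form variant: BH-adjusted p-values scaled by m0_hat/m.

    Quicker than the grid search but a different (clearly labelled) estimand;
    the two can disagree in the second decimal.  m0_hat comes from the
    stage-one BH pass at q' = q_target/(1+q_target).
    """
    p = _validated(p_values)
    _, _, m0 = bky_decisions(p, q_target)
    return np.minimum(bh_adjust(p) * m0 / p.size, 1.0)


@dataclass
class FdrResult:
    """Full outcome of the two-stage procedure at one desired-FDR level."""

    p_values: np.ndarray
    q_target: float
    m: int
    q_prime: float
    r1: int
    m0_hat: int
    rejected: np.ndarray
    q_values: np.ndarray | None = field(default=None)

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def bky_two_stage(
    p_values, q_target: float, grid_step: float = 1e-4, compute_q: bool = True
) -> FdrResult:
    """Run the two-stage BKY procedure and (optionally) its q-values.

    The q-value grid always contains ``q_target`` itself, which guarantees
    ``rejected[h]  <=>  q_values[h] <= q_target``.
    """
    p = _validated(p_values)
    rejected, r1, m0 = bky_decisions(p, q_target)
    q_values = None
    if compute_q:
        q_values = q_values_by_search(p, grid_step=grid_step, extra_levels=[q_target])
    return FdrResult(
        p_values=p,
        q_target=q_target,
        m=p.size,
        q_prime=q_target / (1.0 + q_target),
        r1=r1,
        m0_hat=m0,
        rejected=rejected,
        q_values=q_values,
    )
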