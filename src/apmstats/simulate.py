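"""Synthetic data with the statistical structure the analysis assumes.

The AP-MS generator emulates a 9-channel multiplex (3 wild-type bait, 3
variant bait, 3 no-transfection control) with four protein classes:

* ``BAIT`` — the tagged protein itself, at the per-channel bait level;
* ``BACKGROUND_BINDER`` — bait-dependent preys with true fold 1 (the nulls);
* ``NONSPECIFIC`` — resin-binding contaminants with equal expected signal in
  control and experimental channels, which the confidence filter should drop;
* ``DIFFERENTIAL`` — bait-dependent preys enriched ``differential_fold``-fold
  in the variant condition (the planted positives).

Per-protein binding strength is log-normal; all noise is multiplicative
log-normal with a chosen coefficient of variation, so a t-test on log2
abundances is exactly valid.  Bait-dependent signal leaks into the controls
at a fixed relative carryover.  Everything is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ApmsError
from .filtering import FilterRule, high_confidence_filter
from .enrichment import bait_normalize, condition_t_tests, fold_enrichment
from .fdr import bky_decisions
from .model import AbundanceMatrix, Channel, PlexLayout, Role

CLASS_BAIT = "BAIT"
CLASS_BACKGROUND = "BACKGROUND_BINDER"
CLASS_NONSPECIFIC = "NONSPECIFIC"
CLASS_DIFFERENTIAL = "DIFFERENTIAL"


@dataclass(frozen=True)
class ApmsSimConfig:
    """Generative parameters for one synthetic AP-MS multiplex.

    Defaults describe a realistic pull-down: a couple hundred bait-dependent
    background binders, a hundred resin contaminants, twenty interactors
    enriched twofold in the variant, 10% multiplicative noise, bait level
    around 1,000 with ±10% channel-to-channel jitter, and 30% relative
    carryover of bait-dependent signal into the no-transfection controls.
    """

    n_background_binders: int = 200
    n_nonspecific: int = 100
    n_differential: int = 20
    differential_fold: float = 2.0
    noise_cv: float = 0.10
    bait_level: float = 1000.0
    bait_level_jitter: float = 0.10
    control_carryover: float = 0.3
    binding_log_mean: float = math.log(50.0)
    binding_log_sd: float = 1.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background_binders, self.n_nonspecific, self.n_differential) < 0:
            raise ApmsError("protein counts must be >= 0")
        if self.differential_fold <= 0 or self.noise_cv <= 0:
            raise ApmsError("differential_fold and noise_cv must be > 0")
        if not (0.0 < self.control_carryover <= 1.0):
            raise ApmsError("control_carryover must lie in (0, 1]")
        if self.n_replicates < 2:
            raise ApmsError("need >= 2 replicates per condition")


@dataclass
class SimTruth:
    """Ground-truth labels: per-protein class and true fold (phi=1 for non-differential)."""

    table: pd.DataFrame  # columns: class, phi; index: protein id

    def proteins_of(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["class"] == cls])


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with median 1 and the given CV."""
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=shape)


def default_layout(n_replicates: int = 3) -> PlexLayout:
    channels = []
    for role, prefix in (
        (Role.WT_BAIT, "WT"),
        (Role.VARIANT_BAIT, "VAR"),
        (Role.NEGATIVE_CONTROL, "CTRL"),
    ):
        for r in range(1, n_replicates + 1):
            channels.append(Channel(id=f"{prefix}-{r}", role=role, replicate=r))
    return PlexLayout(channels)


def simulate_apms(
    config: ApmsSimConfig,
) -> tuple[AbundanceMatrix, PlexLayout, SimTruth]:
    """Draw one synthetic abundance matrix with layout and ground truth.

    Experimental abundance of a bait-dependent protein i in channel c is
    ``bait_level_c * b_i * phi_i^[c is variant] * eps`` with b_i log-normal
    and eps multiplicative noise; its control abundance is
    ``carryover * b_i * eps``.  Nonspecific proteins show ``b_i * eps`` in
    every channel.  The bait row is ``bait_level_c * eps`` experimentally and
    ``carryover * bait_level * eps`` in the controls.
    """
    rng = np.random.default_rng(config.seed)
    layout = default_layout(config.n_replicates)
    nrep = config.n_replicates
    wt = layout.wt_channels
    var = layout.variant_channels
    ctrl = layout.control_channels

    bait_levels = config.bait_level * (
        1.0 + config.bait_level_jitter * rng.uniform(-1.0, 1.0, size=2 * nrep)
    )

    n_bg, n_ns, n_dif = (
        config.n_background_binders,
        config.n_nonspecific,
        config.n_differential,
    )
    ids = (
        ["BAIT"]
        + [f"BG{i:04d}" for i in range(1, n_bg + 1)]
        + [f"NS{i:04d}" for i in range(1, n_ns + 1)]
        + [f"DIF{i:04d}" for i in range(1, n_dif + 1)]
    )
    classes = (
        [CLASS_BAIT]
        + [CLASS_BACKGROUND] * n_bg
        + [CLASS_NONSPECIFIC] * n_ns
        + [CLASS_DIFFERENTIAL] * n_dif
    )
    phi = np.ones(len(ids))
    phi[np.array(classes) == CLASS_DIFFERENTIAL] = config.differential_fold

    n = len(ids)
    b = rng.lognormal(config.binding_log_mean, config.binding_log_sd, size=n)
    is_ns = np.array(classes) == CLASS_NONSPECIFIC
    is_bait = np.array(classes) == CLASS_BAIT

    exp_mean = np.empty((n, 2 * nrep))
    exp_mean[:] = bait_levels[None, :] * b[:, None]
    exp_mean[:, nrep:] *= phi[:, None]  # variant channels carry the true fold
    exp_mean[is_ns, :] = b[is_ns, None]
    exp_mean[is_bait, :] = bait_levels[None, :]

    ctrl_mean = np.empty((n, nrep))
    ctrl_mean[:] = config.control_carryover * b[:, None]
    ctrl_mean[is_ns, :] = b[is_ns, None]
    ctrl_mean[is_bait, :] = config.control_carryover * config.bait_level

    values = np.hstack(
        [
            exp_mean * _noise(rng, config.noise_cv, exp_mean.shape),
            ctrl_mean * _noise(rng, config.noise_cv, ctrl_mean.shape),
        ]
    )
    data = pd.DataFrame(values, index=ids, columns=wt + var + ctrl)
    matrix = AbundanceMatrix(data=data, bait_id="BAIT")
    truth = SimTruth(pd.DataFrame({"class": classes, "phi": phi}, index=ids))
    return matrix, layout, truth


def simulate_rater_counts(
    n_participants: int,
    images_per_genotype: int,
    cells_per_image: int,
    true_proportion: dict[str, float],
    image_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Per-image binomial counts around a genotype-level true proportion.

    Each image's latent proportion is the genotype's true proportion
    perturbed on the logit scale by N(0, image_sd); counts are then
    binomial(cells_per_image, latent).  Returns a rater-count table
    (participant, image, genotype, positive, total).
    """
    if image_sd < 0:
        raise ApmsError("image_sd must be >= 0")
    for g, p in true_proportion.items():
        if not (0.0 < p < 1.0):
            raise ApmsError(f"true proportion for {g!r} must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for pi in range(1, n_participants + 1):
        for g, p in true_proportion.items():
            latent = expit(
                logit(p) + rng.normal(0.0, image_sd, size=images_per_genotype)
            )
            pos = rng.binomial(cells_per_image, latent)
            for im in range(1, images_per_genotype + 1):
                rows.append(
                    {
                        "participant": f"participant_{pi}",
                        "image": f"{g}_img{im:02d}",
                        "genotype": g,
                        "positive": int(pos[im - 1]),
                        "total": cells_per_image,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class FdrSimResult:
    """Monte-Carlo estimate of the discovery pipeline's FDR and power."""

    empirical_fdr: float
    fdr_mc_se: float
    power: float
    power_mc_se: float
    per_rep: pd.DataFrame = field(repr=False)
    q_target: float = 0.10


def rep_seed(master_seed: int, rep: int) -> int:
    """Per-rep seed: a counter scheme over (master_seed, rep)."""
    return int(np.random.SeedSequence([master_seed, rep]).generate_state(1)[0] % (2**31))


def run_discovery_rep(
    config: ApmsSimConfig, q_target: float, rule: FilterRule | None = None
) -> tuple[int, int, int, int]:
    """One pipeline pass: returns (rejections, false positives, true positives, family size).

    The tested family is the high-confidence set minus the bait, exactly as
    in the end-to-end pipeline; the t-test runs on log2 normalized abundances.
    """
    matrix, layout, truth = simulate_apms(config)
    fres = high_confidence_filter(matrix, layout, rule)
    family = sorted(fres.retained - {matrix.bait_id})
    if not family:
        return 0, 0, 0, 0
    norm = bait_normalize(matrix, layout)
    tests = condition_t_tests(norm, layout, log_transform=True).loc[family]
    p = tests["p"].to_numpy()
    rejected, _, _ = bky_decisions(p, q_target)
    cls = truth.table.loc[family, "class"].to_numpy()
    r = int(rejected.sum())
    tp = int((rejected & (cls == CLASS_DIFFERENTIAL)).sum())
    return r, r - tp, tp, len(family)


def fdr_simulation(
    config: ApmsSimConfig,
    reps: int,
    q_target: float,
    master_seed: int,
    rule: FilterRule | None = None,
) -> FdrSimResult:
    """Empirical FDR and power of the full discovery pipeline.

    Each rep simulates a fresh multiplex (seeded from ``master_seed`` and the
    rep counter), runs filter -> bait normalization -> fold enrichment ->
    log2 homoscedastic t-test -> two-stage BKY at ``q_target``, and counts
    false positives among rejected non-differential proteins.  Empirical FDR
    is the mean of FP/max(R, 1); power the mean fraction of differential
    proteins rejected.  Monte-Carlo standard errors accompany both.
    """
    if reps < 1:
        raise ApmsError("reps must be >= 1")
    rows = []
    for rep in range(reps):
        cfg = replace(config, seed=rep_seed(master_seed, rep))
        r, fp, tp, fam = run_discovery_rep(cfg, q_target, rule)
        rows.append({"rep": rep, "rejections": r, "false_positives": fp,
                     "true_positives": tp, "family_size": fam})
    per_rep = pd.DataFrame(rows)
    fdp = per_rep["false_positives"] / per_rep["rejections"].clip(lower=1)
    fdr = float(fdp.mean())
    fdr_se = float(fdp.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0
    if config.n_differential > 0:
        frac = per_rep["true_positives"] / config.n_differential
        power = float(frac.mean())
        power_se = float(frac.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0
    else:
        power, power_se = float("nan"), float("nan")
    return FdrSimResult(
        empirical_fdr=fdr,
        fdr_mc_se=fdr_se,
        power=power,
        power_mc_se=power_se,
        per_rep=per_rep,
        q_target=q_target,
    )
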