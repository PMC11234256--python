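"""Blinded multi-rater tissue scoring and two-group measurement comparisons.

Several blinded participants each count, per microscopy image, the total
number of cells and the number with intracellular staining.  Per genotype the
point estimate is the mean (across participants) of each participant's pooled
proportion (summed positives over summed totals), with the SEM taken across
participants.  Significance between two genotypes is assessed per participant
with a Welch t-test on per-image proportions, and the LARGEST of the
per-participant p-values is reported — a deliberately conservative rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ApmsError, CoverageError, InsufficientReplicatesError
from .model import TTestResult
from .enrichment import homoscedastic_t_test, welch_t_test

REQUIRED_COLUMNS = ["participant", "image", "genotype", "positive", "total"]


def validate_rater_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a rater-count table (participant, image, genotype, positive, total)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise ApmsError(f"rater-count table lacks column(s): {missing}")
    df = counts.copy()
    df["positive"] = df["positive"].astype(int)
    df["total"] = df["total"].astype(int)
    if (df["positive"] < 0).any():
        raise ApmsError("positive cell counts must be non-negative")
    if (df["total"] <= 0).any():
        raise ApmsError("total cell counts must be positive")
    bad = df[df["positive"] > df["total"]]
    if not bad.empty:
        row = bad.iloc[0]
        raise ApmsError(
            f"positive > total for participant {row['participant']!r}, "
            f"image {row['image']!r}"
        )
    return df


def read_rater_counts(path) -> pd.DataFrame:
    return validate_rater_counts(pd.read_csv(path, sep="\t"))


@dataclass
class RetentionSummary:
    """Aggregated retention proportions per genotype.

    ``participant_proportions``: genotype -> {participant -> pooled proportion};
    ``mean`` and ``sem`` are taken across participants.
    """

    participant_proportions: dict[str, dict[str, float]]
    mean: dict[str, float]
    sem: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        genotypes = sorted(self.mean)
        return pd.DataFrame(
            {
                "genotype": genotypes,
                "mean_proportion": [self.mean[g] for g in genotypes],
                "sem": [self.sem[g] for g in genotypes],
            }
        )


def retention_summary(counts: pd.DataFrame) -> RetentionSummary:
    """Pooled per-participant proportions, then mean and SEM across participants.

    Pooling sums counts over that participant's images of the genotype, so
    images with more cells weigh more.  Every participant must contribute at
    least one image to every genotype they appear with.
    """
    df = validate_rater_counts(counts)
    participants = sorted(df["participant"].unique())
    genotypes = sorted(df["genotype"].unique())
    props: dict[str, dict[str, float]] = {}
    mean: dict[str, float] = {}
    sem: dict[str, float] = {}
    for g in genotypes:
        sub = df[df["genotype"] == g]
        per_part: dict[str, float] = {}
        for part in participants:
            rows = sub[sub["participant"] == part]
            if rows.empty:
                raise CoverageError(
                    f"participant {part!r} has no images for genotype {g!r}"
                )
            per_part[part] = rows["positive"].sum() / rows["total"].sum()
        vals = np.array(list(per_part.values()))
        props[g] = per_part
        mean[g] = float(vals.mean())
        sem[g] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return RetentionSummary(participant_proportions=props, mean=mean, sem=sem)


def retention_significance(
    counts: pd.DataFrame, genotype_a: str, genotype_b: str
) -> tuple[dict[str, float], float]:
    """Per-participant Welch p-values on per-image proportions, plus the max.

    The reported p-value is the maximum over participants, so every rater
    individually supports any claimed difference.
    """
    df = validate_rater_counts(counts)
    per_participant: dict[str, float] = {}
    for part in sorted(df["participant"].unique()):
        groups = []
        for g in (genotype_a, genotype_b):
            rows = df[(df["participant"] == part) & (df["genotype"] == g)]
            if len(rows) < 2:
                raise InsufficientReplicatesError(
                    f"participant {part!r} has {len(rows)} image(s) for genotype "
                    f"{g!r}; need >= 2"
                )
            groups.append((rows["positive"] / rows["total"]).to_numpy())
        per_participant[part] = welch_t_test(groups[0], groups[1]).p_value
    return per_participant, max(per_participant.values())


def compare_measurements(
    values_a, values_b, variance_mode: str = "welch"
) -> TTestResult:
    """Two-sided t-test between two measurement sets (e.g. TUNEL intensity
    per area, or chondronoid diameters).

    ``variance_mode`` selects pooled-variance ("pooled") or Welch ("welch").
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ApmsError("measurement sets must be non-empty and finite")
    if variance_mode == "pooled":
        return homoscedastic_t_test(a, b)
    if variance_mode == "welch":
        return welch_t_test(a, b)
    raise ApmsError(f"unknown variance_mode {variance_mode!r}")
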