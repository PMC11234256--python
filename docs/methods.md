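# Methods

## Experimental design assumed

One isobaric multiplex quantifies each protein across nine analyzed
channels: three biological replicates each of wild-type bait, variant bait,
and a no-transfection negative control (a tenth, unused channel is
representable in the layout and dropped on load). Channel roles are always
declared in a separate JSON layout, never inferred from column names, since
reporter-channel naming is vendor-specific. Raw, searched protein-level
abundances are the input; spectral search and reporter quantification are
out of scope.

## High-confidence filtering

Filtering runs on raw abundances, before bait normalization: the negative
controls contain no bait, so only the raw scale is comparable across all
nine channels. The per-protein baseline is the arithmetic mean over control
channels with missing values counted as zero — an undetected protein in a
control channel contributes no background signal. The default rule retains
a protein when its abundance strictly exceeds 2× baseline in at least 4 of
the 6 experimental channels. Two readings of the published rule coexist in
the source material; the 4-of-6 strict-inequality reading is the default
because it annotates the published result table, and the stricter
all-replicates reading is available as a mode. A zero baseline with any
positive experimental signal passes: absence from the control is the
strongest enrichment evidence, and the ratio is unbounded. A missing
experimental value fails that channel. The bait itself is always scored and
flagged.

## Normalization, fold enrichment, testing

Bait normalization divides each protein's abundance by the bait's abundance
in the same channel, which exactly cancels any per-channel global rescaling
(pull-down efficiency, loading). Fold enrichment is the ratio of condition
means of normalized abundance (variant over wild-type), computed with
missing values excluded; with equal effective replicate counts this equals
the ratio of sums. Means rather than sums are used so unequal missingness
between conditions behaves sensibly. A zero wild-type mean or an all-missing
condition yields an undefined (NaN) fold enrichment, logged, with the
protein retained in the output.

Differential interaction is tested per protein with a two-sided
pooled-variance t-test on the normalized abundances, untransformed by
default (the literal published description). A log2 option exists because
raw-scale normality of multiplicative abundance noise is doubtful; under
the generator's log-normal noise the log2-scale test is exactly valid, and
the FDR validation harness uses it. Zero pooled variance is resolved
deterministically rather than returning NaN — p = 1 with equal means, p = 0
with unequal means, both logged — so pipelines never silently drop
proteins. The Welch test (Welch–Satterthwaite degrees of freedom) backs the
tissue-scoring comparisons.

## Two-stage BKY FDR and q-values

Stage one is a Benjamini–Hochberg step-up at level q′ = q/(1+q) over all m
hypotheses, giving r1 rejections and the null-count estimate m0 = m − r1;
stage two reruns the BH step-up at q′ with m0 in place of m. Edge cases
follow the original procedure: r1 = 0 accepts everything, r1 = m rejects
everything. Ties in p share the larger rank's threshold, as in any step-up
rule.

The procedure itself returns only accept/reject decisions, so q-values are
defined operationally: the smallest desired-FDR level at which the
hypothesis is rejected, found on a grid of step 1e-4 (the grid always
contains the working level, making "rejected at q" and "q-value ≤ q"
equivalent by construction; rejection sets are monotone in the level). The
implementation sweeps the grid in closed form by grouping levels on the
stage-one rejection count, which is piecewise constant in the level; the
test suite verifies the sweep against a literal level-by-level scan. A
closed-form alternative (BH-adjusted p scaled by m0/m) is provided under a
separate, clearly labelled name; it is a different estimand and can
disagree with the search near the rejection boundary, because the search
re-estimates m0 at every level. Published q-value magnitudes from rounded
p inputs are reproducible only approximately (e.g. the searched q for CALR
is 0.1023 on the packaged reference p-values); rejection decisions are
robust across variants and are what the tests pin down.

The FDR family defaults to the filtered high-confidence set — the only
family the published table reports — with an option to test all detected
proteins. The bait is excluded from the family and the output table: its
normalized abundance is identically 1, so it carries no comparative
information (FE = 1, p = 1 under the zero-variance policy).

## Tissue scoring

Each of several blinded raters counts total and positively stained cells
per image. The genotype point estimate is the mean over raters of each
rater's pooled proportion (summed positives over summed totals across their
images), with the SEM taken across raters; pooling weights images by cell
count. Significance between genotypes uses per-image proportions as the
replication unit — the only reading that yields a within-rater variance —
with a Welch test per rater, reporting the largest p-value across raters.
That max-p rule is conservative by construction (under the null with three
raters, reported p < 0.05 has probability ≈ 0.05³ ≈ 1e-4), which the test
suite confirms by simulation. No minimum-cells-per-image exclusion is
applied by default; a threshold is available. Two-group measurement
comparisons (apoptosis-stain intensity per area, organoid diameters)
default to the Welch variant since the test flavor is unspecified in the
source description.

## Synthetic-data generator

`simulate_apms` draws one multiplex with four protein classes: the bait;
bait-dependent background binders (true fold 1 — the nulls); nonspecific
resin binders with equal expected signal in control and experimental
channels; and differential interactors enriched φ-fold in the variant
condition. Per-protein binding strength is log-normal (median 50, log-sd
1), experimental signal is bait_level × binding × φ^[variant] with ±10%
channel-to-channel jitter in the bait level, and bait-dependent signal
leaks into the controls at 30% relative carryover ("kappa-level" for the
bait row is read as kappa × base bait level). All noise is multiplicative
log-normal with median 1 and CV 10% by default, so log2 values are exactly
normal and the log2 t-test is exact. Defaults (200 background binders, 100
nonspecific, 20 differential at φ = 2, 3+3+3 channels) describe a
realistically sized pull-down with a modest effect at the edge of
detectability for n = 3.

What the generator does **not** emulate: peptide-to-protein rollup,
isotopic-impurity interference between channels, missing-not-at-random
censoring at the detection limit, and correlated binding between proteins
(beyond the channel-level dependence induced by dividing every protein by
the same noisy bait measurement). Passing simulation-based tests therefore
demonstrates correctness of the statistics under the stated model, not
robustness to those real-data features.

`simulate_rater_counts` draws per-image binomial counts around a
genotype-level true proportion perturbed per image on the logit scale,
emulating between-image heterogeneity in a multi-rater scoring experiment.

`fdr_simulation` chains generator and pipeline (filter → normalize → FE →
log2 t-test → BKY) per replicate, counting false positives among rejected
non-differential proteins; it reports mean FDP, power, and Monte-Carlo
standard errors. Per-replicate seeds derive from the master seed by a
counter scheme (`SeedSequence([master_seed, rep])`), making every replicate
independently reproducible. 500 replicates (~3 s) give an FDR standard
error of about 0.007 at the default configuration.

## Numerical and design choices

- Missing abundances stay missing (NaN) at load; each stage states its own
  policy (filter: fail the channel / zero the control; FE and t-test:
  exclude or propagate as undefined).
- Result tables sort by fold enrichment descending, ties by p ascending
  then protein id — the printed convention, with a deterministic tie-break.
- Star annotations for expression panels use strict thresholds 0.05 / 0.01
  / 0.001 on the adjusted p.
- All generators are pure functions of (config, seed) with one pinned RNG
  (numpy's default PCG64); determinism, not a particular bit stream, is the
  contract.
- Known limitation: with only three replicates per condition the
  pooled-variance estimate is noisy, and the pipeline makes no attempt at
  variance moderation — by design, matching the published analysis.
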