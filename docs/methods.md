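# Methods notes

This note records the statistical conventions the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical decisions a reader would need to
reproduce results exactly.

## Preprocessing

Array cohorts follow the chain *background correct → log₂ → quantile
normalize → detection filter*.

* **Background correction** is a minimum-shift rule: when the cohort
  minimum is ≤ 0, every value is shifted so the minimum becomes exactly 1
  (`shift_to_positive`); positive matrices pass through. Model-based
  array background adjustment needs bead-level data that public matrices
  do not carry; the shift rule is deterministic, preserves all
  contrasts, and is recorded in the run log. Mode `none` disables it.
* **Quantile normalization** forces every sample onto the common
  reference distribution (the row-wise mean of the column-sorted
  matrix). Ties within a column receive the mean of the reference values
  over their rank span, which makes the operation deterministic, stable
  under sample permutation, and idempotent. A single-sample cohort is a
  warned no-op.
* **Detection filtering** keeps probes whose array detection p-value is
  *strictly* below 0.01 in at least one sample (both numbers
  configurable). The strict inequality matters at the boundary and is
  asserted in tests.
* **RNA-seq cohorts** distributed as upper-quartile-normalized counts
  take only log₂(x + 1); no quantile step, since such data are already
  between-sample normalized upstream.
* Whether the original analyses filtered on detection p before or after
  quantile normalization is generally unknowable from public methods
  text; this package filters **after** normalization (filtering first
  would change the quantile reference), and the order is visible in
  `normalize.preprocess_array_cohort`.
* **Isoform collapse** (mean of all probes mapped to a gene) happens
  after normalization, on the log₂ scale — averaging raw intensities
  would let bright probes dominate. The mean is unweighted; a median
  variant can be obtained by collapsing manually.

## Consistency screen

Correlations are computed on primary-tumor samples only (configurable),
with mid-ranks everywhere and pairwise-complete removal of missing
values. The per-cohort criterion is boundary-inclusive: ρ ≥ ρ_min and
p ≤ p_max. ρ_min defaults to 0.2 with positive sign required — the
screen seeks positive association with the anchor; `require_positive_rho
= False` switches to |ρ|. The aggregation rule is a strict majority
(> 50%) of *evaluable* cohorts per criterion; a cohort that does not
measure a gene shrinks that gene's denominator rather than counting as a
failure. For the alteration arm the default direction is `down`
(loss-of-expression screen); with `any`, only the majority direction
among passing cohorts counts, so opposite-direction cohorts can never
jointly carry a gene past the threshold (ties break toward `down`).

Small-sample exactness:

* **Spearman**: ρ is the Pearson correlation of mid-ranks; the two-sided
  p-value is exact by full enumeration of all n! rank permutations for
  n ≤ 8 and uses the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df
  otherwise. The minimum n is 3 (the exact route covers it).
* **Mann–Whitney**: exact enumeration when the smaller group has ≤ 8
  values and the pooled data are tie-free; otherwise the normal
  approximation with tie and continuity corrections. Fully tied data
  yield p = 1 (logged) rather than an error, since a degenerate test is
  an expected outcome on filtered array data.

## Moderated t differential expression

The hierarchical model is the standard scaled-inverse-chi-square
hierarchy: s² | σ² ~ σ²·χ²_d/d per probe and σ² ~ s₀²·d₀/χ²_{d₀}. The
prior is estimated by a moment match on e = log s² − ψ(d/2) + log(d/2):
the excess of var(e) over the sampling term ψ′(d/2) equals ψ′(d₀/2),
inverted by Newton iteration on the strictly decreasing trigamma; the
mean relation then gives s₀². When var(e) shows no excess dispersion,
d₀ = ∞ and every variance is fixed at s₀² (normal-limit reference
distribution). d₀ = 0 reduces *exactly* to the ordinary pooled
two-sample t, which is asserted to 1e−10 end to end, and the estimator
agrees with Bioconductor limma's `eBayes` to ~1e−6 on a frozen seeded
fixture (cross-check in the test suite).

Fold-change selection is two-stage on purpose: `significant` (adjusted
p < 0.05) and `fc_filtered` (additionally |linear FC| ≥ 1.5), because
published workflows are often ambiguous about whether the significance
count was taken before or after the fold cut; both readings stay
reproducible. The signed linear fold change is 2^lfc for lfc ≥ 0 and
−2^(−lfc) otherwise, so its magnitude is always ≥ 1. Benjamini–Hochberg
is the classical step-up with running-minimum monotonicity, input order
preserved.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) per gene set via the log-space
survival function, BH across all tested sets. The universe defaults to
whatever gene list the caller supplies — for array experiments the
natural choice is all genes measured after detection filtering — and
query genes outside the universe are dropped with a logged count.
Gene-set collections are user-supplied GMT files; no ontologies are
bundled (they are version-dependent).

## Survival stratification

The stratifier is Q1 vs rest: patients at or below the empirical
0.25-quantile (linear interpolation between order statistics) of the
signature signal form Q1; boundary ties all go to Q1 so the low group is
never empty. The composite signature is the raw mean of the per-gene
log₂ signals (`mean_signal`); `zscore_mean` standardizes each gene first
and is offered because cross-gene scale differences can dominate a raw
mean. Kaplan–Meier curves use the product-limit estimator with
events-before-censoring at tied times. The log-rank test accumulates the
hypergeometric variance term at each distinct event time; the hazard
ratio is the O/E form (O₁/E₁)/(O₂/E₂) with Q1 as group 1, so HR > 1
means the low-expression group recurs faster. A group with observed
events but zero expected (or vice versa) reports a diverged HR (±∞ /
flagged) rather than failing. Cox regression is deliberately not used:
the reporting convention here is KM/log-rank only.

## qPCR / ChIP-qPCR

Amplification efficiency is fixed at 2 (one doubling per cycle),
exposed as a parameter. ΔΔCt anchors on the arithmetic mean ΔCt of the
reference condition, making the reference-condition mean fold exactly 1;
the quantity is invariant to any constant added to all Ct values. ChIP
enrichment is antibody-over-IgG per condition, induced divided by
uninduced; the shared-offset invariance means an input-normalization
step upstream would not change the result. Fold changes are tested
against 1 with a one-sample t (two-sided by default, one-sided
available).

## Synthetic data generator

The generator emulates the statistical structure the screen assumes:

* per-cohort panels of genes measured through 1–4 isoform probes, raw
  intensities 2^(log₂ signal) with per-cell detection p-values, so the
  full preprocessing chain applies;
* anchor–candidate correlations planted at a target **population
  Spearman** ρ via the exact Gaussian identity ρ_S = (6/π)·asin(ρ_P/2);
  because isoform measurement noise attenuates the measured correlation,
  the latent Pearson correlation is inflated by the exact attenuation
  factor σ/√(σ² + τ²/k) per gene (σ = gene-level noise SD, τ = isoform
  noise SD, k = isoform count), so the *measured, isoform-collapsed*
  signal attains the target. This is calibration by construction, exact
  in population for jointly Gaussian signals;
* tumor shifts in log₂ units for planted genes; presence masks that
  remove a gene from chosen cohorts entirely;
* detection noise: a configurable fraction (default 5%) of probes are
  never detected and fall to the detection filter. Noise probes are
  drawn only among filler genes — the anchor's and planted candidates'
  measurability is part of the planted ground truth (`present_in`), and
  letting the platform silently delete them would contradict it;
* disease-free survival from an exponential proportional-hazards model,
  hazard = h₀·exp(Σ β_g z_g) on standardized gene signals (β < 0 =
  protective), with independent uniform censoring whose upper bound is
  calibrated numerically so the expected censored fraction matches the
  target, plus administrative truncation at the maximum follow-up.

Defaults describe a typical public prostate-cancer compendium: 7
cohorts of 12 normal + 50 tumor samples, 200 genes, unit log₂
biological noise, 0.25 isoform noise, baseline hazard 0.02/month
(median ≈ 3 years), 180-month follow-up.

Randomness is structured as one stream per (cohort, gene) pair derived
from the master seed, so adding a gene to the panel never perturbs other
genes' draws; this is asserted in tests.

**What the generator does not emulate:** platform-specific intensity
distributions (beyond the variance prior and detection mechanism),
probe GC/affinity effects, batch structure within a cohort,
non-proportional hazards, informative censoring, and correlated
candidate genes. Tests passing on these worlds therefore demonstrate
the pipeline's correctness and calibration under its stated model, not
robustness to those real-data pathologies.

## Simulation studies and problem sizes

The `studies` module fixes the end-to-end study designs: 100 seeded
seven-cohort worlds for screen recovery (one candidate at ρ = 0.45 in
5/7 cohorts, shift −1, screened against 15 nulls); 5000 null probes for
moderated-t calibration; 2000 probe variances at d₀ = 4, s₀² = 0.05,
d = 4 for prior recovery; 200 survival cohorts of 130 patients with two
equally protective genes (log-hazard 0.5/SD, 50% censored) for the
composite-signature comparison. Each study runs in seconds to about a
minute on one CPU. One sizing lesson is recorded here deliberately:
shrinking the gene panel below ~100 genes biases the screen, because
quantile normalization over too few probes distorts cross-sample ranks
and attenuates planted correlations (measured mean ρ 0.38 vs 0.45 at a
30-gene panel). The studies therefore keep the default 200-gene panel.

## Known limitations

* The screen applies per-cohort thresholds with no multiple-testing
  correction across candidates, matching the screening convention it
  reproduces; a large candidate list will contain majority-vote false
  positives at the expected rate.
* `estimate_variance_prior` assumes a common residual df across probes;
  probes with missing values are not given probe-specific df.
* The exact Spearman permutation p is O(n!) and capped at n = 8;
  between n = 9 and ~12 the t approximation is used even though exact
  enumeration is merely expensive, matching common practice.
* The O/E hazard ratio is a test-based approximation; it is reported
  because it is the convention of the KM/log-rank workflow being
  reproduced, not because it is the most efficient HR estimator.
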