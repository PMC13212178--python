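# Methods

`qualcbma` implements three related pieces of methodology for judging and
contextualizing the amount of evidence behind a coordinate-based meta-analysis
(CBMA) of neuroimaging studies: a power-based study-weighting scheme, a
machine-readable 15-criterion reporting checklist, and a simulation that
quantifies the information advantage of statistical maps over peak
coordinates. This note records the models, their assumptions, the numerical
choices, and what the synthetic data used in testing does and does not
establish.

## 1. Power-based study weighting

### Model

A CBMA's power is driven by the number of independent datasets, but datasets
differ hugely in size. The weighting scheme counts each study as

    count = min(power / 0.80, 1.25),

where `power` is the study's power to detect a one-sided very large effect
(Cohen's d = 1) at p = 0.001 under its own design, computed from the exact
noncentral t distribution:

- one-sample: df = n − 1, noncentrality δ = d·√n,
- two-sample: df = n₁ + n₂ − 2, δ = d·√(n₁n₂/(n₁+n₂)),

and `power = P(T′_{df,δ} > t_{1−α,df})`. A one-sample study of 20 participants
has ≈79.2% power and counts as ≈0.99 datasets; a study of 38 or more counts as
1.25, the cap (1/0.80). Studies contributing full statistical maps count
twice; the cap applies to the power ratio *before* map doubling, so a map
study maxes out at 2.5 and a 5-participant map counts as 2 × 0.04 = 0.08.

Numerical choices:

- Exact noncentral-t quantiles/tails via `scipy.stats.nct`; no normal
  approximation. The two-decimal published lookup table is reproduced to
  ±0.01 over its whole domain (one-sample n = 5–38, two-sample n = 5–69 per
  group).
- δ = 0 is routed through the central t distribution so that null power
  equals α exactly rather than up to quadrature noise.
- Display rounding is two decimals, half-up, matching the printed table; all
  sums (the adjusted dataset count) use full-precision weights. Summing
  rounded weights would drift: 17 studies of n = 20 give 16.84 unrounded
  versus 16.83 from the rounded 0.99.
- Unequal two-sample groups use the harmonic-mean noncentrality above; the
  published table is the equal-groups special case.
- At n = 2–3 a two-sample design can slightly out-power a one-sample design
  of the same per-group n (degrees of freedom beat noncentrality); the
  monotone design ordering is only asserted for n ≥ 4, which covers the
  table's domain.

### The dataset-count criterion and OIS

Criterion 12 of the checklist asks for at least 17 independent datasets
(23 for structural MRI — a hedged recommendation we apply as a hard threshold
under `modality="structural_mri"` because a binary checklist item needs a
deterministic rule; the hedge lives in the rendered wording). The criterion
gates on the *unadjusted* count by default; the adjusted count is advisory
context and becomes the gate only via `Criterion12Config(use_adjusted=True)`.
`ois_total` provides the GRADE-style optimal-information-size arithmetic:
17 studies of 20 participants ≈ 340 participants (one-sample), 17 × 33 = 561
per group (two-sample) — roughly the single-study sample needed to detect a
small effect (d = 0.2) one-sided at p = 0.001 with 80% power.

## 2. The checklist engine

The 15 criteria (each tracing to one of the ten field rules) are a frozen
registry; documents are YAML files with one analysis per individual CBMA —
in multi-CBMA manuscripts each modality or subgroup analysis gets its own
checklist, and multimodal conjunction analyses get none. Validation
distinguishes:

- **errors** — structural rule violations: an empty comment, "not applicable"
  outside criteria 5–6, an unmet criterion with no declaration about
  manuscript commenting;
- **warnings** — an unmet criterion explicitly declared *not* commented in
  the manuscript, or a criterion-12 response contradicting an attached study
  table (a warning, never an error: authors may justify contextually);
- **notes** — every unmet criterion, as a reading aid.

No aggregate score is ever produced; `tally` counts responses across
documents solely for meta-research on reporting practices. The
`manuscript_commented` flag is self-declared — the tool verifies the
declaration, not the manuscript.

Design choices: comments and labels are single-paragraph free text; internal
line breaks are collapsed to spaces at construction so that the Markdown
rendering is lossless (`load(render(doc)) == doc`, byte-identical on
re-render). The rendered criterion-12 text prints the default threshold of
17; the structural-MRI 23 surfaces only through the cross-check warning.

## 3. The map-vs-peak information simulation

### Generative model

Each simulated meta-analysis has k one-sample studies (k = 10–20) of
n = 20 participants, true effect d ∈ {0.2, 0.5, 0.8}, no between-study
heterogeneity. Study t-values are exact noncentral-t draws (df = n − 1,
δ = d√n); the effect estimate is y = t/√n with standard error 1/√n. The
first `n_maps` studies "provide statistical maps" and always report y; the
remaining peak-coordinate studies report y only when significant at
p < 0.001. n = 20 is the package's choice of a realistic per-study size — it
is the sample at which one-sample power for d = 1 hits the weighting scheme's
80% anchor — and is a config knob.

**Censoring sidedness.** The default reporting rule is two-sided: a peak
study is unreported when |t| stays below the two-sided p < 0.001 critical
value, and the estimator assigns it the interval probability mass. This
matches how MetaNSUE defines a non-statistically-significant unreported
effect, and it keeps the likelihood identified even when *every* study is
censored (the interval mass peaks at μ ≈ 0). A strictly one-sided rule
(`sidedness="one_sided"`) is available but degenerate in exactly that case:
with no reported study the likelihood is monotone in μ, the fit fails, and
the meta-analysis must be redrawn — at d = 0.2 and k = 10 this discards over
90% of draws and conditions the surviving cells on "at least one significant
study", which inflates their mean z and can invert the calibration described
below. Redraws are counted and reported either way.

### Estimator

A censored-likelihood MLE in the spirit of MetaNSUE: reported studies
contribute `N(y; μ, se²)` densities, unreported studies the censored mass
(interval for two-sided, lower tail for one-sided). μ̂ maximizes the
log-likelihood (bounded scalar minimization, xatol 1e−9; with no censored
study the closed-form inverse-variance mean is used and the reduction is
exact); the pooled standard error is the inverse square root of the observed
information, a central-difference curvature at μ̂ (h = 1e−4·max(1,|μ̂|)); the
meta-analytic statistic is z = μ̂/se. MetaNSUE's multiple-imputation step is
deliberately not implemented: the quantities of interest here are driven by
the censored likelihood itself. The estimator assumes homogeneity (τ² = 0),
matching the generator, and a normal likelihood for y although y is
noncentral-t distributed — the same approximation effect-size meta-analyses
make, slightly inflating μ̂ (by the nct mean factor, ≈4% at n = 20).

### Calibration and the multiplier

For each effect size, the zero-map cells give a least-squares calibration
√k = a + b·z̄; inverting it turns any cell's mean z into an *equivalent
number of peak-only studies*, (max(a + b·z̄, 0))². The per-map information
multiplier is the slope of the interceptless regression of
(equivalent k − actual k) on n_maps, plus one — per effect size, and pooled
over all cells for the headline figure. Under the defaults (100 meta-analyses
per cell, seed 0) the multiplier comes out near 4 overall, near 10 at
d = 0.2, and just above 1 at d = 0.8: maps matter most exactly when censoring
bites, i.e. for small effects. With censoring disabled the multiplier
collapses to ≈1, a null check that the pipeline measures censoring and
nothing else.

Reproducibility: every (d, k, n_maps) cell draws from its own
`SeedSequence`-spawned stream, so the grid is bit-reproducible under a fixed
seed and independent of evaluation order.

### What the synthetic world does not establish

The generator emulates univariate, homogeneous, one-sample meta-analyses
with a single known per-study n. Real CBMAs are spatial (voxelwise, with
smoothing and correlated peaks), heterogeneous across studies, and mix
designs and sample sizes; none of that is modelled, and the multiplier's
magnitude — though stable in ordering (small effects benefit most) — should
be read as a stylized calibration, not a universal constant. That is also
why the practical weighting rule above counts a map study as only 2, a
deliberately conservative round-down of the simulated factor.

## Known limitations

- Power-based weights are fixed at d = 1 by convention; the scheme does no
  effect-size-specific power planning.
- The checklist engine attests, it does not verify: literature searches,
  threshold uniformity, and manuscript comments are declared by authors.
- The censored-ML z is a large-sample Wald statistic; at heavily censored
  small-k cells its curvature-based standard error is optimistic, which the
  calibration absorbs but single-cell z values inherit.
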