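# Methods

## Problem

In glaucoma, deterioration of the visual field over time is the functional
endpoint that treatment aims to prevent. Longitudinal perimetry produces, per
eye, a series of visual fields: sensitivity thresholds (dB) at the 52
non-blind-spot locations of the Humphrey 24-2 pattern, at roughly half-yearly
visits. The statistical task is a *global* test of the null hypothesis that
no location is deteriorating, built from 52 noisy local trend estimates.
`vfprog` implements two published families of such tests and the framework
needed to compare them fairly.

## PoPLR

At each location, ordinary least squares of sensitivity on time (years from
baseline) gives a slope and the one-sided p-value of the t-test against
deterioration (lower tail, n − 2 df). Local p-values are combined as

    S = −Σₗ ln pₗ ,

which is Fisher's combined chi-square statistic divided by two. Because the
52 local tests are spatially correlated, S is not referred to a chi-square
distribution; instead the *series' own* permutation distribution is used:
the visit order of the value matrix is re-drawn uniformly at random `n_perm`
times (default 5000, sampled with replacement from all orderings), and

    p_global = #{S_perm ≥ S_obs} / n_perm .

Numerical conventions, chosen where the published description is silent:

- Local p-values are clamped to [1e-10, 1] before logs, so S is finite.
- Degenerate fits (zero residual variance): constant values give p = 0.5
  (no evidence either way), an exact noise-free decline gives p = 1e-10, an
  exact improvement p = 1. This avoids 0/0 t-statistics and is neutral
  under the null.
- The tie rule is `≥` (a series whose permutations all tie the observed S
  gets p = 1, and an all-constant series is never flagged); a strict-`>`
  mode and a (x+1)/(n+1) small-sample correction are available behind
  flags. The `≥` rule makes the test slightly conservative:
  P(p < α) ⪅ α.
- The observed ordering is not added to the permutation set.

## ANSWERS

ANSWERS shares the skeleton (52 local p-values, the same combined statistic,
usually written I⁻) but models two salient properties of perimetric data:
threshold errors are skewed and grow with depth of defect, and deterioration
is spatially coherent along retinal nerve-fiber bundles.

### Error model

The measurement error at true sensitivity `level` is a reflected, shifted
Weibull variate

    error = c − W ,  W ~ Weibull(k, λ),  c = λ·Γ(1 + 1/k),

so the error has mean zero, support (−∞, c] (bounded above, long left
tail — large negative excursions are common, large positive ones are not).
(k, λ) are piecewise constant over sensitivity bins. The default table uses
seven bins over [0, 40] dB with k rising from 1.5 (strongly skewed, damaged
ranges) to 3.6 (near-symmetric, healthy ranges) and λ set so the bin SD
matches the default dispersion curve: 1.0 dB at ≥ 30 dB, rising linearly to
6.0 dB at 10 dB, constant below. These numbers are documented stand-ins
capturing the direction and rough magnitude of published perimetric
test-retest behaviour; no claim of instrument-exact calibration is made.
`calibrate_error_model` re-fits the table from test-retest pairs
(per-bin constrained MLE with the mean-zero shift, then isotonic adjustment
so dispersion never increases with sensitivity).

### Regression

Per location, (intercept a, slope b) maximize Σₜ log f(yₜ − a − b·t) with
the bin of the clamped linear predictor (μₜ = clip(a + b·t, 0, 40))
selecting (k, λ, c); observations at the 0 dB floor contribute left-censored
terms log P(error ≤ −μₜ). The 52 independent two-parameter problems (104
free parameters per series) are solved by a Nelder–Mead simplex search run
*batched* across locations. The binned likelihood is piecewise and
genuinely multimodal (distinct basins correspond to different slope
readings of a noisy trajectory, typically where it straddles a bin
boundary), so the search starts from both the OLS fit and the best node of
a vectorized coarse scan over (intercept, slope) — 33 × 31 nodes spanning
±4 dB and ±1.5 dB/year around OLS — and keeps the better optimum per
location. Non-converged locations are retried once from a perturbed start.

Standard errors come from the numerically observed information (central
differences, 2×2). The local p-value is the one-sided Wald
p = Φ(b̂/se), clamped to [1e-10, 1]. When the optimum is pinned against the
support bound (one residual at the density wall) or the Hessian is not
positive definite, the standard error is unusable and the *series* fit is
reported as failed — the same breakdown mode reported for the original
method. On stable synthetic 7–9-visit cohorts roughly 5–10% of series fail;
failures are always surfaced and excluded with counts, never dropped
silently.

### Spatial enhancement

Local evidence is pooled on the log scale, ln p̃ = W ln p, with W a
row-stochastic 52×52 kernel. The default kernel is uniform within each of
six nerve-fiber-bundle sectors (60° angular wedges respecting the
horizontal raphe — a documented stand-in for published bundle maps, which
differ in detail) and zero across sectors. ANSWER is the identity-kernel
special case. Note that the default kernel is symmetric, hence doubly
stochastic, so the *combined* statistic is invariant to enhancement
(1ᵀW ln p = 1ᵀ ln p); enhancement redistributes evidence across the local
p-value map without changing S. Any other row-stochastic kernel may be
supplied, in which case S does change.

### Global p-values

- *Population mode* (the original design): p = (1 + #{S_null ≥ S_obs})/(N+1)
  against a pool of S values from a reference cohort of stable series.
  Pools are method-specific (ANSWERS vs ANSWER).
- *Permutation mode* ("modified" form): as in PoPLR, default 1000
  re-orderings; permutations whose fit fails are excluded from the
  denominator and counted.

## Evaluation framework

- Positive rate: fraction of series with p_global strictly below α, over a
  log-spaced grid of 60 points in [0.001, 0.15].
- False-positive rate: the positive rate after re-ordering each series in
  time once, uniformly at random — this destroys systematic trend while
  preserving each location's marginal distribution, so the measured rate
  estimates the FPR. A repeats option pools several re-orderings per series
  for tighter estimates.
- Specificity equating: positive rates are compared at matched *empirical*
  FPR, by pairing (FPR(α), PR(α)) over the α grid and interpolating
  monotonically; queries outside the observed FPR range return boundary
  values flagged as extrapolated.
- Paired differences of positive rates at a common (possibly equated)
  threshold use a paired percentile bootstrap over series (2000 replicates,
  seeded); the published analyses state no CI construction, so this is the
  package's own choice.

The central mechanism this framework exposes: population-based cutoffs are
only calibrated if the reference population is exchangeable with the test
population. A reference pool generated from unusually reliable test-takers
(dispersion scaled by 0.5) produces far too liberal cutoffs — on re-ordered
stable cohorts the population-mode FPR at α = 0.05 runs an order of
magnitude above nominal, while the individualized permutation variants stay
within binomial bands of 5%. The acceptance suite reproduces this
qualitatively.

## Synthetic cohorts

`generate_cohort` draws, per eye: a baseline field (normal template ≈ 33.5 −
0.12·eccentricity dB, minus sector-wise defects whose nominal depth is
scaled per-eye by Uniform(0.5, 1.5)); visit times starting at 0 with
intervals of configurable mean (default 0.458 y ≈ 5.5 months) and ±25%
uniform jitter; optional sector-wise true slopes (≤ 0) in a configurable
fraction of eyes; and noise in either mode — "weibull" (the error family
above, enabling well-specified recovery experiments) or "gaussian" (same
heteroscedastic SD curve, no skew, for misspecification testing). Values
are clipped to [0, 40] dB after noise, so the 0 dB floor produces exactly
the left-censoring the likelihood handles. True slopes are recorded;
temporal re-ordering invalidates them.

Presets emulate three published cohort profiles (7 visits/early damage,
9 visits/mixed, 18 visits/advanced with baseline MD ≈ −7.7 dB). Test-retest
pairs for error-model calibration are generated *unclipped* so the per-bin
error distributions are exactly the generating family.

Not simulated: thresholding staircases, response errors (false
positives/negatives), learning and fatigue, media opacity, inter-visit
correlation of noise. Consequently, passing calibration tests here
demonstrate statistical correctness under the stated data model — not
clinical performance on real series, whose noise is richer.

## Problem sizes and numerical choices

- Calibration experiments use 300–500 series with 300–1000 permutations;
  the specificity-inflation experiment uses a 150-eye reference pool, a
  100-eye test cohort, and 60 permutations per series for the modified
  variant. These sizes give binomial standard errors of ~1–2 percentage
  points at α = 0.05.
- Simplex tolerances: 1e-7 on the function spread, 1e-5 on the simplex
  size, 400 iterations; verified against exhaustive grid search at
  (0.05 dB, 0.02 dB/y) resolution.
- Noise-free slope recovery by the binned likelihood is exact only while a
  trajectory stays inside one sensitivity bin; crossing a boundary trades
  slope against the differing per-bin mode offsets (a known artifact of
  piecewise-constant error parameters, worth remembering when interpreting
  per-location slopes near bin edges).
- All randomness flows through explicit seeds (`numpy.random.Generator`);
  identical config + seed reproduces cohorts and p-values exactly.

## Known limitations

- The Weibull parameterization, censoring treatment, sector map, and
  spatial kernel are concrete re-specifications of designs whose original
  parameter files are not public; all are config-swappable.
- The ANSWERS failure rate on synthetic data (5–10% of series) exceeds the
  ~2% reported on real series; the mechanism (unreliable standard errors at
  boundary-pinned optima) is the same, but rates depend on the noise model.
- `md_proxy` is template-relative, not an age-corrected normative MD.
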