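# Methods

This note records the model, the estimator conventions, the calibration of
the synthetic-data generator, and the numerical and design choices made
where the underlying measurement conventions left the design open.

## Model

Each cell's system output over a stimulation window ΔT is

    O_i = (L_i(αF) + λ_i) · (G_i + γ_i) · ΔT

- `L_i` — pathway capacity of cell i at dose αF. The population mean
  follows a Hill curve `L̄(d) = L_basal + (L_max − L_basal)·dʰ/(EC50ʰ + dʰ)`
  (defaults: L_max 8, L_basal 0.1, EC50 2 nM, h 1).
- `λ_i` — fast stochastic fluctuation in pathway operation during the
  experiment (zero-mean Gaussian).
- `G_i` — general gene-expression capacity (A.U./min; default mean 0.014,
  giving a constitutive output of ≈2.5 A.U. over ΔT = 180 min).
- `γ_i` — fast intrinsic expression noise, drawn independently for every
  fluorescence channel (zero-mean Gaussian).

`(L_i, G_i)` relative deviations are a correlated lognormal pair
(capacities must stay positive; nothing in the measured data fixes the
distributional family — this is a modeling decision). The correlation ρ
is imposed exactly by inverting the bivariate-lognormal correlation
formula for the Gaussian-copula correlation. Additive noises are clipped
at zero capacity; parameter sets whose clipped mass would exceed 1e-4
(computed by Gauss–Hermite quadrature) are rejected with an error rather
than silently biased.

Variability is always the normalized variance η²(X) = var(X)/mean(X)²,
with the sample (n−1) variance throughout.

## Estimator conventions

- **O and G are medians** of the inducible and constitutive channels;
  **normalization inside the variance estimators uses the mean**. These
  reflect the measurement definitions of the assay and are deliberately
  different; they must not be conflated.
- **Pathway variability** is the sample variance of the difference of the
  mean-normalized channels. In the model this difference cancels the
  shared expression-capacity factor and estimates η²(P) + η²(γ), with
  η²(P) = η²(L) + η²(λ).
- **Intrinsic noise η²(γ)** is the *full* variance of the normalized
  difference of two identically driven reporters (no factor ½). This
  convention is forced by internal consistency: if each channel carries
  independent intrinsic noise with per-channel relative variance q, the
  twin difference has variance 2q and the dual-reporter difference has
  variance η²(P) + 2q; defining η²(γ) ≡ 2q makes both statements read
  η²(P) + η²(γ) exactly. The halved (per-channel) convention used
  elsewhere in the intrinsic/extrinsic-noise literature is available via
  `intrinsic_noise(..., convention="halved")`.
- `eta2_P_corrected = max(0, pathway_variability − intrinsic_noise)`,
  clipped at zero with a flag rather than reported negative.
- The **correlation term** is the residual of the small-noise identity,
  η²(O) − [η²(P)+η²(γ)] − η²(G) ≈ 2ρ·η(L)·η(G).

## Generator calibration (exact parameter recovery)

In a multiplicative model the estimators pick up exact second-order
terms. With pathway relative variance a, expression-capacity relative
variance v_G, and per-channel intrinsic relative variance q, at ρ = 0:

    E[η²(constitutive)]       = v_G + q
    E[twin difference var]    = 2q(1 + a)
    E[dual difference var]    = a + 2q + a(v_G + q)

The η² fields of `SimulationParams` are therefore treated as
*population-level targets for the estimators*, and the internal variances
(a split proportionally into its L and λ parts, v_G, q) are solved per
dose so that the estimator expectations equal the targets exactly at
ρ = 0. Verified at n = 2·10⁶: recovery errors −0.05% / −0.06% / +0.12%
for pathway variability / expression variability / intrinsic noise. At
ρ ≠ 0 residual cross-terms of order ρ·√(η²(L)η²(G))·η² remain (≈1–2.5%
relative at ρ = ±0.3…0.5).

Two consequences worth knowing:

- The small-noise identity carries a systematic offset −2q = −η²(γ)/(1+a):
  the single inducible channel holds only half of the twin-difference γ
  variance. The identity is exact in expectation (including the
  multiplicative cross-terms, which cancel against the covariance term)
  when η²(γ) = 0; the identity check is run in that regime and a separate
  test asserts the predicted offset when η²(γ) > 0.
- Bootstrap-CI coverage of the estimators is evaluated at ρ = 0, where
  the estimand equals the parameter exactly; at ρ ≠ 0 the known
  cross-term offset would conflate estimator bias with CI calibration.

### λ scaling with dose

`lambda_mode="relative"` keeps the λ contribution to pathway variability
equal to `eta2_lambda` at every dose (convenient for parameter-recovery
studies). `lambda_mode="absolute"` (default) anchors the λ SD at the
saturating capacity, so pathway variability decreases monotonically with
dose while mean output increases — the qualitative dose-response shape
observed for the pheromone system. With absolute noise, low doses where
the clipped mass would exceed 1e-4 are rejected; the dose-response
analyses use doses ≥ 0.6 nM at the default parameters.

### Trajectories and crooked events

Trajectories accumulate inducible signal at rate (L_i + λ_ik)·G_i (fresh
λ per sampling interval) and constitutive signal at rate ∝ G_i, both from
zero at the first timepoint; P(t) is the cumulative ratio (defined 0 at
t₀). A fraction `crooked_frac` of cells receives one *transient*
pathway-rate excursion lasting one sampling interval (× or ÷
`jump_magnitude` with equal probability, at a uniformly chosen interior
interval). The excursion is transient by design: a sustained rate switch
only re-levels the cumulative ratio monotonically and is invisible to any
total-variation statistic, whereas a transient excursion makes P
overshoot and relax — the "jump" signature the crookedness index is meant
to flag. Detection is high but not total: late, downward excursions
relax too little before the end of the recording to cross the 0.3
threshold (the pathway rate cannot drop below zero, bounding downward
excursions).

The ~5% of cells that do not respond to induction in imaging experiments
are modeled by `nonresponder_frac` (capacity pinned at basal, no
stimulation noise); the default is 0 so that snapshot parameter-recovery
conditions are clean.

## Trajectory statistics

- **Progressive spread**: at each timepoint from an onset index (default:
  first timepoint where the median P exceeds 5% of its final value,
  avoiding divide-by-small-number artifacts), per-cell values are divided
  by the population median and the spread is the width of the shortest
  interval containing ⌈n/2⌉ of them. For symmetric distributions this
  "shortest half" converges to the IQR (verified to 0.2% at n = 10⁵
  normal draws); unlike the IQR it remains a robust width for the heavy
  asymmetric tails of mutant populations. **MPS** is the median over
  timepoints, with a percentile bootstrap CI over cells.
  The shortest-half width converges at the cube-root rate and carries a
  systematic small-sample downward bias (≈ −9% at 120 cells, −3% at 600
  at default noise); bootstrap CIs are therefore calibrated against the
  estimator's sampling distribution at the same n, not against the
  large-n limit, and CIs at imaging-scale n should be read with that bias
  in mind.
- **Crookedness index** I_C = 1 − |P(T) − P(0)| / Σ|ΔP|, defined 0 when
  the total variation is zero; 0 for any monotone trajectory, → 1 for a
  trajectory that repeatedly reverses; invariant to positive affine
  rescaling. Cells with I_C > 0.3 are classified crooked, and crooked
  cells are additionally split by whether their final P lies below the
  population mean of final P. Both the PSD/MPS construction and I_C are
  reconstructions of statistics whose defining property (MPS ≈ IQR for
  symmetric distributions; I_C ∈ [0,1], 0 for monotone accumulation,
  threshold 0.3 meaningful) they satisfy exactly; each is isolated behind
  a single function so an alternative definition can be swapped in.

## Screen selection and clustering

Thresholds are empirical tail quantiles (linear interpolation of order
statistics; default tail probability 0.025 per side) of the reference-
replicate distributions for the three screened variables. Criteria are
strict inequalities; boundary equality is not selected. Because the
dual-reporter screen has no twin inducible channel, hit-calling uses the
uncorrected pathway variability (η²(P)+η²(γ)); intrinsic noise is small
and strain-independent at these scales. Confirmation across replicate
re-assays uses a k-of-m vote per criterion (default 2 of 3; the original
screen re-assayed three independent segregants without stating a vote
rule). The k-of-m confirmation is what gives the pipeline its
specificity: with five tail criteria at 2.5% each, single-replicate
calling alone would flag ≈12% of reference-like strains.

Clustering log₁₀-transforms the 10-measurement matrix and median-centers
each row (log base does not affect Pearson distances after centering),
uses 1 − Pearson r between strain rows as the distance and unweighted
average linkage; rows are sorted lexicographically first so merges are
deterministic, and zero-variance rows (correlation undefined) are
excluded with a warning. Flat cuts are configuration-driven (cluster
count or height); signature blocks report higher/lower/≈median with a
dead-band ε (default 0.1 log₁₀ units) and an "any" state when the
within-cluster SD exceeds a dispersion bound (default 1.0).

## Curve comparison

Mean curves average P and η²(P) per dose across replicates. The ABC is
the exact integral of |f − g| over the common P-interval: trapezoidal
integration on the union of breakpoints plus the crossing points of the
linear segments (a signed area would cancel for crossing curves; skipping
the crossing points would under-count). Extrapolation beyond the common
support is never performed.

The resampling test's null hypothesis is that the two strains are the
same. The default resampling unit is the **cell**: per dose, the cells of
all replicates of both strains are pooled; each resample redraws
synthetic replicates of the original sizes with replacement, recomputes
the per-replicate decompositions, rebuilds the two mean curves and their
ABC. The two-sided p-value is
(1 + #{|ABC* − median(ABC*)| ≥ |ABC_obs − median(ABC*)|}) / (N + 1),
never zero. Cell-level resampling is what gives the test resolution:
with three replicates per strain, whole-replicate resampling has so few
distinguishable redraws that ~3% of them reproduce the full group
separation by chance (flooring p near 0.02), and exhaustive label
permutation has only C(6,3) = 20 splits. Both coarser schemes remain
available (`unit="replicates"`, `method="permutation"`). Measured over
200 null simulations the type-I error at α = 0.05 is ≈0.05 with
essentially uniform p-values, and with a 4-fold pathway-variability
difference and three replicates per strain the test rejects at p < 0.01
in ≈100% of simulations.

One quirk of the median-centered two-sided rule: an observed ABC of
exactly 0 (byte-identical inputs) lands in the far lower tail of the null
and yields a *small* p — the rule flags unusual similarity as well as
unusual difference.

## Event statistics

Point estimates use the full sample (SD with n−1, CV = SD/mean); standard
errors are bootstrap SDs over 10⁴ with-replacement resamples (seeded,
bit-reproducible). Permutation tests are two-sided on the absolute
difference of the chosen statistic (mean, SD or CV — the test statistic
matches the table row it annotates) with exhaustive enumeration whenever
C(n_a+n_b, n_a) ≤ 10⁵ (p = #extreme/#total) and Monte-Carlo relabeling
with the +1/(N+1) correction otherwise. Fisher's exact test is two-sided
by the minimum-likelihood convention (sum of hypergeometric probabilities
≤ that of the observed table, with a 1e-7 relative tie tolerance), the
convention of mainstream count-data usage; it is computed by scipy and
checked against a brute-force hypergeometric enumeration in the tests.
Missing timings (cells that never polarized) are excluded per statistic
with excluded counts reported; category comparisons are per-category 2×2
tables against the reference strain, uncorrected by default with
Bonferroni/Benjamini–Hochberg available.

## What the synthetic data do and do not emulate

The generator reproduces the statistical structure the estimators are
built for: multiplicative pathway × expression output, dose-dependent
mean capacity, correlated capacities, channel-independent intrinsic
noise, nonresponder subpopulations, planted screen effects on the mean
and variability axes, and trajectory-level instability events. It does
not model reporter maturation kinetics (handled experimentally by
translation-inhibitor holds in the assays this mirrors), receptor-level
feedback or push–pull mechanisms, spatial signaling-site dynamics,
cytometer measurement noise, or debris/doublet artifacts. Passing tests
therefore demonstrate that the estimators and tests recover the truth
*under the model's assumptions*; with real cytometry data the optional
percentile-trim filter (off by default) and instrument-specific gating
remain the user's responsibility.

## Problem sizes and numerical choices

Simulation-based checks use 10⁵ cells for point recovery, 500 cells ×
100 runs for CI coverage, 2·10⁴ cells × 30 seeds for the identity, 200
null + 100 power simulations (600–1500 resamples each) for the ABC test,
500 simulations for permutation calibration, and a 1,000-strain screen
(3 replicates × 2 doses × 300 cells) for end-to-end hit and cluster
recovery. These sizes give Monte-Carlo error comfortably below each
acceptance band. Ties in UPGMA are broken by the deterministic
lexicographic row order; quantiles everywhere use numpy's linear
interpolation of order statistics; OLS for the rational fit is solved by
least squares on the [1, 1/P] design with a rank check.
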