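# Methods

## The model

`egidrive` models a closed, randomly-mixing population of two true-breeding
genotypes — an engineered-genetic-incompatibility (EGI) line and a wild-type
line — under extreme underdominance: both pure genotypes are fully fit and
every cross-genotype hybrid dies before adulthood. Generations are discrete
and non-overlapping.

With `x` the adult EGI frequency, pairing frequencies in the **propensity
parameterization** are `(cx)^2` for EGI×EGI, `2cx(1−cx)` for the two hybrid
orientations and `(1−cx)^2` for wt×wt, where `c > 0` rescales the effective
EGI frequency in mate pairing. In the **preference parameterization**
(`c = 1`) each pairing is weighted relative to wt×wt by `w1` (EGI×EGI), `w2`
(EGI-female × wt-male) and `w3` (wt-female × EGI-male), normalized by
`z = w1 x² + (w2+w3) x(1−x) + (1−x)²`. The two parameterizations are
alternatives, not composable; `DriveParams` rejects mixing them.

Because hybrids leave no offspring, only the two self-cross terms survive
into the next generation:

```
x' = F (cx)² / (F (cx)² + (1 − cx)²)            propensity form
x' = F w1 x² / (F w1 x² + (1 − x)²)             preference form
```

`F > 0` is EGI fecundity relative to wild-type. The per-generation change
`Δx = x' − x` has fixed points at 0 and 1 (stable) and one interior unstable
equilibrium `x*` — the replacement threshold. In the preference form the
hybrid weights `w2, w3` cancel, so only the product `F·w1` moves the
threshold, with closed form `x* = 1/(1 + F·w1)` when `c = 1`.

Note the propensity pairing terms stop summing to 1 once `c·x > 1`.
`Δx` remains well defined there (it involves only `(cx)²` and `(1−cx)²`),
so the fitter is allowed to explore that region; `mating_probabilities`
emits a warning because the probability reading breaks.

## Threshold location

`find_threshold` scans `Δx` on a regular grid over (0, 1) (default step
1e-3) for negative-to-positive sign changes, including exact zeros at grid
nodes, and refines each bracket by bisection (default interval tolerance
1e-9). Plain bisection was chosen over faster root finders because `Δx` is
cheap and monotone bracketing is unconditionally robust. For `c = 1` the
result is verified in the test suite against the closed form and against an
independent dense-scan oracle. If several crossings exist (possible only
with `c ≠ 1`) the smallest is returned with a warning; if none exists a
`NoThresholdError` is raised rather than a boundary value.

## Fitting the single-generation assay

Each assay replicate contributes one residual `dx_i − Δx(x0_i; θ)`, so
every vial weighs equally regardless of how many replicates share a
starting frequency (replicate counts in the emulated designs differ, 6–7
versus 3). Replicates with zero total offspring have undefined `dx` and are
excluded with a warning.

The optimizer is Gauss-Newton with a central-difference Jacobian (relative
step 1e-6), initialized at the neutral model `(F, c) = (1, 1)`, converging
when the largest parameter step falls below 1e-8 or after 100 iterations.
When the normal equations are ill-conditioned or a step would increase the
sum of squares, a Levenberg-style multiplicative damping term on the
normal-equations diagonal is raised until a descent step is found; accepted
steps therefore never increase the objective, and damped fits are flagged.
Parameter steps that would leave the domain (`F ≤ 0`, `c ≤ 0`) are rejected
the same way.

Standard deviations come from the usual NLS covariance
`(JᵀJ)⁻¹ · SSR/(n − p)` with `n` the number of usable records and `p` the
number of free parameters. `R²` is `1 − SSR/SST` with `SST` about the
observation mean; it can be negative for fits worse than a constant.

The **one-sigma threshold band** displaces *all* free parameters jointly by
`+σ` and by `−σ` and re-solves for the root; parameter covariance is
deliberately ignored. This is a reporting convention, not a calibrated
confidence interval — in practice it behaves like a roughly 68% band, and
the test suite only asserts that behaviour loosely. A displaced parameter
set with no interior root leaves that end of the band open (`None`).

Because `F` and `w1` enter the preference-form dynamics only through their
product, they are not jointly identifiable from assay data; the
`product_Fw1` variant fits the product as one parameter, while
`predict_threshold_from_components` combines `F` and `w1` measured in
independent fecundity and mate-choice experiments.

## Mate-choice statistics

The 4-fly assay (one male and one female of each genotype; the first pair
to mate is recorded) yields a 2×2 count table over female × male genotype.

* `chi_squared_uniform` — Pearson statistic against equal 25% expectation
  in each of the four cells (df = 3). Cell counts are small, so the p-value
  is estimated by Monte-Carlo: `empirical_p_value` simulates uniform
  multinomial tables of the same total and returns the add-one tail
  estimate `(1 + #{sim ≥ obs})/(n_sims + 1)`, which is never zero and has a
  floor of about `1/n_sims` (1e-5 at the default 100 000 simulations).
* `fisher_exact_2x2` — exact conditional test with fixed margins
  (scipy-backed); `greater` tests enrichment of the like-with-like
  diagonal (assortative mating). Two-sided is the default since the
  sidedness convention of published analyses of such tables varies. The
  test suite checks it cell-for-cell against a brute-force hypergeometric
  enumeration in exact rational arithmetic over every table with total ≤ 30.
* `estimate_preferences` — `w1 = n_ee/n_ww`, `w2 = n_ew/n_ww`,
  `w3 = n_we/n_ww`. At frequency ½ — the 4-fly design — these count ratios
  are the multinomial maximum-likelihood estimates of the pairing weights,
  and plugging them back reproduces the observed cell frequencies exactly.
  Undefined when the wt×wt cell is empty; the error suggests explicit
  pseudocounts rather than applying any silently.
* `quadrant_assign` — splits the `(x0, dx)` scatter at `dx = 0` and a
  vertical line (the threshold for drive data, 0.5 for controls).
  Quadrants B (above split, spreading) and C (below split, declining) are
  drive-consistent. Ties are deterministic: `dx = 0` counts as
  non-positive, `x0 = split` counts as right-of-split. A consequence worth
  noting: a noiseless point sitting exactly on the unstable equilibrium has
  `dx = 0` and falls in D.
* `two_proportion_z_test` — pooled-variance z statistic with a two-sided
  normal p; degenerate pooled proportions (0 or 1) return `(0, 1)` with a
  warning.

## Synthetic data

The generators emulate the two published vial layouts: `vial40`
(20 males + 20 females, starting frequencies 5%–95% in 5% steps, default
6 replicates each) and `bottle120` (60 + 60, 10%–90% in 10% steps, default
3 replicates). The default offspring intensity is λ = 3.93 adults per
wild-type female, i.e. the measured 78.6 adults per 20-female wild-type
vial; EGI×EGI pairs scale it by `F`. Founders are allocated per sex by
nearest-integer rounding of the nominal frequency, and fitted models use
the realized (rounded) starting frequency, not the nominal one.

`simulate_assay` gives each female one mating and one brood:

* **Preference mode** (`c = 1`): each female chooses a male genotype with
  probability proportional to (pairing weight × male genotype frequency
  among founders). With neutral weights the expected offspring frequency
  is exactly the deterministic map's prediction; with strong non-neutral
  weights the single-mating constraint makes the generator's expectation
  deviate from the weighted-multinomial pairing model — a deliberate
  piece of realism (a female cannot mate twice), noted here because tests
  of generator/model agreement use neutral or mildly non-neutral weights.
* **Propensity mode** (`c ≠ 1`): each mating's pair type is drawn directly
  from the propensity pairing distribution
  `((cx)², cx(1−cx), cx(1−cx), (1−cx)²)`, which sums to one whenever
  `c·x ≤ 1` (the generator refuses `c·x > 1` as unphysical). Drawing from
  the pairing distribution itself, rather than weighting per-founder mate
  choice, is what makes the generator's expectation agree with the
  propensity-form map for `c ≠ 1` — the property the parameter-recovery
  tests rely on.

Broods are Poisson (`λF` for EGI×EGI, `λ` for wt×wt, 0 for hybrids) and
independent across females, so a vial's offspring counts are Poisson sums.
Zero-offspring vials are retained (exclusion is the fitter's decision).

`simulate_control_assay` emulates the negative control of two interfertile
wild-type lines: all pairings viable at equal fecundity, cross-line brood
labels split Bernoulli(½) per offspring (a neutral codominant line marker),
giving exactly zero expected frequency change. The hybrid-lethal generator
cannot represent this experiment, hence the dedicated function.

`simulate_mate_choice_trial` draws first-mating pairs from the four
pairings with probabilities proportional to `(w1, w2, w3, 1)` — the 4-fly
design at frequency ½. `simulate_discrete_generations` chains single-vial
simulations, reseeding each generation at the realized offspring frequency
with nearest-integer founder allocation, and terminates at fixation, loss,
population extinction (no offspring at all) or a generation cap.

All generators take a seed (or a `numpy.random.Generator`) and are
bit-reproducible for a fixed seed.

### What the generators do not emulate

Remating and sperm storage (paternity is single-sire), egg-to-adult
developmental timing, larval competition and density dependence,
temperature effects on fecundity or incompatibility (temperature is
pass-through metadata), partial hybrid survival, sex-ratio distortion, and
overlapping generations. Tests passing on synthetic data therefore
demonstrate correctness of the estimation machinery under the stated noise
model (multinomial mating + Poisson broods), not robustness to these
real-data features.

## Problem sizes and numerical defaults

Simulation-backed tests use the 40-fly design at its default six replicates
per frequency (114 vials per assay); coverage properties use 200 seeded
fits, and sampling-distribution checks use 30 fits — enough for the
binomial/3σ margins asserted. Monte-Carlo p-values default to 100 000
simulations (floor 1e-5). Root finding uses grid step 1e-3 and bisection
tolerance 1e-9; Jacobians use relative step 1e-6; Gauss-Newton stops at
parameter steps below 1e-8.

## Reporting conventions

Frequencies are fractions in [0, 1] everywhere in the library; the CLI and
examples additionally print nearest-integer percent. Published threshold
percentages mix rounding conventions (two of the printed values are
consistent only with truncation, or with rounding an already-rounded
intermediate), so the library never rounds internally and the acceptance
script reports nearest-integer percent of the full-precision root.

## Known limitations

* The one-sigma threshold band ignores parameter covariance (by design,
  matching the reporting convention it reproduces); for strongly
  correlated `(F, c)` fits it can be too narrow or too wide.
* In `F_and_c` fits the two parameters are nearly collinear on flat
  residual surfaces; the damped fallback keeps the fit stable but the
  individual sigmas are then large and strongly anti-correlated.
* The Monte-Carlo chi-squared null assumes exchangeable trials pooled
  across replicate vials, as in the emulated assay.
* `import_workbook` is a best-effort reader for spreadsheet supplements
  and requires the four count columns to be present under their canonical
  names on some sheet.
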