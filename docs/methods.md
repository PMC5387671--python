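# Methods

`mortens` projects national age-specific mortality and life expectancy with a
performance-weighted ensemble of age–period–cohort models. This note records
the models, the estimation scheme, the synthetic study conditions, and the
numerical and design choices, with their rationale.

## The projection method

For one country and sex, the data are deaths `D[a,y]` and person-years of
exposure `N[a,y]` on an age-group × calendar-year grid. The method has three
stages.

**1. Holdout scoring.** The last `k` calendar years with data (default 13)
are withheld. Every ensemble member is fitted to the remaining years and
projects the withheld period. Each member's *projection bias* is

    bias = mean over withheld years of (observed e0 − median projected e0),

where e0 is life expectancy at birth from the abridged life table of that
year's age-specific rates. The sign is kept: positive bias means
under-projection.

**2. Weighting.** Member `i` receives weight

    w_i = exp(−|bias_i|) / Σ_j exp(−|bias_j|),

so weight decays exponentially in the magnitude of the life-expectancy error
and the weights sum to one. Weights are computed separately per country and
sex.

**3. Pooling.** Members are refitted on all available data. From each
member's posterior-predictive distribution of future age-specific death
rates, a number of draws proportional to its weight (largest-remainder
apportionment of the total, default 5000) is pooled, with per-draw
provenance retained. All reported quantities — life expectancy at birth and
at 65, the probability of dying before 70, threshold-crossing probabilities,
rank distributions across countries, female−male gaps, and age-band
decompositions of the projected gain — are functionals of this pooled draw
set.

## Ensemble members

Every member models log death rates as baseline + period component +
optional cohort component. The default 21-member grid
(`src/mortens/data/ensemble21.yaml`) spans five structural axes:

| axis | levels |
|---|---|
| period structure | common index (`log m = α_a + κ_y`); age-loaded bilinear Lee–Carter (`α_a + β_a κ_y`, Σβ=1); age-group-specific trends (`α_a + κ_{a,y}`) |
| trend extrapolation | linear in time; random walk with drift |
| age smoothing | none; first-difference penalty (τ=20); second-difference penalty (τ=80) |
| cohort effect | none; shrunken smoothed diagonal effects |
| recency weight λ | 1.0, 0.95, 0.90 (observation weight λ^(last−y)) |

The grid is configuration, not code: any YAML file with the same five fields
per member defines an alternative ensemble.

## Estimation

Fitting is a two-stage empirical-Bayes scheme chosen for speed, determinism,
and transparent uncertainty propagation; each fit is closed-form up to a
small alternating-least-squares loop and takes milliseconds.

**Stage 1 — structure.** Empirical log rates `Z = log((D + 0.5)/N)` (the
half-death continuity correction handles zero counts) are decomposed into
baseline `α` (recency-weighted row means), period index/indices (row means,
weighted rank-1 ALS, or per-age series, depending on the structure), and
optionally cohort effects (per-diagonal weighted residual means, shrunk by
one pseudo-observation toward zero and smoothed with a first-difference
penalty along the cohort index, then centred). Age smoothing solves

    argmin_x Σ_a w_a (x_a − v_a)² + τ ‖Δ^d x‖²,

with `w_a` the mean annual death count of group `a` — the precision of a
log-rate estimate is approximately its death count, so abundant ages are
essentially unmoved while sparse ages borrow from neighbours. This is the
MAP analogue of a random-walk smoothing prior against the Poisson
likelihood; an unweighted penalty would distort the baseline schedule where
adjacent ages legitimately differ by orders of magnitude.

**Stage 2 — trend posterior.** The period index gets a conjugate
normal–inverse-χ² posterior. For the random walk with drift, the drift
estimate is the (recency-weighted, gap-normalised) mean annual increment
with variance `c·σ²`, and `σ²` carries `n−1` degrees of freedom from the
increment residuals; registration gaps contribute increments normalised by
their length. For the linear trend, weighted least squares gives the
coefficient posterior with `n−2` degrees of freedom. The posterior
predictive draws σ² from its scaled inverse-χ² marginal, the drift (or
coefficients) from the conditional normal, and then the future path —
cumulated innovations for the random walk, i.i.d. residuals for the linear
trend. α, β, and cohort effects are held at their stage-1 values: with
national-scale exposures their sampling error is negligible next to trend
uncertainty, which the calibration checks below bear out. Future cells
belonging to cohorts never observed take a zero cohort effect (they are
shrunk toward zero anyway when data are thin).

Members whose fit produces non-finite state raise `ModelFitError` and are
dropped before weighting; the remaining weights renormalise.

## Life tables and decomposition

Abridged life tables use the standard actuarial conversion
`q = n·m / (1 + n(1−a)m)` with configurable a-fractions (default 0.1 for age
0, 0.5 elsewhere), radix 1, and a constant-hazard closure `L = l/m` for the
open 85+ interval; a zero open-interval rate with survivors is an error
rather than a silent infinity. `P(die < 70) = 1 − l(70)` is unconditional
from birth. Against a 0.01-year piecewise-constant-hazard integration
oracle, e0 agrees within 1% on random realistic schedules and within 0.5%
of constant-hazard closed forms.

The age decomposition of a life-expectancy change replaces one age group's
rate at a time, recording the change in e0 (stepwise replacement). The
youngest-first and oldest-first orders are averaged, making the
decomposition exactly additive (contributions sum to Δe0 to ~1e−10) and
exactly antisymmetric under swapping the endpoints. Group contributions are
summed into reporting bands 0–29, 30–64, 65+.

## Synthetic study conditions

No mortality database ships with the package; the generator
(`mortens.simulate`) plays the role of the death-registration panel.

* One surface: `log m[a,y] = α_a + β_a κ_y + γ_cohort(a,y)`, κ a random walk
  with drift, γ i.i.d. normal per integer birth cohort
  (`cohort = year − group midpoint`), deaths Poisson with mean `N·m` (a
  negative-binomial switch adds overdispersion; off by default). Defaults:
  the 19-group schedule of a high-income country (infant rate ≈ 6/1000,
  85+ rate ≈ 0.15, e0 ≈ 81 in 1985), β uniform, drift −0.35/yr on κ
  (≈ 1.8%/yr mortality decline), κ innovation sd 0.5, exposure 10⁶
  person-years per group, 30 years from 1985.
* The study panel (`demo_panel`): countries spread deterministically in
  drift (−0.50 to −0.20, spanning fast South-Korea-like to slow gains),
  cohort effects with sd 0.05 (modest 5% log-rate deviations — real
  schedules have cohort structure, and omitting it would make several
  members exactly correct, an unrealistically easy regime), and male
  surfaces with baseline log rates +0.35 and drift 0.10 faster, so women
  live longer while the gap narrows (the converging-sexes regime of
  industrialised countries).

What the generator does *not* emulate: wars and epidemics, registration
artifacts, age misreporting and redistribution, correlated shocks across
countries, and non-Gompertz old-age plateaus. Passing tests therefore
demonstrate internal correctness and calibration under a smooth
Lee–Carter-plus-cohort world, not robustness to real-data pathologies.

## Calibration evidence (computed by the test suite)

* The age-loaded random-walk member's 95% drift interval covers the true
  simulated drift in 19/20 seeded replicates.
* Fitting the common-index member to its own generative form and projecting
  8 years covers the true future e0 at a rate inside [80%, 97%] over 30
  replicates (nominal 90%).
* On ten replicate 6-country × 2-sex panels with a five-member
  axis-spanning mini-ensemble and an 8-year holdout, pooled 90% intervals
  cover withheld life expectancy in ≈96% of country-years (slightly
  conservative: the innovation variance estimate absorbs Poisson noise in
  the extracted index), and the pooled projection's average absolute bias
  beats the post-hoc best single member's in 6/10 replicates.

## Problem sizes and numerical choices

Default problem sizes — 19 age groups, 30-year series, a few hundred draws
per member during validation, 2000–5000 pooled draws — were chosen so the
whole synthetic study runs in seconds; every simulation size in the tests is
stated in the test itself. Other fixed choices: largest-remainder
apportionment with ties broken by member order; pooled draws selected by a
seeded shuffle per member; rank distributions pair draws across countries by
index after a seeded shuffle (countries are treated as independent);
the headline sex gap is the difference of posterior medians, with the paired
per-draw difference reported as a diagnostic; the bias point summary is the
posterior median (switchable to the mean); draws equal to an interval
endpoint count as covered. All stochastic stages take explicit seeds, and
per-unit/per-member child seeds are derived with CRC-stable entropy so
results are reproducible across processes.

## Known limitations

* Stage-1 parameter uncertainty (α, β, cohort effects) is not propagated;
  at small-country exposures this understates spread.
* Cohort effects are frozen at their fitted values during projection, and
  unseen future cohorts get a zero effect.
* The exponential-bias weights use life expectancy at birth only; an
  e65-based variant would weight old-age fit more heavily.
* The 21-member grid is one defensible enumeration of the structural axes,
  not a canonical set; conclusions about between-model variance depend on
  its diversity.
* Coverage on the weighting holdout is mildly optimistic because the same
  withheld years inform the weights.
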