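# mortens

Probabilistic projection of national age-specific mortality and life
expectancy with a **performance-weighted Bayesian model ensemble**.

Single-model mortality forecasts hide the uncertainty that comes from
choosing the model itself: a Lee–Carter extrapolation, an age-specific
trend model, and a cohort model can disagree by years of life expectancy at
a 15-year horizon. `mortens` is for demographers, actuaries, and health
planners who want that model uncertainty inside the interval instead of
swept under it.

## The method

For each country–sex mortality surface (deaths and exposure by age group ×
year):

1. **Holdout scoring** — withhold the last *k* years (default 13), fit each
   of 21 age–period–cohort models on the rest, and score each member's
   *projection bias*: observed minus median-projected life expectancy at
   birth, averaged over the withheld years.
2. **Exponential bias weights** — member *i* gets
   `w_i = exp(−|bias_i|) / Σ_j exp(−|bias_j|)`.
3. **Pooling** — refit on all data, draw from each member's
   posterior-predictive death rates in proportion to `w_i`
   (largest-remainder apportionment), and pool the draws.

Abridged life tables (`q = n·m / (1 + n(1−a)m)`, open-interval closure
`L = l/m`) turn every pooled rate draw into life expectancy at birth (e0)
and at 65 (e65) and the probability of dying before 70 (q70). From the
pooled draws the package computes credible intervals,
threshold-crossing probabilities, country rank distributions, female−male
gaps, between-model variance shares, and an exactly additive
stepwise-replacement decomposition of projected e0 gains into ages 0–29,
30–64, and 65+.

The 21 members vary period structure (common index / Lee–Carter bilinear /
age-specific trends), trend law (linear / random walk with drift), age
smoothing, cohort effects, and recency weighting; the grid lives in
`src/mortens/data/ensemble21.yaml` and can be replaced wholesale. A
synthetic-data module generates Lee–Carter-plus-cohort surfaces with Poisson
counts so the entire pipeline is testable without external data.

## Worked example

```python
import mortens as mt

panel = mt.demo_panel(n_countries=3, n_years=30, seed=2)   # 1985-2014
specs = mt.default_ensemble()                               # 21 members
val = mt.run_validate(panel, specs, holdout=13, draws_per_model=300, seed=2)
res = mt.run_project(panel, specs, val.weight_tables, horizon=16,
                     total_draws=2000, seed=2)
print(res.summary_table(metrics=("e0",), years=[2030]))
```

prints (see `examples/05_model_averaged_projection.py`):

```
   country    sex metric  year    median     lower      upper
country-00 female     e0  2030 99.594749 91.169830 114.812670
country-00   male     e0  2030 97.175164 89.129409 109.384167
country-01 female     e0  2030 91.132878 86.637109  96.799166
country-01   male     e0  2030 85.198070 80.805032  90.884581
country-02 female     e0  2030 88.207965 83.126124  95.892537
country-02   male     e0  2030 87.569843 83.488449  92.466168
```

Each row is the posterior median and 95% equal-tailed interval of projected
life expectancy at birth in 2030, pooled over the weighted ensemble.
`country-00` was generated with the fastest mortality decline, so its
median is highest and its interval widest — trend uncertainty compounds
over the horizon. Follow-ups on the same objects:

```python
from mortens.pooling import prob_exceeds, variance_decomposition
proj = res.projections[("country-00", "female")]
prob_exceeds(proj, "e0", 2030, 90.0)          # 0.99  P(e0 > 90 years)
variance_decomposition(proj, "e0", 2030)      # between/within model shares
```

The `examples/` directory walks through each capability: surface
simulation, life tables, single-member fitting and projection, holdout
weighting, pooled projections with ranks, and age decomposition of gains.
A thin CLI wraps the same pipeline:

```sh
mortens simulate --out panel.csv --countries 4 --years 30 --seed 1
mortens validate --surfaces panel.csv --out val/ --holdout-years 13 --seed 1
mortens project  --surfaces panel.csv --out proj/ --horizon 16 --seed 1
```

Input surfaces are plain CSV: `country,sex,year,age_group,deaths,population`
with age groups `0, 1-4, 5-9, …, 85+`; years absent from the file are
treated as registration gaps, never imputed.

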