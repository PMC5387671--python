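"""Ensemble specification, fitting, and posterior-predictive projection."""
import dataclasses

import numpy as np
import pytest

from mortens import (AgeGroupScheme, MortalitySurface, build_life_table,
                     default_ensemble, fit_ensemble, fit_model,
                     life_expectancy_at, life_expectancy_grid,
                     project_life_expectancy, sample_projection)
from mortens.models import DrawCube, FittedModel, ModelSpec, TrendFit
from mortens.simulate import SurfaceParams, generate_surface

LC_SPEC = ModelSpec(id="lc", period_structure="age_loaded",
                    age_structure="independent", trend="rwd")
COMMON_SPEC = ModelSpec(id="com", period_structure="common",
                        age_structure="independent", trend="rwd")


class TestDefaultEnsemble:
    def test_exactly_twenty_one_distinct_members(self):
        specs = default_ensemble()
        assert len(specs) == 21
        assert len({s.id for s in specs}) == 21

    def test_grid_spans_declared_axes(self):
        specs = default_ensemble()
        assert {s.cohort_effect for s in specs} == {"none", "smoothed"}
        assert {s.age_structure for s in specs} == {"independent", "rw1", "rw2"}
        assert {s.period_structure for s in specs} == {"common", "age_loaded",
                                                       "age_specific"}
        assert len({s.time_weight for s in specs}) >= 2
        assert {s.trend for s in specs} == {"linear", "rwd"}

    def test_invalid_spec_fields_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(id="bad", age_structure="cubic")
        with pytest.raises(ValueError):
            ModelSpec(id="bad", time_weight=0.0)


class TestFitModel:
    def test_short_fit_window_rejected(self):
        surf, _ = generate_surface(SurfaceParams(seed=1, n_years=20))
        with pytest.raises(ValueError, match="need >= 10"):
            fit_model(LC_SPEC, surf, fit_window=(1985, 1990))

    def test_drift_recovery_smoke(self):
        """The matching Lee–Carter member recovers the simulated drift."""
        hits = 0
        for seed in range(5):
            surf, truth = generate_surface(SurfaceParams(seed=seed))
            fm = fit_model(LC_SPEC, surf)
            lo, hi = fm.drift_interval(0.95)
            hits += lo <= truth.params.kappa_drift <= hi
        assert hits >= 4

    def test_recency_weighting_tracks_trend_break(self):
        """After a late trend break, a recency-weighted member projects the
        first future year closer to the post-break trend."""
        scheme = AgeGroupScheme()
        years = 30
        alpha = np.asarray(SurfaceParams().alpha)
        # drift -0.02/yr on log rates for 24 years, then -0.06/yr for 6
        t = np.arange(years)
        kappa = np.where(t < 24, -0.02 * t, -0.02 * 24 - 0.06 * (t - 24))
        log_m = alpha[:, None] + kappa[None, :]
        pop = np.full((19, years), 1e7)
        deaths = pop * np.exp(log_m)   # expected counts, no sampling noise
        surf = MortalitySurface(country="b", sex="female", first_year=1985,
                                deaths=deaths, population=pop, scheme=scheme)
        post_break = np.exp(log_m[:, -1] - 0.06)  # post-break extension
        spec_eq = dataclasses.replace(COMMON_SPEC, id="eq", time_weight=1.0)
        spec_rec = dataclasses.replace(COMMON_SPEC, id="rec", time_weight=0.5)
        f_eq = fit_model(spec_eq, surf).point_forecast(1)[:, 0]
        f_rec = fit_model(spec_rec, surf).point_forecast(1)[:, 0]
        err_eq = np.abs(np.log(f_eq) - np.log(post_break)).mean()
        err_rec = np.abs(np.log(f_rec) - np.log(post_break)).mean()
        assert err_rec < err_eq

    def test_scaling_deaths_and_population_near_invariant(self):
        """Multiplying deaths and exposure by the same constant leaves the
        fit essentially unchanged; the small continuity-correction effect
        shrinks log rates toward the truth as counts grow (alpha decreases)."""
        surf, _ = generate_surface(SurfaceParams(seed=8))
        scaled = MortalitySurface(
            country=surf.country, sex=surf.sex, first_year=surf.first_year,
            deaths=surf.deaths * 10, population=surf.population * 10,
            scheme=surf.scheme)
        a1 = fit_model(LC_SPEC, surf).alpha
        a2 = fit_model(LC_SPEC, scaled).alpha
        assert np.max(np.abs(a1 - a2)) < 5e-3
        assert np.all(a2 <= a1 + 1e-12)

    def test_missing_years_inside_window_tolerated(self):
        surf, _ = generate_surface(
            SurfaceParams(seed=3, missing_years=(1995, 1996)))
        fm = fit_model(LC_SPEC, surf)
        assert 1995 not in fm.fit_years and len(fm.fit_years) == 28

    def test_fit_ensemble_fits_all_members(self):
        surf, _ = generate_surface(SurfaceParams(seed=2))
        fitted = fit_ensemble(default_ensemble(), surf)
        assert len(fitted) == 21


def _degenerate_model(drift=-0.3):
    scheme = AgeGroupScheme()
    alpha = np.asarray(SurfaceParams().alpha)
    trend = TrendFit(kind="rwd", level=0.0, last_year=2014, sigma2=0.0, df=5,
                     drift=drift, drift_var_unit=0.01)
    return FittedModel(spec=COMMON_SPEC, country="d", sex="female",
                       scheme=scheme, fit_years=np.arange(1985, 2015),
                       alpha=alpha, beta=np.ones(19), trend=trend,
                       last_year=2014)


class TestSampleProjection:
    def test_zero_variance_draws_follow_point_trend(self):
        fm = _degenerate_model()
        cube = sample_projection(fm, horizon=5, n_draws=20, seed=0)
        assert np.all(cube.draws == cube.draws[:1])
        np.testing.assert_allclose(cube.draws[0], fm.point_forecast(5))

    def test_single_draw_allowed(self):
        surf, _ = generate_surface(SurfaceParams(seed=1))
        cube = sample_projection(fit_model(LC_SPEC, surf), 3, 1, seed=2)
        assert cube.n_draws == 1 and cube.draws.shape == (1, 19, 3)

    def test_same_seed_identical_cubes(self):
        surf, _ = generate_surface(SurfaceParams(seed=1))
        fm = fit_model(LC_SPEC, surf)
        c1 = sample_projection(fm, 5, 50, seed=7)
        c2 = sample_projection(fm, 5, 50, seed=7)
        np.testing.assert_array_equal(c1.draws, c2.draws)

    def test_zero_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            sample_projection(_degenerate_model(), 0, 10, seed=0)

    def test_interval_width_grows_with_horizon_for_rwd(self):
        """Predictive uncertainty accumulates along a random-walk path."""
        for seed in range(10):
            surf, _ = generate_surface(SurfaceParams(seed=100 + seed))
            fm = fit_model(COMMON_SPEC, surf)
            cube = sample_projection(fm, 15, 2000, seed=seed)
            lo, hi = np.quantile(np.log(cube.draws), [0.05, 0.95], axis=0)
            width = np.median(hi - lo, axis=0)   # median over ages, per year
            # allow Monte-Carlo jitter in the empirical quantiles
            assert np.all(np.diff(width) > -0.01)

    def test_cube_validation(self):
        with pytest.raises(ValueError, match="positive"):
            DrawCube(model_id="x", draws=np.zeros((2, 3, 1)),
                     years=np.array([2020]))


class TestProjectLifeExpectancy:
    def test_identical_draws_give_equal_life_expectancy(self):
        cube = sample_projection(_degenerate_model(), 4, 10, seed=0)
        e = project_life_expectancy(cube, AgeGroupScheme())
        assert np.all(e == e[:1])

    def test_halving_rates_raises_life_expectancy_everywhere(self):
        surf, _ = generate_surface(SurfaceParams(seed=4))
        cube = sample_projection(fit_model(LC_SPEC, surf), 4, 30, seed=1)
        halved = DrawCube(model_id="h", draws=cube.draws / 2, years=cube.years)
        e1 = project_life_expectancy(cube, AgeGroupScheme())
        e2 = project_life_expectancy(halved, AgeGroupScheme())
        assert np.all(e2 > e1)

    def test_single_draw_matches_direct_life_table(self):
        cube = sample_projection(_degenerate_model(), 3, 1, seed=5)
        e = project_life_expectancy(cube, AgeGroupScheme())
        lt = build_life_table(cube.draws[0, :, 1], AgeGroupScheme())
        assert e[0, 1] == pytest.approx(life_expectancy_at(lt, 0))


def test_posterior_predictive_calibration_on_own_generative_form():
    """Fitting the common-index random-walk member to data simulated from
    that same process covers the true future life expectancy close to the
    nominal 90% rate."""
    hits, total = 0, 0
    for rep in range(30):
        p = SurfaceParams(seed=500 + rep, n_years=30,
                          beta=(1.0 / 19,) * 19)
        surf, truth = generate_surface(p)
        train = surf.restrict(1985, 2006)
        fm = fit_model(COMMON_SPEC, train)
        cube = sample_projection(fm, 8, 300, seed=rep)
        e_draws = project_life_expectancy(cube, surf.scheme)
        true_e0 = truth.e0(2014)
        lo, hi = np.quantile(e_draws[:, -1], [0.05, 0.95])
        hits += lo <= true_e0 <= hi
        total += 1
    assert 0.80 <= hits / total <= 0.97
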