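"""Draw allocation, pooling, and posterior summaries of the averaged model."""
import numpy as np
import pytest

from mortens import (AgeGroupScheme, allocate_draws, change_distribution,
                     compute_weights, pool, prob_exceeds, rank_distribution,
                     sex_gap, summarize, variance_decomposition)
from mortens.models import DrawCube
from mortens.pooling import BMAProjection

SCHEME = AgeGroupScheme()
YEARS = np.array([2020, 2021])


def _cube(model_id, shift=0.0, n=100, seed=0, sd=0.05):
    rng = np.random.default_rng(seed)
    base = np.full((n, 19, 2), 0.02)
    noise = np.exp(sd * rng.standard_normal((n, 1, 1)) + shift)
    return DrawCube(model_id=model_id, draws=base * noise, years=YEARS)


class TestAllocateDraws:
    def test_equal_weights_split_exactly(self):
        counts = allocate_draws(np.full(21, 1 / 21), 21000)
        assert np.all(counts == 1000)

    def test_degenerate_weight_takes_all(self):
        np.testing.assert_array_equal(allocate_draws([1.0, 0.0], 500), [500, 0])

    def test_largest_remainder_hand_case(self):
        np.testing.assert_array_equal(
            allocate_draws([0.5, 0.3, 0.2], 10), [5, 3, 2])

    def test_quota_property_random_weights(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            w = rng.dirichlet(np.ones(rng.integers(2, 25)))
            total = int(rng.integers(1, 5000))
            counts = allocate_draws(w, total)
            assert counts.sum() == total
            assert np.all(np.abs(counts - total * w) < 1.0)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            allocate_draws([1.0], 0)


class TestPool:
    def test_single_model_identity(self):
        cube = _cube("only", n=50)
        proj = pool([cube], [50], seed=1, scheme=SCHEME)
        assert proj.n_draws == 50
        np.testing.assert_allclose(np.sort(proj.rates, axis=0),
                                   np.sort(cube.draws, axis=0))
        assert set(proj.provenance) == {"only"}

    def test_zero_allocation_excludes_model(self):
        proj = pool([_cube("a"), _cube("b", seed=1)], [0, 60], seed=0,
                    scheme=SCHEME)
        assert set(proj.provenance) == {"b"} and proj.n_draws == 60

    def test_identical_distributions_pool_to_same_mean(self):
        c1, c2 = _cube("a", n=4000, seed=1), _cube("b", n=4000, seed=2)
        proj = pool([c1, c2], [2000, 2000], seed=3, scheme=SCHEME)
        pooled_mean = proj.rates.mean()
        assert pooled_mean == pytest.approx(c1.draws.mean(), rel=5e-3)

    def test_overallocation_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pool([_cube("a", n=10)], [20], seed=0, scheme=SCHEME)

    def test_deterministic_given_seed(self):
        cubes = [_cube("a", n=80, seed=1), _cube("b", n=80, seed=2)]
        p1 = pool(cubes, [40, 40], seed=9, scheme=SCHEME)
        p2 = pool(cubes, [40, 40], seed=9, scheme=SCHEME)
        np.testing.assert_array_equal(p1.rates, p2.rates)


class TestSummaries:
    def test_point_mass_zero_width_interval(self):
        proj = pool([_cube("a", sd=0.0, n=30)], [30], seed=0, scheme=SCHEME)
        s = summarize(proj, "e0", 2020)
        assert s["lower"] == pytest.approx(s["upper"]) == pytest.approx(s["median"])

    def test_median_of_three_values(self):
        rates = np.full((3, 19, 1), 0.02)
        rates[0] *= 0.9
        rates[2] *= 1.1
        proj = BMAProjection(country="x", sex="f", scheme=SCHEME,
                             years=np.array([2030]), rates=rates,
                             provenance=np.array(["m"] * 3))
        e = np.sort(proj.metric_draws("e0", 2030))
        assert summarize(proj, "e0", 2030)["median"] == pytest.approx(e[1])

    def test_wide_interval_quantiles(self):
        rng = np.random.default_rng(1)
        rates = 0.02 * np.exp(0.01 * rng.standard_normal((10_000, 19, 1)))
        proj = BMAProjection(country="x", sex="f", scheme=SCHEME,
                             years=np.array([2030]), rates=rates,
                             provenance=np.array(["m"] * 10_000))
        draws = proj.metric_draws("e0", 2030)
        s = summarize(proj, "e0", 2030, level=0.95)
        assert s["lower"] == pytest.approx(np.quantile(draws, 0.025), abs=0.01)
        assert s["upper"] == pytest.approx(np.quantile(draws, 0.975), abs=0.01)

    def test_unknown_metric_rejected(self):
        proj = pool([_cube("a")], [10], seed=0, scheme=SCHEME)
        with pytest.raises(ValueError, match="metric"):
            summarize(proj, "e99", 2020)

    def test_prob_exceeds_edges_and_quantile(self):
        proj = pool([_cube("a", n=2000, seed=4)], [2000], seed=0, scheme=SCHEME)
        draws = proj.metric_draws("e0", 2020)
        assert prob_exceeds(proj, "e0", 2020, draws.min() - 1) == 1.0
        med = float(np.median(draws))
        assert prob_exceeds(proj, "e0", 2020, med) == pytest.approx(0.5, abs=0.02)
        q90 = float(np.quantile(draws, 0.9))
        assert prob_exceeds(proj, "e0", 2020, q90) == pytest.approx(0.10, abs=0.02)


class TestChangeDistribution:
    def test_identical_years_no_change(self):
        rates = np.broadcast_to(np.full(19, 0.02), (40, 2, 19))
        proj = BMAProjection(country="x", sex="f", scheme=SCHEME, years=YEARS,
                             rates=np.moveaxis(rates, 1, 2).copy(),
                             provenance=np.array(["m"] * 40))
        ch = change_distribution(proj, "e0", 2020, 2021)
        assert np.all(ch["draws"] == 0.0) and ch["prob_increase"] == 0.0

    def test_lower_rates_mean_certain_increase(self):
        rng = np.random.default_rng(2)
        r2020 = 0.02 * np.exp(0.02 * rng.standard_normal((50, 19)))
        rates = np.stack([r2020, r2020 * 0.8], axis=2)  # (n, 19, 2)
        proj = BMAProjection(country="x", sex="f", scheme=SCHEME, years=YEARS,
                             rates=rates, provenance=np.array(["m"] * 50))
        ch = change_distribution(proj, "e0", 2020, 2021)
        assert ch["prob_increase"] == 1.0

    def test_single_draw_point_change(self):
        rates = np.stack([np.full((1, 19), 0.02), np.full((1, 19), 0.01)], axis=2)
        proj = BMAProjection(country="x", sex="f", scheme=SCHEME, years=YEARS,
                             rates=rates, provenance=np.array(["m"]))
        ch = change_distribution(proj, "e0", 2020, 2021)
        assert len(ch["draws"]) == 1 and ch["median"] == pytest.approx(ch["draws"][0])

    def test_observed_baseline_year_carried(self):
        proj = pool([_cube("a", n=30)], [30], seed=0, scheme=SCHEME,
                    observed_rates={2010: np.full(19, 0.03)})
        ch = change_distribution(proj, "e0", 2010, 2021)
        assert np.all(ch["draws"] != 0)
        with pytest.raises(ValueError, match="not in projection"):
            change_distribution(proj, "e0", 1999, 2021)


class TestRankDistribution:
    def test_single_country_rank_one(self):
        proj = pool([_cube("a")], [50], seed=0, scheme=SCHEME)
        mat = rank_distribution([proj], "e0", 2020)
        assert mat.shape == (1, 1) and mat[0, 0] == 1.0

    def test_disjoint_supports_deterministic_ranks(self):
        hi = pool([_cube("a", shift=-0.5, n=200)], [200], seed=0, scheme=SCHEME)
        lo = pool([_cube("b", shift=+0.5, n=200, seed=5)], [200], seed=1,
                  scheme=SCHEME)
        mat = rank_distribution([hi, lo], "e0", 2020, seed=2)
        np.testing.assert_array_equal(mat, [[1.0, 0.0], [0.0, 1.0]])

    def test_exchangeable_countries_near_uniform_ranks(self):
        projs = [pool([_cube(f"m{i}", n=10_000, seed=i)], [10_000], seed=i,
                      scheme=SCHEME) for i in range(3)]
        mat = rank_distribution(projs, "e0", 2020, seed=7)
        np.testing.assert_allclose(mat, np.full((3, 3), 1 / 3), atol=0.02)
        np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)


class TestSexGap:
    def test_identical_projections_zero_gap(self):
        f = pool([_cube("a", n=100, seed=3)], [100], seed=0, scheme=SCHEME)
        m = pool([_cube("a", n=100, seed=3)], [100], seed=0, scheme=SCHEME)
        assert sex_gap(f, m, 2020)["gap_of_medians"] == pytest.approx(0.0)

    def test_shifted_draws_show_up_in_gap(self):
        f = pool([_cube("a", n=300, seed=1, sd=0.0, shift=-0.3)], [300], seed=0,
                 scheme=SCHEME)
        m = pool([_cube("b", n=300, seed=2, sd=0.0)], [300], seed=0,
                 scheme=SCHEME)
        g = sex_gap(f, m, 2020)
        assert g["gap_of_medians"] > 0
        assert g["gap_of_medians"] == pytest.approx(g["paired_median"], abs=1e-9)


class TestVarianceDecomposition:
    def test_identical_model_distributions_no_between_share(self):
        cubes = [_cube("a", n=4000, seed=1), _cube("b", n=4000, seed=2)]
        proj = pool(cubes, [3000, 3000], seed=0, scheme=SCHEME)
        vd = variance_decomposition(proj, "e0", 2020)
        assert vd["between_share"] < 0.01

    def test_distinct_constants_all_between(self):
        cubes = [_cube("a", sd=0.0, shift=0.0), _cube("b", sd=0.0, shift=-0.2)]
        proj = pool(cubes, [50, 50], seed=0, scheme=SCHEME)
        vd = variance_decomposition(proj, "e0", 2020)
        assert vd["between_share"] == pytest.approx(1.0)
        assert vd["within_share"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_total_variance_split(self):
        """Two equal-count models, means 0 and 2, unit within-variance:
        between = within = 1, shares 0.5/0.5."""
        draws = np.concatenate([
            np.tile([-1.0, 1.0], 50),          # mean 0, var 1
            np.tile([1.0, 3.0], 50),           # mean 2, var 1
        ])
        labels = np.array(["a"] * 100 + ["b"] * 100)
        proj = BMAProjection(country="x", sex="f", scheme=SCHEME,
                             years=np.array([2030]),
                             rates=np.full((200, 19, 1), 0.02),
                             provenance=labels)
        proj._metric_cache[("e0", 2030)] = draws
        vd = variance_decomposition(proj, "e0", 2030)
        assert vd["between"] == pytest.approx(1.0)
        assert vd["within"] == pytest.approx(1.0)
        assert vd["between_share"] == pytest.approx(0.5)

    def test_degenerate_flagged(self):
        cubes = [_cube("a", sd=0.0), _cube("b", sd=0.0)]
        proj = pool(cubes, [50, 50], seed=0, scheme=SCHEME)
        vd = variance_decomposition(proj, "e0", 2020)
        assert vd["degenerate"] and np.isnan(vd["between_share"])

    def test_single_model_rejected(self):
        proj = pool([_cube("a")], [50], seed=0, scheme=SCHEME)
        with pytest.raises(ValueError):
            variance_decomposition(proj, "e0", 2020)
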