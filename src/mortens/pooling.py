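"""Pooling per-model posterior draws into the model-averaged projection.

Draw counts per member are the largest-remainder apportionment of the total
by the member weights, so each member contributes a number of draws
proportional to its weight.  The pooled draw cube carries per-draw
provenance (source model id), which supports the law-of-total-variance
decomposition into between-model and within-model components.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lifetable import life_expectancy_grid, prob_death_before_grid
from .models import DrawCube
from .surfaces import AgeGroupScheme

__all__ = [
    "BMAProjection",
    "allocate_draws",
    "pool",
    "summarize",
    "prob_exceeds",
    "change_distribution",
    "rank_distribution",
    "sex_gap",
    "variance_decomposition",
]

METRICS = ("e0", "e65", "q70")


def allocate_draws(weights, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` draws by weight.

    Accepts a weight vector or a :class:`~mortens.validation.WeightTable`.
    Guarantees Σ counts = total and |count_i − total·w_i| < 1.
    """
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if total <= 0:
        raise ValueError("total draw count must be positive")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    quota = total * w
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        frac = quota - counts
        # ties broken by model order for determinism
        order = np.lexsort((np.arange(len(w)), -frac))
        counts[order[:short]] += 1
    return counts


@dataclass
class BMAProjection:
    """Pooled posterior draws of death rates with per-draw provenance."""

    country: str
    sex: str
    scheme: AgeGroupScheme
    years: np.ndarray               # projection calendar years
    rates: np.ndarray               # (n_total, n_groups, horizon)
    provenance: np.ndarray          # (n_total,) source model ids
    observed_rates: dict = field(default_factory=dict)  # year -> (n_groups,)
    _metric_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.years = np.asarray(self.years)
        self.rates = np.asarray(self.rates, dtype=float)
        self.provenance = np.asarray(self.provenance)
        if self.rates.shape[0] != len(self.provenance):
            raise ValueError("provenance must label every pooled draw")

    @property
    def n_draws(self) -> int:
        return self.rates.shape[0]

    def _rates_at(self, year: int) -> np.ndarray:
        idx = np.flatnonzero(self.years == year)
        if len(idx):
            return np.moveaxis(self.rates, 1, 2)[:, idx[0], :]  # (n, A)
        if int(year) in self.observed_rates:
            obs = self.observed_rates[int(year)]
            return np.broadcast_to(obs, (self.n_draws, len(obs)))
        raise ValueError(f"year {year} not in projection range or carried observations")

    def metric_draws(self, metric: str, year: int) -> np.ndarray:
        """Per-draw life-table summary (e0 | e65 | q70) for one year."""
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
        key = (metric, int(year))
        if key not in self._metric_cache:
            rates = self._rates_at(year)
            if metric == "e0":
                vals = life_expectancy_grid(rates, self.scheme, at_age=0)
            elif metric == "e65":
                vals = life_expectancy_grid(rates, self.scheme, at_age=65)
            else:
                vals = prob_death_before_grid(rates, self.scheme, age=70)
            self._metric_cache[key] = vals
        return self._metric_cache[key]


def pool(cubes, counts, seed: int = 0, country: str = "", sex: str = "",
         scheme: AgeGroupScheme = None, observed_rates: dict = None) -> BMAProjection:
    """Concatenate a seeded random subset of draws from each member's cube.

    ``counts[i]`` draws are taken from ``cubes[i]`` after a seeded shuffle of
    its draw indices; deterministic given the seed.
    """
    counts = np.asarray(counts, dtype=int)
    if len(counts) != len(cubes):
        raise ValueError("one count per cube required")
    years = cubes[0].years
    for c in cubes:
        if not np.array_equal(c.years, years):
            raise ValueError("all cubes must share projection years")
        if c.draws.shape[1:] != cubes[0].draws.shape[1:]:
            raise ValueError("all cubes must share age groups and horizon")
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for cube, k in zip(cubes, counts):
        if k == 0:
            continue
        if k > cube.n_draws:
            raise ValueError(
                f"allocation {k} exceeds available draws ({cube.n_draws}) "
                f"for model {cube.model_id}"
            )
        idx = rng.permutation(cube.n_draws)[:k]
        parts.append(cube.draws[idx])
        labels.extend([cube.model_id] * int(k))
    if not parts:
        raise ValueError("no draws allocated")
    return BMAProjection(
        country=country, sex=sex,
        scheme=scheme or AgeGroupScheme(), years=years,
        rates=np.concatenate(parts, axis=0), provenance=np.array(labels),
        observed_rates=dict(observed_rates or {}),
    )


def summarize(proj: BMAProjection, metric: str, year: int,
              level: float = 0.95) -> dict:
    """Median and equal-tailed credible interval of a metric in one year."""
    draws = proj.metric_draws(metric, year)
    lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
    return {
        "metric": metric, "year": int(year), "median": float(np.median(draws)),
        "lower": float(lo), "upper": float(hi), "level": level, "draws": draws,
    }


def prob_exceeds(proj: BMAProjection, metric: str, year: int,
                 threshold: float) -> float:
    """Posterior probability the metric exceeds ``threshold`` in ``year``."""
    draws = proj.metric_draws(metric, year)
    return float(np.mean(draws > threshold))


def change_distribution(proj: BMAProjection, metric: str, year_from: int,
                        year_to: int) -> dict:
    """Per-draw change metric(year_to) − metric(year_from) and P(increase)."""
    d_from = proj.metric_draws(metric, year_from)
    d_to = proj.metric_draws(metric, year_to)
    change = d_to - d_from
    return {
        "metric": metric, "year_from": int(year_from), "year_to": int(year_to),
        "draws": change, "median": float(np.median(change)),
        "prob_increase": float(np.mean(change > 0)),
    }


def rank_distribution(projections, metric: str, year: int,
                      seed: int = 0) -> np.ndarray:
    """P(country c holds rank r), rank 1 = highest metric value.

    Draws are treated as independent across countries: each country's draw
    vector is shuffled with a seeded generator, truncated to the common
    count, and ranks computed draw-wise.  Rows (countries) and columns
    (ranks) each sum to 1.
    """
    rng = np.random.default_rng(seed)
    vecs = [p.metric_draws(metric, year) for p in projections]
    n = min(len(v) for v in vecs)
    mat = np.stack([rng.permutation(v)[:n] for v in vecs])  # (C, n)
    C = len(vecs)
    order = np.argsort(-mat, axis=0, kind="stable")          # (C, n): country at each rank
    probs = np.zeros((C, C))
    for r in range(C):
        cnt = np.bincount(order[r], minlength=C)
        probs[:, r] = cnt / n
    return probs


def sex_gap(proj_female: BMAProjection, proj_male: BMAProjection, year: int,
            metric: str = "e0") -> dict:
    """Female−male gap: difference of posterior medians (headline) plus the
    per-draw paired difference as a diagnostic."""
    f = proj_female.metric_draws(metric, year)
    m = proj_male.metric_draws(metric, year)
    n = min(len(f), len(m))
    paired = f[:n] - m[:n]
    return {
        "year": int(year), "metric": metric,
        "gap_of_medians": float(np.median(f) - np.median(m)),
        "paired_median": float(np.median(paired)),
        "paired_draws": paired,
    }


def variance_decomposition(proj: BMAProjection, metric: str, year: int) -> dict:
    """Between-model vs within-model variance shares (law of total variance).

    Groups pooled draws by source model; weights are the pooled draw counts.
    Shares sum to 1 when total variance is positive; a zero total variance is
    flagged with NaN shares.
    """
    draws = proj.metric_draws(metric, year)
    labels = proj.provenance
    models = [m for m in dict.fromkeys(labels)]
    if len(models) < 2:
        raise ValueError("need draws from at least 2 models")
    means, variances, ws = [], [], []
    if len(draws) < 2:
        raise ValueError("need at least 2 pooled draws")
    for m in models:
        sub = draws[labels == m]
        means.append(sub.mean())
        variances.append(sub.var(ddof=0))
        ws.append(len(sub) / len(draws))
    means, variances, ws = map(np.asarray, (means, variances, ws))
    grand = np.sum(ws * means)
    between = float(np.sum(ws * (means - grand) ** 2))
    within = float(np.sum(ws * variances))
    total = between + within
    if total <= 0:
        return {"between_share": np.nan, "within_share": np.nan,
                "between": between, "within": within, "degenerate": True}
    return {"between_share": between / total, "within_share": within / total,
            "between": between, "within": within, "degenerate": False}
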