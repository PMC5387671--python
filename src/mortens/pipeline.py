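"""End-to-end orchestration: holdout validation and pooled projections.

``run_validate`` implements the weighting protocol: withhold the last k
years per country–sex, fit every ensemble member on the remainder, score
members by life-expectancy projection bias, convert biases to exponential
weights, and report the pooled (model-averaged) bias and interval coverage
on the withheld years.  ``run_project`` refits members on all available
data, samples draws per member in proportion to its weight, and pools them
into the final projection object per country–sex.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import life_expectancy_grid
from .models import (ModelFitError, fit_model, project_life_expectancy,
                     sample_projection)
from .pooling import BMAProjection, allocate_draws, pool
from .surfaces import MortalitySurface
from .validation import (WeightTable, average_absolute_bias, compute_weights,
                         coverage, holdout_split, projection_bias)

__all__ = ["ValidationResult", "ProjectionResult", "run_validate", "run_project"]


def _child_seed(seed: int, *keys) -> int:
    # crc32 rather than hash(): stable across processes
    import zlib
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _observed_e0(surface: MortalitySurface) -> np.ndarray:
    rates = surface.rates()[:, surface.observed]
    return life_expectancy_grid(rates.T, surface.scheme)


@dataclass
class ValidationResult:
    weight_tables: dict                 # (country, sex) -> WeightTable
    model_bias: pd.DataFrame            # long table country/sex/model_id/bias/weight
    bma_bias: dict                      # (country, sex) -> years
    bma_coverage: dict                  # (country, sex) -> proportion
    holdout_years: int
    level: float

    def summary(self) -> dict:
        """Panel-level validation summary (the headline validation numbers)."""
        units = list(self.bma_bias)
        bma_avg = average_absolute_bias(self.bma_bias)
        per_model = self.model_bias.groupby("model_id")["bias"] \
            .apply(lambda b: float(np.mean(np.abs(b))))
        best_model = per_model.idxmin()
        return {
            "n_units": len(units),
            "bma_avg_abs_bias": bma_avg,
            "best_model_id": best_model,
            "best_model_avg_abs_bias": float(per_model.min()),
            "mean_coverage": float(np.mean(list(self.bma_coverage.values()))),
            "level": self.level,
        }


def run_validate(surfaces, specs, holdout: int = 13, draws_per_model: int = 200,
                 seed: int = 0, level: float = 0.90,
                 point: str = "median") -> ValidationResult:
    """Holdout evaluation of every member on every surface.

    ``surfaces`` is an iterable of :class:`MortalitySurface` (one per
    country–sex).  Non-convergent members are dropped from that unit's
    weight table with a warning.
    """
    weight_tables, bma_bias, bma_cov = {}, {}, {}
    rows = []
    for surface in surfaces:
        unit = (surface.country, surface.sex)
        train, withheld = holdout_split(surface, holdout)
        wh_years = withheld.observed_years
        horizon = int(wh_years[-1]) - train.last_year
        obs_e0 = _observed_e0(withheld)
        cubes, biases, ids = [], [], []
        for spec in specs:
            try:
                fm = fit_model(spec, train)
            except ModelFitError:
                import warnings
                warnings.warn(f"model {spec.id} excluded for {unit}", stacklevel=2)
                continue
            cube = sample_projection(fm, horizon, draws_per_model,
                                     seed=_child_seed(seed, *unit, spec.id))
            e_draws = project_life_expectancy(cube, surface.scheme)
            cols = [cube.year_index(y) for y in wh_years]
            e_draws = e_draws[:, cols]
            biases.append(projection_bias(obs_e0, e_draws, point=point))
            ids.append(spec.id)
            cubes.append((cube, e_draws))
        wt = compute_weights(biases, model_ids=ids, country=surface.country,
                             sex=surface.sex,
                             holdout_years=(int(wh_years[0]), int(wh_years[-1])))
        weight_tables[unit] = wt
        rows.extend(zip([surface.country] * len(ids), [surface.sex] * len(ids),
                        ids, wt.biases, wt.weights))
        counts = allocate_draws(wt, draws_per_model)
        pooled_e = np.concatenate([
            ed[np.random.default_rng(_child_seed(seed, *unit, "pool", mid))
               .permutation(ed.shape[0])[:k]]
            for (cube, ed), k, mid in zip(cubes, counts, ids) if k > 0
        ], axis=0)
        bma_bias[unit] = projection_bias(obs_e0, pooled_e, point=point)
        bma_cov[unit] = coverage(pooled_e, obs_e0, level=level)
    model_bias = pd.DataFrame(
        rows, columns=["country", "sex", "model_id", "bias", "weight"])
    return ValidationResult(weight_tables=weight_tables, model_bias=model_bias,
                            bma_bias=bma_bias, bma_coverage=bma_cov,
                            holdout_years=holdout, level=level)


@dataclass
class ProjectionResult:
    projections: dict                   # (country, sex) -> BMAProjection
    horizon: int
    total_draws: int

    def summary_table(self, metrics=("e0", "e65", "q70"), years=None,
                      level: float = 0.95) -> pd.DataFrame:
        from .pooling import summarize
        rows = []
        for (country, sex), proj in self.projections.items():
            yrs = years if years is not None else [int(proj.years[-1])]
            for metric in metrics:
                for year in yrs:
                    s = summarize(proj, metric, year, level=level)
                    rows.append((country, sex, metric, int(year), s["median"],
                                 s["lower"], s["upper"]))
        return pd.DataFrame(rows, columns=["country", "sex", "metric", "year",
                                           "median", "lower", "upper"])


def run_project(surfaces, specs, weight_tables, horizon: int = 20,
                total_draws: int = 5000, seed: int = 0) -> ProjectionResult:
    """Final projections: refit on all data, pool draws by weight.

    ``weight_tables`` maps (country, sex) to a :class:`WeightTable` (for
    example from :func:`run_validate`).  Members absent from a unit's weight
    table (for example dropped during validation) are skipped for that unit.
    The last observed year's rates are carried on each projection object so
    change distributions can be anchored at an observed year.
    """
    projections = {}
    spec_by_id = {s.id: s for s in specs}
    for surface in surfaces:
        unit = (surface.country, surface.sex)
        wt: WeightTable = weight_tables[unit]
        counts = allocate_draws(wt, total_draws)
        cubes, kept = [], []
        for mid, k in zip(wt.model_ids, counts):
            if k == 0:
                continue
            fm = fit_model(spec_by_id[mid], surface)
            cubes.append(sample_projection(fm, horizon, int(k),
                                           seed=_child_seed(seed, *unit, mid, "proj")))
            kept.append(int(k))
        last = surface.last_year
        j = int(np.flatnonzero(surface.years == last)[0])
        obs_rates = {last: surface.deaths[:, j] / surface.population[:, j]}
        projections[unit] = pool(
            cubes, kept, seed=_child_seed(seed, *unit, "pool"),
            country=surface.country, sex=surface.sex, scheme=surface.scheme,
            observed_rates=obs_rates,
        )
    return ProjectionResult(projections=projections, horizon=horizon,
                            total_draws=total_draws)
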