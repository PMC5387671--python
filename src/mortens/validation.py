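"""Holdout evaluation of ensemble members and exponential bias weights.

The weighting scheme: withhold the most recent k years of a surface, fit each
member on the remainder, project the withheld years, and score each member by
its *projection bias* — observed minus projected life expectancy at birth,
averaged over the withheld years (projected summarised by the posterior
median by default).  Member weights are exp(−|bias|), normalised to sum to 1,
so weight decays exponentially in the magnitude of the bias.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surfaces import MortalitySurface

__all__ = [
    "WeightTable",
    "holdout_split",
    "projection_bias",
    "compute_weights",
    "coverage",
    "average_absolute_bias",
]


@dataclass
class WeightTable:
    """Per-model holdout bias and normalised ensemble weight."""

    model_ids: list
    biases: np.ndarray
    weights: np.ndarray
    country: str = ""
    sex: str = ""
    holdout_years: tuple = ()

    def __post_init__(self):
        self.biases = np.asarray(self.biases, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.model_ids) == len(self.biases) == len(self.weights)):
            raise ValueError("model_ids, biases, weights must align")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")

    def weight_of(self, model_id: str) -> float:
        return float(self.weights[self.model_ids.index(model_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "country": self.country, "sex": self.sex,
            "model_id": self.model_ids, "bias": self.biases,
            "weight": self.weights,
        })

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def holdout_split(surface: MortalitySurface, k: int = 13):
    """Split off the last ``k`` calendar years with data.

    Returns ``(training, withheld)`` surfaces.  The withheld part is exactly
    the last ``k`` observed years; training is the complement and must retain
    at least 10 observed years.
    """
    if k < 1:
        raise ValueError("holdout length k must be at least 1 year")
    obs_years = surface.observed_years
    if len(obs_years) <= k:
        raise ValueError(f"surface has {len(obs_years)} observed years; cannot withhold {k}")
    if len(obs_years) - k < 10:
        raise ValueError(
            f"withholding {k} years leaves {len(obs_years) - k} observed years "
            "for training; need >= 10"
        )
    cut = int(obs_years[-k])  # first withheld calendar year
    training = surface.restrict(int(surface.years[0]), cut - 1)
    withheld = surface.restrict(cut, int(surface.years[-1]))
    return training, withheld


def projection_bias(observed: np.ndarray, projected: np.ndarray,
                    point: str = "median") -> float:
    """Mean over withheld years of observed − point(projected) in years.

    ``observed``: per-year life expectancy from withheld data, shape (Y,).
    ``projected``: per-draw per-year life expectancy, shape (n_draws, Y).
    Positive bias means the model under-projected.
    """
    observed = np.asarray(observed, dtype=float)
    projected = np.asarray(projected, dtype=float)
    if projected.ndim != 2 or projected.shape[1] != observed.shape[0]:
        raise ValueError("projected must be (n_draws, n_years) matching observed years")
    if point == "median":
        centre = np.median(projected, axis=0)
    elif point == "mean":
        centre = projected.mean(axis=0)
    else:
        raise ValueError("point must be 'median' or 'mean'")
    return float(np.mean(observed - centre))


def compute_weights(biases, model_ids=None, country: str = "", sex: str = "",
                    holdout_years: tuple = ()) -> WeightTable:
    """Normalised exponential-bias weights w_i = exp(−|b_i|) / Σ_j exp(−|b_j|)."""
    if isinstance(biases, dict):
        model_ids = list(biases.keys())
        biases = np.array([biases[m] for m in model_ids], dtype=float)
    else:
        biases = np.asarray(biases, dtype=float)
        if model_ids is None:
            model_ids = [f"model-{i}" for i in range(len(biases))]
    if len(biases) == 0:
        raise ValueError("no models to weight")
    if np.any(~np.isfinite(biases)):
        raise ValueError("biases must be finite")
    raw = np.exp(-np.abs(biases))
    weights = raw / raw.sum()
    return WeightTable(model_ids=list(model_ids), biases=biases, weights=weights,
                       country=country, sex=sex, holdout_years=tuple(holdout_years))


def coverage(projected: np.ndarray, observed: np.ndarray,
             level: float = 0.90) -> float:
    """Fraction of years whose observation falls in the central interval.

    The interval is the equal-tailed empirical ``level`` interval of the
    draws for that year (inclusive at the endpoints).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    projected = np.asarray(projected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if projected.ndim != 2 or projected.shape[0] < 2:
        raise ValueError("need at least 2 draws, shaped (n_draws, n_years)")
    if projected.shape[1] != observed.shape[0]:
        raise ValueError("projected and observed years must align")
    lo = np.quantile(projected, (1.0 - level) / 2.0, axis=0)
    hi = np.quantile(projected, (1.0 + level) / 2.0, axis=0)
    return float(np.mean((observed >= lo) & (observed <= hi)))


def average_absolute_bias(bias_by_unit) -> float:
    """Mean absolute projection bias over country–sex units (years)."""
    b = np.asarray(list(bias_by_unit.values()) if isinstance(bias_by_unit, dict)
                   else bias_by_unit, dtype=float)
    if b.size == 0:
        raise ValueError("no units supplied")
    return float(np.mean(np.abs(b)))
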