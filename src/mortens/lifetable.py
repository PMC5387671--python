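"""Abridged life tables from age-specific death rates.

Converts interval death rates m into conditional death probabilities q via
the actuarial identity q = n·m / (1 + n·(1−a)·m), builds the standard
columns (l, d, L, T, e) with radix 1, and exposes the three headline
summaries: life expectancy at birth, life expectancy at a given age, and the
probability of dying before age 70.  The open-ended terminal interval takes
q = 1 and L = l/m (constant-hazard closure).

The grid functions are vectorised over arbitrary leading dimensions so that
posterior draw cubes can be transformed without Python loops.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surfaces import AgeGroupScheme

__all__ = [
    "LifeTable",
    "build_life_table",
    "life_expectancy_at",
    "prob_death_before",
    "life_expectancy_grid",
    "prob_death_before_grid",
    "survivorship_grid",
]


def _columns(m: np.ndarray, scheme: AgeGroupScheme):
    """Life-table columns for rate arrays of shape (..., n_groups)."""
    m = np.asarray(m, dtype=float)
    A = scheme.n_groups
    if m.shape[-1] != A:
        raise ValueError(f"expected {A} age groups, got {m.shape[-1]}")
    if np.any(~np.isfinite(m)) or np.any(m < 0):
        raise ValueError("death rates must be finite and non-negative")
    n = scheme.widths  # closed-interval widths
    a = np.asarray(scheme.a_fractions, dtype=float)

    q = np.empty_like(m)
    mc = m[..., :-1]
    q[..., :-1] = np.minimum(n * mc / (1.0 + n * (1.0 - a[:-1]) * mc), 1.0)
    q[..., -1] = 1.0

    l = np.empty_like(m)
    l[..., 0] = 1.0
    l[..., 1:] = np.cumprod(1.0 - q[..., :-1], axis=-1)
    d = l * q

    L = np.empty_like(m)
    L[..., :-1] = n * (l[..., :-1] - (1.0 - a[:-1]) * d[..., :-1])
    m_open = m[..., -1]
    l_open = l[..., -1]
    if np.any((m_open == 0) & (l_open > 0)):
        raise ValueError(
            "zero death rate in the open-ended interval with survivors remaining: "
            "remaining life expectancy undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        L[..., -1] = np.where(l_open > 0, l_open / np.where(m_open > 0, m_open, 1.0), 0.0)

    T = np.flip(np.cumsum(np.flip(L, axis=-1), axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    return q, l, d, L, T, e


@dataclass
class LifeTable:
    """One abridged life table (radix 1.0)."""

    scheme: AgeGroupScheme
    m: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_group": self.scheme.labels, "m": self.m, "q": self.q,
             "l": self.l, "d": self.d, "L": self.L, "T": self.T, "e": self.e}
        )

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def build_life_table(rates, scheme: AgeGroupScheme = None) -> LifeTable:
    """Build an abridged life table from one rate vector."""
    scheme = scheme or AgeGroupScheme()
    m = np.asarray(rates, dtype=float)
    if m.ndim != 1:
        raise ValueError("build_life_table expects a 1-D rate vector")
    q, l, d, L, T, e = _columns(m, scheme)
    return LifeTable(scheme=scheme, m=m, q=q, l=l, d=d, L=L, T=T, e=e)


def life_expectancy_at(lt: LifeTable, age: float = 0) -> float:
    """Remaining life expectancy at an age-group boundary (years)."""
    i = lt.scheme.index_of(age)
    if lt.l[i] <= 0:
        raise ValueError(f"no survivors at age {age}; life expectancy undefined")
    return float(lt.e[i])


def prob_death_before(lt: LifeTable, age: float = 70) -> float:
    """Probability a newborn dies before ``age`` (an interval boundary)."""
    if age > lt.scheme.lower_bounds[-1]:
        raise ValueError("age lies beyond the open-ended interval start")
    i = lt.scheme.index_of(age)
    return float(1.0 - lt.l[i])


# -- vectorised forms ---------------------------------------------------------

def life_expectancy_grid(rates, scheme: AgeGroupScheme = None, at_age: float = 0) -> np.ndarray:
    """Life expectancy at ``at_age`` for rate arrays shaped (..., n_groups)."""
    scheme = scheme or AgeGroupScheme()
    i = scheme.index_of(at_age)
    _, l, _, _, _, e = _columns(rates, scheme)
    if np.any(l[..., i] <= 0):
        raise ValueError(f"no survivors at age {at_age} in some table")
    return e[..., i]


def prob_death_before_grid(rates, scheme: AgeGroupScheme = None, age: float = 70) -> np.ndarray:
    """P(death before ``age``) for rate arrays shaped (..., n_groups)."""
    scheme = scheme or AgeGroupScheme()
    if age > scheme.lower_bounds[-1]:
        raise ValueError("age lies beyond the open-ended interval start")
    i = scheme.index_of(age)
    _, l, _, _, _, _ = _columns(rates, scheme)
    return 1.0 - l[..., i]


def survivorship_grid(rates, scheme: AgeGroupScheme = None) -> np.ndarray:
    """Survivorship l(x) at interval starts for rate arrays (..., n_groups)."""
    scheme = scheme or AgeGroupScheme()
    _, l, _, _, _, _ = _columns(rates, scheme)
    return l
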