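"""Age-group schemes and country–sex mortality surfaces.

A *mortality surface* holds death counts and mid-year population (person-years
of exposure) on an age-group × calendar-year grid for one country and sex.
Years inside the span may be flagged as missing (death registration gaps);
missing years are carried explicitly and never imputed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroupScheme",
    "MortalitySurface",
    "read_surface",
    "write_surface",
    "death_rates",
    "restrict_years",
]

_DEFAULT_BOUNDS = (0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85)


@dataclass(frozen=True)
class AgeGroupScheme:
    """Abridged age grouping: interval lower bounds plus a-fractions.

    ``lower_bounds`` start at 0 and are strictly increasing; the final
    interval is open-ended.  ``a_fractions`` give the average fraction of the
    interval lived by those dying within it (the :math:`{}_na_x` convention),
    one value per interval, each in (0, 1).
    """

    lower_bounds: tuple = _DEFAULT_BOUNDS
    a_fractions: tuple = (0.1,) + (0.5,) * (len(_DEFAULT_BOUNDS) - 1)

    def __post_init__(self):
        lb = np.asarray(self.lower_bounds, dtype=float)
        if lb[0] != 0:
            raise ValueError("first age-group lower bound must be 0")
        if not np.all(np.diff(lb) > 0):
            raise ValueError("age-group lower bounds must be strictly increasing")
        a = np.asarray(self.a_fractions, dtype=float)
        if len(a) != len(lb):
            raise ValueError("need one a-fraction per age group")
        if np.any((a <= 0) | (a >= 1)):
            raise ValueError("a-fractions must lie strictly in (0, 1)")

    @property
    def n_groups(self) -> int:
        return len(self.lower_bounds)

    @property
    def widths(self) -> np.ndarray:
        """Widths of the closed intervals (length ``n_groups - 1``)."""
        return np.diff(np.asarray(self.lower_bounds, dtype=float))

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints in years; the open interval uses lower + 2.5."""
        lb = np.asarray(self.lower_bounds, dtype=float)
        mids = np.empty(self.n_groups)
        mids[:-1] = lb[:-1] + self.widths / 2.0
        mids[-1] = lb[-1] + 2.5
        return mids

    @property
    def labels(self) -> list:
        out = []
        lb = self.lower_bounds
        w = self.widths
        for i, lo in enumerate(lb[:-1]):
            if w[i] == 1:
                out.append(str(int(lo)))
            else:
                out.append(f"{int(lo)}-{int(lo + w[i] - 1)}")
        out.append(f"{int(lb[-1])}+")
        return out

    def index_of(self, age: float) -> int:
        """Index of the interval starting exactly at ``age``."""
        lb = list(self.lower_bounds)
        if age not in lb:
            raise ValueError(f"age {age} is not an age-group boundary of this scheme")
        return lb.index(age)

    @classmethod
    def from_labels(cls, labels) -> "AgeGroupScheme":
        """Reconstruct a scheme from labels like ``["0", "1-4", ..., "85+"]``."""
        lowers = []
        for lab in labels:
            lab = str(lab).strip()
            if lab.endswith("+"):
                lowers.append(int(lab[:-1]))
            elif "-" in lab:
                lowers.append(int(lab.split("-")[0]))
            else:
                lowers.append(int(lab))
        lowers_t = tuple(sorted(lowers))
        if lowers_t != tuple(lowers):
            raise ValueError("age-group labels are not in ascending order")
        a = tuple(0.1 if lo == 0 and lowers_t[1] <= 1 else 0.5 for lo in lowers_t)
        return cls(lower_bounds=lowers_t, a_fractions=a)


@dataclass
class MortalitySurface:
    """Deaths and exposure by age group and year for one country–sex.

    ``deaths`` and ``population`` are ``(n_groups, n_years)`` arrays over the
    contiguous span ``first_year .. first_year + n_years - 1``; columns for
    missing years hold NaN and are flagged False in ``observed``.
    """

    country: str
    sex: str
    first_year: int
    deaths: np.ndarray
    population: np.ndarray
    scheme: AgeGroupScheme = dataclasses.field(default_factory=AgeGroupScheme)
    observed: np.ndarray = None

    def __post_init__(self):
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        if self.deaths.shape != self.population.shape:
            raise ValueError("deaths and population shapes differ")
        if self.deaths.shape[0] != self.scheme.n_groups:
            raise ValueError(
                f"surface has {self.deaths.shape[0]} age rows, scheme defines "
                f"{self.scheme.n_groups} groups"
            )
        if self.observed is None:
            self.observed = np.ones(self.deaths.shape[1], dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != (self.deaths.shape[1],):
            raise ValueError("observed mask length must equal number of years")
        if int(self.observed.sum()) < 2:
            raise ValueError("surface must contain at least 2 observed years")
        obs = self.observed
        d, p = self.deaths[:, obs], self.population[:, obs]
        if np.any(~np.isfinite(d)) or np.any(d < 0):
            ya, yy = np.argwhere(~(np.isfinite(self.deaths) & (self.deaths >= 0)) & obs)[0]
            raise ValueError(
                f"invalid deaths at age group '{self.scheme.labels[ya]}', "
                f"year {self.first_year + yy}"
            )
        if np.any(~np.isfinite(p)) or np.any(p <= 0):
            bad = np.argwhere((~np.isfinite(self.population) | (self.population <= 0)) & obs)
            ya, yy = bad[0]
            raise ValueError(
                f"non-positive population at age group '{self.scheme.labels[ya]}', "
                f"year {self.first_year + yy}"
            )

    # -- basic views ---------------------------------------------------------
    @property
    def n_years(self) -> int:
        return self.deaths.shape[1]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_years)

    @property
    def observed_years(self) -> np.ndarray:
        return self.years[self.observed]

    @property
    def last_year(self) -> int:
        return int(self.observed_years[-1])

    def rates(self) -> np.ndarray:
        """Death rates deaths/population; NaN columns for missing years."""
        m = np.full_like(self.deaths, np.nan)
        m[:, self.observed] = self.deaths[:, self.observed] / self.population[:, self.observed]
        return m

    def restrict(self, first: int, last: int) -> "MortalitySurface":
        if first > last:
            raise ValueError("first year must not exceed last year")
        years = self.years
        if first < years[0] or last > years[-1]:
            raise ValueError(
                f"[{first}, {last}] outside surface span [{years[0]}, {years[-1]}]"
            )
        sel = (years >= first) & (years <= last)
        obs = self.observed[sel]
        if not obs.any():
            raise ValueError(f"no observed years in [{first}, {last}]")
        return MortalitySurface(
            country=self.country,
            sex=self.sex,
            first_year=first,
            deaths=self.deaths[:, sel].copy(),
            population=self.population[:, sel].copy(),
            scheme=self.scheme,
            observed=obs.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per observed (year, age group)."""
        rows = []
        labels = self.scheme.labels
        for j, year in enumerate(self.years):
            if not self.observed[j]:
                continue
            for i, lab in enumerate(labels):
                rows.append(
                    (self.country, self.sex, int(year), lab,
                     self.deaths[i, j], self.population[i, j])
                )
        return pd.DataFrame(
            rows, columns=["country", "sex", "year", "age_group", "deaths", "population"]
        )


def death_rates(surface: MortalitySurface) -> pd.DataFrame:
    """Death rates (deaths per person-year) as age-group × year table."""
    return pd.DataFrame(surface.rates(), index=surface.scheme.labels, columns=surface.years)


def restrict_years(surface: MortalitySurface, first: int, last: int) -> MortalitySurface:
    """Restrict a surface to the calendar-year window ``[first, last]``."""
    return surface.restrict(first, last)


def read_surface(path, country: str = None, sex: str = None,
                 scheme: AgeGroupScheme = None, sep: str = ",") -> MortalitySurface:
    """Read one country–sex surface from a delimited text file.

    The file must have columns ``country,sex,year,age_group,deaths,population``
    with one row per combination.  Years absent from the file (inside the
    observed span) are recorded as missing.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"country", "sex", "year", "age_group", "deaths", "population"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    if country is not None:
        df = df[df["country"] == country]
    elif df["country"].nunique() > 1:
        raise ValueError("file contains multiple countries; pass country=")
    if sex is not None:
        df = df[df["sex"] == sex]
    elif df["sex"].nunique() > 1:
        raise ValueError("file contains multiple sexes; pass sex=")
    if df.empty:
        raise ValueError("no rows for the requested country/sex")
    if df.duplicated(subset=["year", "age_group"]).any():
        dup = df[df.duplicated(subset=["year", "age_group"])].iloc[0]
        raise ValueError(f"duplicate row for year {dup['year']}, age group {dup['age_group']}")

    if scheme is None:
        labels_in_file = list(dict.fromkeys(df["age_group"].astype(str)))
        scheme = AgeGroupScheme.from_labels(sorted(
            labels_in_file,
            key=lambda s: int(s.rstrip("+").split("-")[0]),
        ))
    labels = scheme.labels
    if set(df["age_group"].astype(str)) != set(labels):
        raise ValueError("age groups in file do not match the declared scheme")

    years_present = np.sort(df["year"].unique())
    first, last = int(years_present[0]), int(years_present[-1])
    span = np.arange(first, last + 1)
    observed = np.isin(span, years_present)
    A, Y = scheme.n_groups, len(span)
    deaths = np.full((A, Y), np.nan)
    population = np.full((A, Y), np.nan)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    for _, row in df.iterrows():
        i = lab_idx[str(row["age_group"])]
        j = int(row["year"]) - first
        deaths[i, j] = row["deaths"]
        population[i, j] = row["population"]
    for j in np.flatnonzero(observed):
        if np.any(np.isnan(deaths[:, j])):
            raise ValueError(f"year {first + j} has rows for only some age groups")
    return MortalitySurface(
        country=str(df["country"].iloc[0]), sex=str(df["sex"].iloc[0]),
        first_year=first, deaths=deaths, population=population,
        scheme=scheme, observed=observed,
    )


def write_surface(surface: MortalitySurface, path, sep: str = ",") -> None:
    """Write a surface in the long text format read by :func:`read_surface`."""
    surface.to_frame().to_csv(path, sep=sep, index=False)
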