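"""Ensemble members: age–period–cohort projection models for log death rates.

Every member models log m[a, y] as an age baseline plus a period component
and, optionally, a smoothed birth-cohort component:

* ``period_structure = "common"``      log m = alpha_a + kappa_y
* ``period_structure = "age_loaded"``  log m = alpha_a + beta_a kappa_y (Lee–Carter)
* ``period_structure = "age_specific"`` log m = alpha_a + kappa_{a,y}

The period index (or each per-age index) is extrapolated with either a
weighted linear trend or a random walk with drift.  Estimation is a fast
two-stage empirical-Bayes scheme: stage 1 extracts the age/period/cohort
structure from recency-weighted log empirical rates (alternating least
squares for the bilinear form); stage 2 places conjugate
normal–inverse-chi-square posteriors on the trend parameters (drift and
innovation variance) and the posterior predictive is simulated by drawing
the variance from its scaled inverse-chi-square marginal, the drift from its
conditional normal, and the future index path given both.  Age smoothing
("independent" | "rw1" | "rw2") applies a first- or second-difference
roughness penalty to the age-indexed vectors (baseline, loadings, per-age
drifts); cohort effects are shrunken, first-difference-smoothed diagonal
residual means.

Observation weights decay as ``time_weight ** (last_year − y)`` so members
with ``time_weight < 1`` privilege recent years.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .lifetable import life_expectancy_grid
from .surfaces import AgeGroupScheme, MortalitySurface

__all__ = [
    "ModelSpec",
    "FittedModel",
    "DrawCube",
    "ModelFitError",
    "default_ensemble",
    "load_ensemble",
    "fit_model",
    "fit_ensemble",
    "sample_projection",
    "project_life_expectancy",
]

AGE_STRUCTURES = ("independent", "rw1", "rw2")
PERIOD_STRUCTURES = ("common", "age_loaded", "age_specific")
COHORT_EFFECTS = ("none", "smoothed")
TRENDS = ("linear", "rwd")

# Roughness-penalty strength per age-smoothing level (difference order, tau).
_SMOOTH = {"independent": (1, 0.0), "rw1": (1, 20.0), "rw2": (2, 80.0)}
_COHORT_SHRINK = 1.0   # pseudo-cells pulled toward 0 per cohort
_COHORT_TAU = 2.0      # first-difference penalty along cohort index
_MIN_TRAIN_YEARS = 10


class ModelFitError(RuntimeError):
    """Raised when a member fails to produce a finite fitted state."""


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one ensemble member."""

    id: str
    age_structure: str = "rw1"
    period_structure: str = "age_loaded"
    cohort_effect: str = "none"
    time_weight: float = 1.0
    trend: str = "rwd"

    def __post_init__(self):
        if self.age_structure not in AGE_STRUCTURES:
            raise ValueError(f"unknown age_structure {self.age_structure!r}")
        if self.period_structure not in PERIOD_STRUCTURES:
            raise ValueError(f"unknown period_structure {self.period_structure!r}")
        if self.cohort_effect not in COHORT_EFFECTS:
            raise ValueError(f"unknown cohort_effect {self.cohort_effect!r}")
        if self.trend not in TRENDS:
            raise ValueError(f"unknown trend {self.trend!r}")
        if not (0.0 < self.time_weight <= 1.0):
            raise ValueError("time_weight must lie in (0, 1]")


def load_ensemble(path) -> list:
    """Load an ensemble grid from a YAML file (list of spec mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [ModelSpec(**entry) for entry in raw["members"]]
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("ensemble member ids must be unique")
    return specs


def default_ensemble() -> list:
    """The packaged 21-member grid (see ``data/ensemble21.yaml``)."""
    ref = importlib.resources.files("mortens.data") / "ensemble21.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_ensemble(path)


# -- numerical helpers --------------------------------------------------------

def _diff_matrix(n: int, order: int) -> np.ndarray:
    D = np.eye(n)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


def _smooth_vector(v: np.ndarray, structure: str, w=None) -> np.ndarray:
    """Difference roughness penalty: argmin Σ w_a (x_a−v_a)² + tau ||D x||².

    ``w`` carries the data precision per age (mean death count, normalised
    to mean 1): ages with abundant deaths are barely moved, sparse ages are
    shrunk toward their neighbours — the MAP analogue of a random-walk
    smoothing prior against a Poisson likelihood.
    """
    v = np.asarray(v, dtype=float)
    order, tau = _SMOOTH[structure]
    if tau == 0.0 or len(v) <= order:
        return v
    w = np.ones(len(v)) if w is None else np.asarray(w, dtype=float)
    D = _diff_matrix(len(v), order)
    return np.linalg.solve(np.diag(w) + tau * (D.T @ D), w * v)


@dataclass
class TrendFit:
    """Posterior state of one extrapolated period index."""

    kind: str                 # "linear" | "rwd"
    level: float              # index value at the last observed year
    last_year: int
    sigma2: float             # innovation / residual variance point estimate
    df: int                   # degrees of freedom for the variance posterior
    # rwd: drift and unit-variance scale such that Var(drift) = c * sigma2
    drift: float = 0.0
    drift_var_unit: float = 0.0
    # linear: coefficients (intercept, slope) about t_center and unit covariance
    coef: np.ndarray = None
    cov_unit: np.ndarray = None
    t_center: float = 0.0

    def point(self, t_future: np.ndarray) -> np.ndarray:
        t_future = np.asarray(t_future, dtype=float)
        if self.kind == "rwd":
            return self.level + self.drift * (t_future - self.last_year)
        return self.coef[0] + self.coef[1] * (t_future - self.t_center)

    def simulate(self, t_future: np.ndarray, n_draws: int, rng) -> np.ndarray:
        """Posterior-predictive index paths, shape (n_draws, horizon)."""
        t_future = np.asarray(t_future, dtype=float)
        H = len(t_future)
        df = max(self.df, 1)
        if self.sigma2 > 0:
            sigma2 = self.sigma2 * df / rng.chisquare(df, size=n_draws)
        else:
            sigma2 = np.zeros(n_draws)
        sigma = np.sqrt(sigma2)
        if self.kind == "rwd":
            drift = self.drift + np.sqrt(self.drift_var_unit * sigma2) * \
                rng.standard_normal(n_draws)
            shocks = sigma[:, None] * rng.standard_normal((n_draws, H))
            steps = np.diff(np.concatenate(
                [[self.last_year], t_future]).astype(float))
            incr = drift[:, None] * steps[None, :] + \
                np.sqrt(steps)[None, :] * shocks
            return self.level + np.cumsum(incr, axis=1)
        # linear: coefficient uncertainty plus i.i.d. residual noise
        chol = np.linalg.cholesky(self.cov_unit + 1e-30 * np.eye(2))
        z = rng.standard_normal((n_draws, 2))
        coef = self.coef[None, :] + (z @ chol.T) * sigma[:, None]
        noise = sigma[:, None] * rng.standard_normal((n_draws, H))
        tt = t_future - self.t_center
        return coef[:, [0]] + coef[:, [1]] * tt[None, :] + noise


def _fit_trend_linear(t: np.ndarray, k: np.ndarray, w: np.ndarray) -> TrendFit:
    t = np.asarray(t, dtype=float)
    t_center = np.average(t, weights=w)
    X = np.column_stack([np.ones_like(t), t - t_center])
    XtW = X.T * w
    G = XtW @ X
    coef = np.linalg.solve(G, XtW @ k)
    resid = k - X @ coef
    n = len(t)
    df = max(n - 2, 1)
    sigma2 = float(np.sum(w * resid**2) / np.sum(w) * n / df)
    cov_unit = np.linalg.inv(G)
    return TrendFit(kind="linear", level=float(k[-1]), last_year=int(t[-1]),
                    sigma2=sigma2, df=df, coef=coef, cov_unit=cov_unit,
                    t_center=float(t_center))


def _fit_trend_rwd(t: np.ndarray, k: np.ndarray, w: np.ndarray) -> TrendFit:
    t = np.asarray(t, dtype=float)
    gaps = np.diff(t)           # >= 1; > 1 across missing years
    inc = np.diff(k)
    wi = w[1:]                  # weight of the later endpoint
    drift = float(np.sum(wi * inc) / np.sum(wi * gaps))
    u = (inc - drift * gaps) / np.sqrt(gaps)
    n = len(inc)
    df = max(n - 1, 1)
    sigma2 = float(np.sum(wi * u**2) / np.sum(wi) * n / df)
    drift_var_unit = float(np.sum(wi**2 * gaps) / np.sum(wi * gaps) ** 2)
    return TrendFit(kind="rwd", level=float(k[-1]), last_year=int(t[-1]),
                    sigma2=sigma2, df=df, drift=drift,
                    drift_var_unit=drift_var_unit)


def _fit_trend(t, k, w, kind) -> TrendFit:
    if len(t) < 3:
        raise ModelFitError("need at least 3 observed years for the trend stage")
    fit = _fit_trend_linear(t, k, w) if kind == "linear" else _fit_trend_rwd(t, k, w)
    if not np.isfinite([fit.level, fit.sigma2]).all():
        raise ModelFitError("non-finite trend fit")
    return fit


# -- fitted model -------------------------------------------------------------

@dataclass
class FittedModel:
    """Fitted state of one ensemble member on one country–sex surface."""

    spec: ModelSpec
    country: str
    sex: str
    scheme: AgeGroupScheme
    fit_years: np.ndarray          # observed calendar years used
    alpha: np.ndarray              # (A,) smoothed baseline log rates
    beta: np.ndarray               # (A,) period loadings (sum 1; ones for common)
    trend: object                  # TrendFit or list[TrendFit] (age_specific)
    gamma: dict = field(default_factory=dict)  # cohort year -> effect
    last_year: int = 0

    def drift_summary(self):
        """(mean, sd, df) of the annual trend slope of the period index.

        For the age-specific structure this is the loading-weighted average
        of the per-age slopes (diagnostic only).
        """
        def one(tf: TrendFit):
            if tf.kind == "rwd":
                return tf.drift, np.sqrt(tf.drift_var_unit * tf.sigma2), tf.df
            return (tf.coef[1], float(np.sqrt(tf.cov_unit[1, 1] * tf.sigma2)),
                    tf.df)
        if isinstance(self.trend, TrendFit):
            return one(self.trend)
        means, sds, dfs = zip(*[one(tf) for tf in self.trend])
        w = self.beta / self.beta.sum()
        return (float(np.sum(w * np.asarray(means))),
                float(np.sqrt(np.sum(w**2 * np.asarray(sds) ** 2))),
                int(min(dfs)))

    def drift_interval(self, level: float = 0.95):
        """Central posterior interval for the annual slope (t marginal)."""
        from scipy import stats
        mean, sd, df = self.drift_summary()
        tq = stats.t.ppf(0.5 + level / 2.0, df)
        return mean - tq * sd, mean + tq * sd

    def _gamma_matrix(self, years: np.ndarray) -> np.ndarray:
        mids = np.round(self.scheme.midpoints).astype(int)
        cmat = np.asarray(years)[None, :] - mids[:, None]
        if not self.gamma:
            return np.zeros(cmat.shape)
        return np.vectorize(lambda c: self.gamma.get(int(c), 0.0))(cmat)

    def _log_rates_from_kappa(self, kappa, years) -> np.ndarray:
        """kappa: (..., H) or per-age (..., A, H) -> log rates (..., A, H)."""
        g = self._gamma_matrix(years)
        if self.spec.period_structure == "age_specific":
            return self.alpha[:, None] + kappa + g
        return (self.alpha[:, None] + self.beta[:, None] * kappa[..., None, :]
                + g)

    def point_forecast(self, horizon: int) -> np.ndarray:
        """Posterior-mean rate forecast, shape (n_groups, horizon)."""
        years = np.arange(self.last_year + 1, self.last_year + 1 + horizon)
        if self.spec.period_structure == "age_specific":
            kappa = np.stack([tf.point(years) for tf in self.trend])
        else:
            kappa = self.trend.point(years)
        return np.exp(self._log_rates_from_kappa(kappa, years))


@dataclass
class DrawCube:
    """Posterior draws of age-specific death rates over projection years."""

    model_id: str
    draws: np.ndarray      # (n_draws, n_groups, horizon)
    years: np.ndarray      # projection calendar years
    seed: int = 0

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[0] < 1:
            raise ValueError("draws must be (n_draws, n_groups, horizon) with >= 1 draw")
        if np.any(~np.isfinite(self.draws)) or np.any(self.draws <= 0):
            raise ValueError("all death-rate draws must be positive and finite")
        self.years = np.asarray(self.years)
        if len(self.years) != self.draws.shape[2]:
            raise ValueError("years length must match the draw horizon")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise ValueError(f"year {year} not in projection range")
        return int(idx[0])


# -- fitting ------------------------------------------------------------------

def _cohort_effects(R: np.ndarray, cell_w: np.ndarray, cmat: np.ndarray) -> dict:
    """Shrunken, smoothed mean residual per birth cohort."""
    cohorts = np.unique(cmat)
    sums = np.array([np.sum(cell_w[cmat == c] * R[cmat == c]) for c in cohorts])
    wts = np.array([np.sum(cell_w[cmat == c]) for c in cohorts])
    raw = sums / (wts + _COHORT_SHRINK)
    D = _diff_matrix(len(cohorts), 1)
    smoothed = np.linalg.solve(np.eye(len(cohorts)) + _COHORT_TAU * (D.T @ D), raw)
    smoothed = smoothed - np.average(smoothed, weights=wts + _COHORT_SHRINK)
    return {int(c): float(g) for c, g in zip(cohorts, smoothed)}


def fit_model(spec: ModelSpec, surface: MortalitySurface,
              fit_window: tuple = None, seed: int = None) -> FittedModel:
    """Fit one ensemble member to a surface.

    ``fit_window`` is an inclusive ``(first, last)`` calendar-year range;
    missing years inside the window simply contribute no terms.  ``seed`` is
    accepted for interface symmetry — the estimator is deterministic.
    """
    if fit_window is not None:
        surface = surface.restrict(*fit_window)
    years = surface.observed_years
    if len(years) < _MIN_TRAIN_YEARS:
        raise ValueError(
            f"fit window has {len(years)} observed years; need >= {_MIN_TRAIN_YEARS}"
        )
    scheme = surface.scheme
    A = scheme.n_groups
    obs = surface.observed
    D = surface.deaths[:, obs]
    N = surface.population[:, obs]
    # Empirical log rates with a 0.5-death continuity correction for zeros.
    Z = np.log((D + 0.5) / N)
    w_year = spec.time_weight ** (years[-1] - years)
    w_year = w_year / w_year.sum()

    # per-age precision for the smoothing penalty: mean annual deaths
    # (the log-rate estimate for an age group has variance ~ 1/deaths)
    age_w = (D + 0.5).mean(axis=1)
    alpha = _smooth_vector(Z @ w_year, spec.age_structure, age_w)
    R = Z - alpha[:, None]

    gamma = {}
    if spec.cohort_effect == "smoothed":
        mids = np.round(scheme.midpoints).astype(int)
        cmat = years[None, :] - mids[:, None]
        cell_w = np.broadcast_to(w_year[None, :], (A, len(years))).copy()
        gamma = _cohort_effects(R, cell_w, cmat)
        gmat = np.vectorize(lambda c: gamma.get(int(c), 0.0))(cmat)
        R = R - gmat

    if spec.period_structure == "common":
        beta = np.ones(A)
        kappa = R.mean(axis=0)
        trend = _fit_trend(years, kappa, w_year, spec.trend)
    elif spec.period_structure == "age_loaded":
        beta, kappa = _bilinear_als(R, w_year)
        beta = _smooth_vector(beta, spec.age_structure, age_w)
        s = beta.sum()
        if abs(s) < 1e-12:
            raise ModelFitError("degenerate loadings in bilinear fit")
        beta, kappa = beta / s, kappa * s
        trend = _fit_trend(years, kappa, w_year, spec.trend)
    else:  # age_specific
        beta = np.ones(A) / A
        fits = [_fit_trend(years, R[a], w_year, spec.trend) for a in range(A)]
        drifts = np.array([tf.drift if tf.kind == "rwd" else tf.coef[1]
                           for tf in fits])
        sm = _smooth_vector(drifts, spec.age_structure, age_w)
        for tf, d in zip(fits, sm):
            if tf.kind == "rwd":
                tf.drift = float(d)
            else:
                tf.coef = np.array([tf.coef[0], float(d)])
        trend = fits

    fm = FittedModel(spec=spec, country=surface.country, sex=surface.sex,
                     scheme=scheme, fit_years=years, alpha=alpha, beta=beta,
                     trend=trend, gamma=gamma, last_year=int(years[-1]))
    if not (np.isfinite(fm.alpha).all() and np.isfinite(fm.beta).all()):
        raise ModelFitError("non-finite fitted state")
    return fm


def _bilinear_als(R: np.ndarray, w_year: np.ndarray, n_iter: int = 60,
                  tol: float = 1e-10):
    """Weighted rank-1 fit R ~ beta kappa' by alternating least squares."""
    A, Y = R.shape
    kappa = R.mean(axis=0)
    if np.sum(w_year * kappa**2) < 1e-14:
        return np.ones(A) / A, kappa
    beta = np.ones(A) / A
    prev = np.inf
    for _ in range(n_iter):
        beta = (R * w_year) @ kappa / np.sum(w_year * kappa**2)
        if np.sum(beta**2) < 1e-14:
            raise ModelFitError("bilinear fit collapsed")
        kappa = beta @ R / np.sum(beta**2)
        denom = np.sum(w_year * kappa**2)
        if denom < 1e-14:
            break
        loss = np.sum(w_year * (R - np.outer(beta, kappa)) ** 2)
        if abs(prev - loss) < tol * (1 + loss):
            break
        prev = loss
    if beta.sum() < 0:
        beta, kappa = -beta, -kappa
    return beta, kappa


def fit_ensemble(specs, surface: MortalitySurface, fit_window=None,
                 on_error: str = "drop"):
    """Fit every member; non-convergent members are dropped with a warning."""
    import warnings
    fitted = []
    for spec in specs:
        try:
            fitted.append(fit_model(spec, surface, fit_window=fit_window))
        except ModelFitError as exc:
            if on_error != "drop":
                raise
            warnings.warn(f"model {spec.id} excluded: {exc}", stacklevel=2)
    if not fitted:
        raise ModelFitError("every ensemble member failed to fit")
    return fitted


# -- projection ---------------------------------------------------------------

def sample_projection(fm: FittedModel, horizon: int, n_draws: int,
                      seed: int = 0) -> DrawCube:
    """Posterior-predictive draws of future death rates.

    Propagates trend-parameter uncertainty (drift/slope and innovation
    variance) and, for random-walk trends, the accumulated process noise.
    Identical seeds give identical cubes.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1 year")
    if n_draws < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    years = np.arange(fm.last_year + 1, fm.last_year + 1 + horizon)
    if fm.spec.period_structure == "age_specific":
        paths = np.stack([tf.simulate(years, n_draws, rng) for tf in fm.trend],
                         axis=1)                     # (n_draws, A, H)
        log_m = fm.alpha[None, :, None] + paths
        log_m = log_m + fm._gamma_matrix(years)[None, :, :]
    else:
        kappa = fm.trend.simulate(years, n_draws, rng)   # (n_draws, H)
        log_m = (fm.alpha[None, :, None]
                 + fm.beta[None, :, None] * kappa[:, None, :]
                 + fm._gamma_matrix(years)[None, :, :])
    return DrawCube(model_id=fm.spec.id, draws=np.exp(log_m), years=years,
                    seed=seed)


def project_life_expectancy(cube: DrawCube, scheme: AgeGroupScheme,
                            at_age: float = 0) -> np.ndarray:
    """Life expectancy at ``at_age`` per (draw, projection year)."""
    # draws are (n, A, H); life-table grid wants the age axis last
    rates = np.moveaxis(cube.draws, 1, 2)
    return life_expectancy_grid(rates, scheme, at_age=at_age)
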