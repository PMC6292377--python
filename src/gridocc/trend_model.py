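"""Binomial GLM trend fitting for grid-cell occupancy series.

The unit of analysis is the cell-year: a Bernoulli response (did the cell
contain at least one checklist recording the species that year) modelled on
the logit scale as a log-linear function of year, optionally adjusted for
observer effort (summed checklist hours in the cell-year).  Fitting is by
iteratively reweighted least squares to a deviance-change tolerance of
1e-8 (at most 100 iterations), with complete-separation detection.  Year is
centered before fitting; the slope is reported on the per-year scale.

Companion inference tools: analysis of deviance between nested fits
(likelihood-ratio test), an overdispersion test on the sum of squared
Pearson residuals against the residual degrees of freedom, Wald and
profile-likelihood confidence intervals, per-year growth-rate summaries,
and checklist-level co-occurrence rates between species.

:class:`OccupancyTrendGLM` is a scikit-learn style estimator; the
module-level functions are thin wrappers around it operating directly on
the aggregated cell-year table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_MU_EPS = 1e-10
_SEPARATION_MU = 1e-6


class DegenerateResponseError(ValueError):
    """All responses identical: the trend is not estimable."""


def _bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Logistic-regression IRLS.

    Returns ``(beta, cov, deviance, converged, separation)``.  Separation
    is flagged when every observation is predicted essentially perfectly
    (fitted probability within 1e-6 of its response), the classic symptom
    of complete separation where the MLE diverges.
    """
    n, p = X.shape
    offset = np.zeros(n) if offset is None else offset
    beta = np.zeros(p)
    deviance = _bernoulli_deviance(y, expit(offset))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        w = mu * (1.0 - mu)
        z = (eta - offset) + (y - mu) / w
        xtw = X.T * w
        try:
            beta = linalg.solve(xtw @ X, xtw @ z, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular information matrix (collinear predictors?)"
            ) from exc
        new_deviance = _bernoulli_deviance(y, expit(X @ beta + offset))
        if abs(new_deviance - deviance) < tol:
            deviance = new_deviance
            converged = True
            break
        deviance = new_deviance
    mu = np.clip(expit(X @ beta + offset), _MU_EPS, 1.0 - _MU_EPS)
    w = mu * (1.0 - mu)
    fisher = (X.T * w) @ X
    try:
        cov = linalg.inv(fisher)
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    perfect = np.where(y == 1.0, mu > 1.0 - _SEPARATION_MU, mu < _SEPARATION_MU)
    separation = bool(perfect.all())
    return beta, cov, deviance, converged, separation


@dataclass
class TrendFit:
    """A fitted (or degenerate) occupancy trend model.

    Coefficients are on the log-odds scale; ``year`` is the per-year slope
    (invariant to the internal centering, whose offset is ``year_mean``).
    ``pearson_chi2`` is the sum of squared Pearson residuals.
    """

    names: tuple
    params: np.ndarray | None
    cov: np.ndarray | None
    deviance: float
    null_deviance: float
    df_residual: int
    pearson_chi2: float
    n_obs: int
    converged: bool
    degenerate: bool = False
    separation: bool = False
    link: str = "logit"
    year_mean: float = 0.0
    _X: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def _index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no coefficient named {name!r}") from None

    def coef(self, name: str) -> float:
        if self.params is None:
            raise DegenerateResponseError("degenerate fit has no coefficients")
        return float(self.params[self._index(name)])

    def se(self, name: str) -> float:
        i = self._index(name)
        return float(np.sqrt(self.cov[i, i]))

    def wald_p(self, name: str) -> float:
        z = self.coef(name) / self.se(name)
        return float(2.0 * norm.sf(abs(z)))

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    def to_dict(self) -> dict:
        if self.degenerate or self.params is None:
            return {
                "degenerate": True,
                "converged": False,
                "n_obs": self.n_obs,
                "link": self.link,
            }
        return {
            "degenerate": False,
            "converged": self.converged,
            "separation": self.separation,
            "link": self.link,
            "n_obs": self.n_obs,
            "coefficients": {
                name: {"estimate": self.coef(name), "se": self.se(name)}
                for name in self.names
            },
            "year_mean": self.year_mean,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "df_residual": self.df_residual,
            "pearson_chi2": self.pearson_chi2,
        }


class OccupancyTrendGLM(BaseEstimator):
    """Bernoulli GLM of occupancy on (centered) year and optional effort.

    Parameters
    ----------
    predictors : tuple of str
        Subset of ``("year", "effort")``; the design always includes an
        intercept.
    tol, max_iter
        IRLS convergence tolerance on the deviance change, and iteration cap.

    Fitted attributes (trailing underscore) include ``coef_``,
    ``coef_names_``, ``cov_``, ``deviance_``, ``null_deviance_``,
    ``df_residual_``, ``pearson_chi2_``, ``n_obs_``, ``converged_``,
    ``separation_`` and ``year_mean_``.  A response that is all-0 or all-1
    raises :class:`DegenerateResponseError`; complete separation is
    flagged (``converged_ = False``) rather than silently reported.
    """

    def __init__(self, predictors=("year",), tol=1e-8, max_iter=100):
        self.predictors = predictors
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        columns = [np.ones(len(X))]
        for name in self.predictors:
            if name not in ("year", "effort"):
                raise ValueError(f"unknown predictor {name!r}")
            if name not in X.columns:
                raise ValueError(f"predictor column {name!r} missing from X")
            values = np.asarray(X[name], dtype=float)
            if name == "year":
                if fitting:
                    self.year_mean_ = float(values.mean())
                values = values - self.year_mean_
            columns.append(values)
        return np.column_stack(columns)

    def fit(self, X: pd.DataFrame, y) -> "OccupancyTrendGLM":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise ValueError("empty table")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary")
        if "year" in self.predictors and len(np.unique(X["year"])) < 2:
            raise ValueError("need at least two distinct years")
        if len(np.unique(y)) < 2:
            raise DegenerateResponseError(
                "all responses identical; occupancy trend not estimable"
            )
        design = self._design(X, fitting=True)
        beta, cov, deviance, converged, separation = _irls(
            design, y, tol=self.tol, max_iter=self.max_iter
        )
        if separation:
            logger.warning("complete separation detected; estimates diverge")
        # intercept-only null fit for the analysis-of-deviance baseline
        _, _, null_deviance, _, _ = _irls(
            design[:, :1], y, tol=self.tol, max_iter=self.max_iter
        )
        mu = np.clip(expit(design @ beta), _MU_EPS, 1.0 - _MU_EPS)
        self.coef_names_ = ("intercept", *self.predictors)
        self.coef_ = beta
        self.cov_ = cov
        self.deviance_ = deviance
        self.null_deviance_ = null_deviance
        self.df_residual_ = len(y) - design.shape[1]
        self.pearson_chi2_ = float(np.sum((y - mu) ** 2 / (mu * (1.0 - mu))))
        self.n_obs_ = len(y)
        self.converged_ = bool(converged and not separation)
        self.separation_ = separation
        self._design_ = design
        self._y_ = y
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design = self._design(pd.DataFrame(X), fitting=False)
        p = expit(design @ self.coef_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def result_(self) -> TrendFit:
        """Package the fitted state as a :class:`TrendFit`."""
        return TrendFit(
            names=self.coef_names_,
            params=self.coef_.copy(),
            cov=self.cov_.copy(),
            deviance=self.deviance_,
            null_deviance=self.null_deviance_,
            df_residual=self.df_residual_,
            pearson_chi2=self.pearson_chi2_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            separation=self.separation_,
            year_mean=getattr(self, "year_mean_", 0.0),
            _X=self._design_,
            _y=self._y_,
        )


def fit_occupancy_glm(
    table: pd.DataFrame,
    species: str,
    predictors=("year",),
) -> TrendFit:
    """Fit the occupancy trend GLM on an aggregated cell-year table.

    ``table`` must carry columns ``year``, ``effort_hours`` (if effort is a
    predictor) and the boolean response ``occupied_<species>``.  A response
    that never (or always) indicates occupancy yields a degenerate
    :class:`TrendFit` (flagged, no coefficient table) rather than an
    estimate.
    """
    response = f"occupied_{species}"
    if response not in table.columns:
        raise KeyError(f"table has no column {response!r}")
    if len(table) == 0:
        raise ValueError("empty cell-year table")
    y = table[response].astype(float).to_numpy()
    X = pd.DataFrame({"year": table["year"].to_numpy()})
    if "effort" in predictors:
        X["effort"] = table["effort_hours"].to_numpy()
    model = OccupancyTrendGLM(predictors=tuple(predictors))
    try:
        model.fit(X, y)
    except DegenerateResponseError:
        logger.warning("degenerate response for %s: occupancy constant", species)
        return TrendFit(
            names=(),
            params=None,
            cov=None,
            deviance=np.nan,
            null_deviance=np.nan,
            df_residual=len(y) - 1,
            pearson_chi2=np.nan,
            n_obs=len(y),
            converged=False,
            degenerate=True,
        )
    return model.result_()


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


def likelihood_ratio_test(null_fit: TrendFit, full_fit: TrendFit) -> LRTResult:
    """Analysis of deviance between two nested fits on identical rows."""
    if null_fit.degenerate or full_fit.degenerate:
        raise ValueError("cannot compare degenerate fits")
    if null_fit.n_obs != full_fit.n_obs:
        raise ValueError("fits use different numbers of observations")
    if not set(null_fit.names) <= set(full_fit.names):
        raise ValueError("models are not nested")
    df = len(full_fit.names) - len(null_fit.names)
    if df < 0:
        raise ValueError("null model has more coefficients than the full model")
    statistic = max(0.0, null_fit.deviance - full_fit.deviance)
    p = float(chi2.sf(statistic, df)) if df > 0 else 1.0
    if df == 0:
        statistic = 0.0
    return LRTResult(statistic=statistic, df=df, p=p)


@dataclass(frozen=True)
class OverdispersionResult:
    ratio: float
    statistic: float
    df: int
    p: float
    overdispersed: bool


def overdispersion_test(fit: TrendFit, alpha: float = 0.05) -> OverdispersionResult:
    """Chi-square test of the Pearson statistic against its residual df.

    The statistic is the sum of squared Pearson residuals
    ``(y - p)^2 / (p (1 - p))``; its ratio to the residual degrees of
    freedom should be near 1 under the binomial assumption.  Overdispersion
    is flagged when the upper-tail chi-square probability falls below
    ``alpha``.
    """
    if fit.df_residual <= 0:
        raise ValueError("no residual degrees of freedom")
    statistic = float(fit.pearson_chi2)
    ratio = statistic / fit.df_residual
    p = float(chi2.sf(statistic, fit.df_residual))
    return OverdispersionResult(
        ratio=ratio,
        statistic=statistic,
        df=fit.df_residual,
        p=p,
        overdispersed=bool(p < alpha),
    )


def annual_growth(fit: TrendFit) -> dict:
    """Growth-rate summaries for the year coefficient, both conventions.

    ``percent_per_year_log_odds`` is 100 x b (the "18% per year" reading of
    a log-odds slope); ``odds_ratio`` is exp(b) and
    ``percent_odds_change_per_year`` is 100 x (exp(b) - 1).
    """
    b = fit.coef("year")
    return {
        "b_year": b,
        "percent_per_year_log_odds": 100.0 * b,
        "odds_ratio": float(np.exp(b)),
        "percent_odds_change_per_year": 100.0 * (float(np.exp(b)) - 1.0),
    }


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("interval must contain its point estimate")


def _profile_deviance(fit: TrendFit, index: int, value: float, tol: float) -> float:
    """Deviance with coefficient ``index`` held at ``value`` (others refit)."""
    X, y = fit._X, fit._y
    reduced = np.delete(X, index, axis=1)
    offset = value * X[:, index]
    _, _, deviance, _, _ = _irls(reduced, y, offset=offset, tol=tol)
    return deviance


def confidence_interval(
    fit: TrendFit,
    coefficient: str = "year",
    level: float = 0.95,
    method: str = "profile",
    tol: float = 1e-6,
) -> IntervalEstimate:
    """Wald or profile-likelihood interval for one coefficient.

    The profile interval inverts the chi-square(1) cutoff on the profile
    deviance by bisection to ``tol`` on the coefficient scale; if a bound
    cannot be bracketed (e.g. a diverging likelihood near separation) the
    Wald interval is returned with a warning.
    """
    if fit.degenerate:
        raise DegenerateResponseError("degenerate fit has no interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    index = fit._index(coefficient)
    point = fit.coef(coefficient)
    se = fit.se(coefficient)
    if not np.isfinite(se) or se <= 0:
        raise ValueError("coefficient has zero or undefined variance")
    if method == "wald":
        z = norm.ppf(0.5 + level / 2.0)
        return IntervalEstimate(point, point - z * se, point + z * se, level, "wald")
    if method != "profile":
        raise ValueError("method must be 'wald' or 'profile'")

    cutoff = fit.deviance + chi2.ppf(level, 1)
    bounds = []
    for direction in (-1.0, 1.0):
        inside, step = point, se
        outside = None
        for _ in range(40):
            candidate = inside + direction * step
            if _profile_deviance(fit, index, candidate, tol=1e-10) > cutoff:
                outside = candidate
                break
            inside = candidate
            step *= 2.0
        if outside is None:
            warnings.warn(
                "profile bound failed to bracket; falling back to Wald",
                RuntimeWarning,
            )
            z = norm.ppf(0.5 + level / 2.0)
            return IntervalEstimate(point, point - z * se, point + z * se, level, "wald")
        while abs(outside - inside) > tol:
            middle = 0.5 * (inside + outside)
            if _profile_deviance(fit, index, middle, tol=1e-10) > cutoff:
                outside = middle
            else:
                inside = middle
        bounds.append(0.5 * (inside + outside))
    lower, upper = sorted(bounds)
    return IntervalEstimate(point, lower, upper, level, "profile")


@dataclass(frozen=True)
class CooccurrenceResult:
    species_a: str
    species_b: str
    pct_a_with_b: float | None
    pct_b_with_a: float | None
    n_a: int
    n_b: int


def cooccurrence_rates(
    detections: pd.DataFrame, species_a: str, species_b: str
) -> CooccurrenceResult:
    """Share of checklists recording one species that also record the other.

    Percentages are rounded to one decimal place; a direction whose
    denominator species has zero presences is undefined (``None``).
    ``detections`` must be zero-filled for both species.
    """
    for species in (species_a, species_b):
        if not (detections["species"] == species).any():
            raise KeyError(f"species {species!r} absent from the detection table")
    with_a = set(
        detections.loc[
            (detections["species"] == species_a) & detections["present"],
            "checklist_id",
        ]
    )
    with_b = set(
        detections.loc[
            (detections["species"] == species_b) & detections["present"],
            "checklist_id",
        ]
    )
    both = len(with_a & with_b)
    pct_a = round(100.0 * both / len(with_a), 1) if with_a else None
    pct_b = round(100.0 * both / len(with_b), 1) if with_b else None
    return CooccurrenceResult(
        species_a=species_a,
        species_b=species_b,
        pct_a_with_b=pct_a,
        pct_b_with_a=pct_b,
        n_a=len(with_a),
        n_b=len(with_b),
    )
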