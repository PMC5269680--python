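"""Least-squares fitting of q-exponential and exponential survival curves.

The model fitted to an empirical CCDF is ``c(d) = e_q(-(d - 1)/x0)``: the
offset anchors the model at 1 for the minimal possible distance d=1, matching
the empirical curve's first point.  Residuals are taken over the distinct
observed distances (one point per distinct distance, unweighted) in linear
space by default; log10 space is available for tail emphasis.  The optimizer
is scipy's trust-region-reflective least squares with bounds q in [1, 3.5]
and x0 > 0, started from q=1.5 and the exponential fit's x0.

The fitted q is the clustering score: q ~ 1 means the word is placed like the
memoryless geometric null; larger q means a heavier-tailed distance
distribution, i.e. spatial clustering.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so they
compose with sklearn tooling; :func:`fit_q_exponential` and
:func:`fit_exponential` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .core_math import QParams, q_exponential, q_logarithm
from .occurrences import DistanceSample, EmpiricalCCDF, empirical_ccdf

__all__ = [
    "FitResult",
    "QLogLinearity",
    "QExponentialFitter",
    "ExponentialFitter",
    "fit_q_exponential",
    "fit_exponential",
    "qlog_linearity",
]

DEFAULT_Q_BOUNDS = (1.0, 3.5)
DEFAULT_X0_BOUNDS = (1e-9, np.inf)
DEFAULT_Q_INIT = 1.5
_FTOL = 1e-10
_MAX_NFEV = 10_000


@dataclass(frozen=True)
class FitResult:
    """Outcome of a survival-curve fit.

    ``r_squared`` and ``rms`` are computed in the fit space over the distinct-
    distance points; ``n`` is the underlying number of distances.  For
    ``model='exponential'`` the q parameter is exactly 1.
    """

    params: QParams
    r_squared: float
    rms: float
    n: int
    fit_space: str
    converged: bool
    model: str
    n_points: int

    @property
    def q(self) -> float:
        return self.params.q

    @property
    def x0(self) -> float:
        return self.params.x0


@dataclass(frozen=True)
class QLogLinearity:
    """OLS line through the q-log-transformed CCDF (linearity diagnostic)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    n_excluded: int


def _model_values(d: np.ndarray, q: float, x0: float, offset: float) -> np.ndarray:
    return np.asarray(q_exponential(-(d - offset) / x0, q))


def _to_fit_space(values: np.ndarray, fit_space: str) -> np.ndarray:
    if fit_space == "linear":
        return values
    if fit_space == "log10":
        return np.log10(np.maximum(values, 1e-300))
    raise ValueError(f"fit_space must be 'linear' or 'log10', got {fit_space!r}")


def _goodness(obs: np.ndarray, model: np.ndarray) -> tuple[float, float]:
    resid = obs - model
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rms = float(np.sqrt(ss_res / obs.size))
    return r2, rms


def _exponential_x0_init(d: np.ndarray, c: np.ndarray, offset: float) -> float:
    # log-linear regression ln c = -(d-offset)/x0 gives a robust starting x0
    slope = np.polyfit(d - offset, np.log(c), 1)[0]
    if slope >= 0:
        return float(max(d.max() - offset, 1.0))
    return float(-1.0 / slope)


class QExponentialFitter(BaseEstimator):
    """Fit a q-exponential survival curve to a sample of distances.

    Parameters
    ----------
    q_bounds, x0_bounds : tuple of float
        Box bounds for the optimizer.  q below 1 is excluded by default:
        sub-exponential (anti-clustered) placement is outside the ranking
        model's scope.
    q_init : float
        Starting entropic index.
    fit_space : {'linear', 'log10'}
        Space in which residuals, R^2 and RMS are computed.
    offset : float
        The model is ``e_q(-(d - offset)/x0)``; default 1 anchors it at the
        minimal distance, 0 gives the raw Tsallis form.
    min_occurrences : int
        Minimum number of distances required to build the CCDF.

    Attributes
    ----------
    q_, x0_ : float
        Fitted parameters.
    r_squared_, rms_ : float
        Goodness of fit in ``fit_space``.
    n_ : int
        Number of distances behind the fitted CCDF.
    converged_ : bool
    result_ : FitResult
    ccdf_ : EmpiricalCCDF

    Examples
    --------
    >>> import numpy as np
    >>> from qword.synthetic import sample_q_exponential_distances
    >>> from qword.core_math import QParams
    >>> s = sample_q_exponential_distances(QParams(q=1.5, x0=50), n=20000, seed=0)
    >>> fitter = QExponentialFitter().fit(s.distances)
    >>> abs(fitter.q_ - 1.5) < 0.1
    True
    """

    _model_name = "q_exponential"

    def __init__(
        self,
        q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
        x0_bounds: tuple[float, float] = DEFAULT_X0_BOUNDS,
        q_init: float = DEFAULT_Q_INIT,
        fit_space: str = "linear",
        offset: float = 1.0,
        min_occurrences: int = 50,
    ):
        self.q_bounds = q_bounds
        self.x0_bounds = x0_bounds
        self.q_init = q_init
        self.fit_space = fit_space
        self.offset = offset
        self.min_occurrences = min_occurrences

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit from a raw distance sample (array-like of integers >= 1)."""
        X = np.asarray(X)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValueError("X must be a 1d array of distances (or a column vector)")
        sample = DistanceSample(word="sample", distances=X, n_occurrences=X.size + 1)
        return self.fit_ccdf(empirical_ccdf(sample, self.min_occurrences))

    def fit_ccdf(self, ccdf: EmpiricalCCDF):
        """Fit from a prebuilt empirical CCDF."""
        d = ccdf.distances.astype(float)
        c_obs = _to_fit_space(ccdf.values, self.fit_space)

        x0_init = getattr(self, "_forced_x0_init", None)
        if x0_init is None:
            x0_init = _exponential_x0_init(d, ccdf.values, self.offset)
        theta0, lower, upper = self._initial_point(x0_init)

        def residuals(theta):
            model = _to_fit_space(self._theta_model(d, theta), self.fit_space)
            return model - c_obs

        sol = optimize.least_squares(
            residuals,
            theta0,
            bounds=(lower, upper),
            method="trf",
            ftol=_FTOL,
            xtol=_FTOL,
            gtol=_FTOL,
            max_nfev=_MAX_NFEV,
        )
        q, x0 = self._theta_params(sol.x)
        r2, rms = _goodness(c_obs, _to_fit_space(self._theta_model(d, sol.x), self.fit_space))
        converged = bool(sol.status > 0 and np.isfinite(rms))
        self.result_ = FitResult(
            params=QParams(q=q, x0=x0),
            r_squared=r2,
            rms=rms,
            n=ccdf.n,
            fit_space=self.fit_space,
            converged=converged,
            model=self._model_name,
            n_points=d.size,
        )
        self.q_ = q
        self.x0_ = x0
        self.r_squared_ = r2
        self.rms_ = rms
        self.n_ = ccdf.n
        self.converged_ = converged
        self.ccdf_ = ccdf
        return self

    # hooks overridden by the exponential (q pinned to 1) variant
    def _initial_point(self, x0_init):
        qlo, qhi = self.q_bounds
        xlo, xhi = self.x0_bounds
        q0 = min(max(self.q_init, qlo), qhi)
        x00 = min(max(x0_init, xlo), 1e12 if np.isinf(xhi) else xhi)
        return [q0, x00], [qlo, xlo], [qhi, xhi]

    def _theta_model(self, d, theta):
        return _model_values(d, theta[0], theta[1], self.offset)

    def _theta_params(self, theta):
        return float(theta[0]), float(theta[1])

    # -- prediction -------------------------------------------------------

    def predict(self, X):
        """Model CCDF values at the given distances."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit must be called before predict")
        d = np.asarray(X, dtype=float)
        if d.ndim == 2 and d.shape[1] == 1:
            d = d.ravel()
        return _model_values(d, self.q_, self.x0_, self.offset)


class ExponentialFitter(QExponentialFitter):
    """Exponential-null variant: the same machinery with q pinned at 1.

    This is the model random (shuffled or i.i.d.) sequences obey; comparing
    its residuals with the free-q fit's quantifies how non-random a word's
    placement is.
    """

    _model_name = "exponential"

    def _initial_point(self, x0_init):
        xlo, xhi = self.x0_bounds
        return [min(max(x0_init, xlo), 1e12 if np.isinf(xhi) else xhi)], [xlo], [xhi]

    def _theta_model(self, d, theta):
        return _model_values(d, 1.0, theta[0], self.offset)

    def _theta_params(self, theta):
        return 1.0, float(theta[0])


def fit_q_exponential(
    ccdf: EmpiricalCCDF,
    init: QParams | None = None,
    q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
    x0_bounds: tuple[float, float] = DEFAULT_X0_BOUNDS,
    fit_space: str = "linear",
    offset: float = 1.0,
) -> FitResult:
    """Fit the q-exponential survival curve to an empirical CCDF."""
    fitter = QExponentialFitter(
        q_bounds=q_bounds,
        x0_bounds=x0_bounds,
        q_init=init.q if init is not None else DEFAULT_Q_INIT,
        fit_space=fit_space,
        offset=offset,
    )
    if init is not None:
        fitter._forced_x0_init = init.x0
        fitter.fit_ccdf(ccdf)
        return fitter.result_
    return fitter.fit_ccdf(ccdf).result_


def fit_exponential(
    ccdf: EmpiricalCCDF,
    x0_bounds: tuple[float, float] = DEFAULT_X0_BOUNDS,
    fit_space: str = "linear",
    offset: float = 1.0,
) -> FitResult:
    """Fit the exponential (q=1) null survival curve."""
    return (
        ExponentialFitter(x0_bounds=x0_bounds, fit_space=fit_space, offset=offset)
        .fit_ccdf(ccdf)
        .result_
    )


def qlog_linearity(
    ccdf: EmpiricalCCDF, params: QParams, min_tail_count: int = 30
) -> QLogLinearity:
    """Linearity diagnostic: q-log-transform the CCDF and regress on d.

    Under a perfect Tsallis curve ``e_q(-d/x0)`` the transform ln_q with the
    fitted q turns the CCDF into the straight line ``-d/x0``, so an OLS
    R^2 near 1 confirms the q-exponential shape (and a wrong q bends the
    line).  Points where the transform is undefined are excluded and counted.

    The q-log amplifies the relative sampling error of small CCDF values by
    ``c**-q``, so extreme-tail points would drown the diagnostic in noise:
    points supported by fewer than ``min_tail_count`` observations
    (``c * n < min_tail_count``) are excluded as well (set 0 to keep all).
    """
    d = ccdf.distances.astype(float)
    c = ccdf.values
    usable = (c > 0) & (c * ccdf.n >= min_tail_count)
    if not usable.any():
        usable = c > 0
    n_excluded = int((~usable).sum())
    y = np.asarray(q_logarithm(c[usable], params.q))
    finite = np.isfinite(y)
    n_excluded += int((~finite).sum())
    y, x = y[finite], d[usable][finite]
    if x.size < 2:
        raise ValueError("need at least two usable points for the q-log diagnostic")
    res = stats.linregress(x, y)
    return QLogLinearity(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
        n_excluded=n_excluded,
    )
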