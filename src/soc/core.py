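"""Second-order causal direction estimation for a bivariate time series.

The model under comparison is an instantaneous linear structural equation
between two jointly stationary, autocorrelated variables:

    model 1:  y_t = alpha * x_t + d_t      (x causes y)
    model 2:  x_t = alpha * y_t + e_t      (y causes x)

where the regressor and the disturbance have *different* autocorrelation
functions.  Working with windows of length L taken from the (standardized)
series, the Gaussian mutual information between the regressor windows and
the residual windows is computed from log-determinants of window
covariances.  The decision criterion is

    C = 2 I(x, d) - 2 I(y, e)

and the direction is x -> y when C < 0, y -> x when C > 0: in the true
model the residual is independent of the regressor, so its mutual
information term vanishes, while in the reversed model it does not
(whenever the regressor and noise autocorrelations differ at some lag).
Only covariances enter the criterion, so the method applies to
non-Gaussian data as well; non-Gaussianity affects higher moments only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import toeplitz

X_TO_Y = "x_to_y"
Y_TO_X = "y_to_x"
UNDETERMINED = "undetermined"

_LOG_2PI = math.log(2.0 * math.pi)


class ZeroVarianceError(ValueError):
    """Raised when a series is constant and cannot be standardized."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested windowing."""


class NumericalSingularityError(ArithmeticError):
    """Raised when a covariance stays singular after ridge escalation."""


def flip_direction(direction: str) -> str:
    if direction == X_TO_Y:
        return Y_TO_X
    if direction == Y_TO_X:
        return X_TO_Y
    return UNDETERMINED


@dataclass(frozen=True)
class WindowSet:
    """Fixed-length window instances of one variable (m instances x L points)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("WindowSet values must be a 2-D (m x L) array")
        if v.shape[0] < 2:
            raise InsufficientDataError("a WindowSet needs at least 2 instances")
        if v.shape[1] < 1:
            raise ValueError("window length must be >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("WindowSet values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def window_length(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CovarianceEstimate:
    """A (possibly regularized) window covariance matrix."""

    matrix: np.ndarray
    ridge_used: float = 0.0
    toeplitz_projected: bool = False

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DecisionResult:
    """Outcome of a pairwise direction decision.

    ``criterion_C`` is in nats; negative values favour x -> y, positive
    values y -> x, matching the sign convention of the second-order
    criterion.  Baseline detectors map their own statistics onto the same
    convention.
    """

    criterion_C: float
    direction: str
    alpha_hat: float
    mi_x_d: float
    mi_y_e: float
    method: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "criterion_C": self.criterion_C,
            "direction": self.direction,
            "alpha_hat": self.alpha_hat,
            "mi_x_d": self.mi_x_d,
            "mi_y_e": self.mi_y_e,
            "method": self.method,
            "config": dict(self.config),
        }


@dataclass(frozen=True)
class SOCConfig:
    """Tunable parameters of the second-order decision pipeline.

    window_length : int
        Window length L (samples).  Short windows keep many instances per
        series; the default 5 already spans several lags of typical AR
        regressors.
    stride : int or None
        Offset between window starts.  ``None`` selects non-overlapping
        windows (stride = L) and falls back to stride 1 when the series is
        too short to yield ``m_min`` non-overlapping windows.  An explicit
        stride is used as given.
    ridge : float
        Relative ridge added to covariance diagonals before factorization,
        escalated by factors of 10 up to ``ridge_max`` on failure.
    toeplitz : bool
        If True, project window covariances onto Toeplitz structure
        (diagonal averaging) before use; off by default.
    tie_tol : float
        |C| at or below this returns an undetermined direction.
    """

    window_length: int = 5
    stride: Optional[int] = None
    ridge: float = 1e-6
    ridge_max: float = 1e-2
    toeplitz: bool = False
    tie_tol: float = 1e-12

    @property
    def m_min(self) -> int:
        return max(20, 10 * self.window_length)

    def to_dict(self) -> dict:
        return {
            "window_length": self.window_length,
            "stride": self.stride,
            "ridge": self.ridge,
            "ridge_max": self.ridge_max,
            "toeplitz": self.toeplitz,
            "tie_tol": self.tie_tol,
        }


def standardize(series: np.ndarray) -> np.ndarray:
    """Center and scale a series to mean 0, population variance 1."""
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("standardize expects a 1-D series of length >= 2")
    if not np.all(np.isfinite(s)):
        raise ValueError("series contains non-finite values")
    mu = s.mean()
    sd = s.std()  # population divisor
    if sd == 0.0 or not np.isfinite(sd):
        raise ZeroVarianceError("cannot standardize a constant series")
    return (s - mu) / sd


def standardize_instances(matrix: np.ndarray) -> np.ndarray:
    """Standardize each time index across instances (rows = instances)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 instances")
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    if np.any(sd == 0.0):
        raise ZeroVarianceError("a time index is constant across instances")
    return (m - mu) / sd


def build_window_set(series: np.ndarray, window_length: int, stride: int) -> WindowSet:
    """Cut a series into windows starting at 0, stride, 2*stride, ...

    A trailing partial window is discarded.  The same offsets must be used
    for the paired variable so that window rows stay aligned in time.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1:
        raise ValueError("series must be 1-D")
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    n = s.size
    starts = np.arange(0, n - window_length + 1, stride)
    if starts.size < 2:
        raise InsufficientDataError(
            f"series of length {n} yields {starts.size} complete windows "
            f"(L={window_length}, stride={stride}); need >= 2"
        )
    rows = np.stack([s[i : i + window_length] for i in starts])
    return WindowSet(rows)


def estimate_alpha(wx: WindowSet, wy: WindowSet) -> float:
    """Pooled lag-0 regression coefficient of y on x over all window entries.

    With both variables standardized this equals the pooled lag-0
    correlation, which is the single coefficient shared by the two
    candidate directions.
    """
    _check_aligned(wx, wy)
    x = wx.values.ravel()
    y = wy.values.ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    varx = float(xc @ xc)
    if varx == 0.0:
        raise ZeroVarianceError("x windows have zero pooled variance")
    return float(xc @ yc) / varx


def pooled_correlation(wx: WindowSet, wy: WindowSet) -> float:
    """Pooled lag-0 Pearson correlation over all aligned window entries.

    Symmetric in its arguments, which makes the downstream criterion
    exactly antisymmetric under argument swap.
    """
    _check_aligned(wx, wy)
    x = wx.values.ravel()
    y = wy.values.ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ZeroVarianceError("zero pooled variance in correlation")
    return float(xc @ yc) / denom


def residual_windows(wcause: WindowSet, weffect: WindowSet, alpha: float) -> WindowSet:
    """Entry-wise residual effect - alpha * cause (not re-standardized)."""
    _check_aligned(wcause, weffect)
    return WindowSet(weffect.values - alpha * wcause.values)


def _toeplitz_project(c: np.ndarray) -> np.ndarray:
    L = c.shape[0]
    first = np.array([np.mean(np.diagonal(c, k)) for k in range(L)])
    return toeplitz(first)


def window_covariance(ws: WindowSet, ridge: float = 0.0, toeplitz_proj: bool = False) -> CovarianceEstimate:
    """L x L sample covariance across window instances (divisor m).

    Optionally projects onto Toeplitz structure (stationarity) by
    averaging along diagonals, then adds ridge * mean(diag) to the
    diagonal.
    """
    v = ws.values
    c = np.atleast_2d(np.cov(v, rowvar=False, bias=True))
    if toeplitz_proj:
        c = _toeplitz_project(c)
    ridge_abs = 0.0
    if ridge > 0.0:
        ridge_abs = ridge * float(np.mean(np.diag(c)))
        c = c + ridge_abs * np.eye(c.shape[0])
    return CovarianceEstimate(c, ridge_used=ridge_abs, toeplitz_projected=toeplitz_proj)


def joint_covariance(wa: WindowSet, wb: WindowSet, ridge: float = 0.0) -> CovarianceEstimate:
    """2L x 2L covariance of row-wise concatenated windows [a; b]."""
    _check_aligned(wa, wb)
    v = np.concatenate([wa.values, wb.values], axis=1)
    c = np.atleast_2d(np.cov(v, rowvar=False, bias=True))
    ridge_abs = 0.0
    if ridge > 0.0:
        ridge_abs = ridge * float(np.mean(np.diag(c)))
        c = c + ridge_abs * np.eye(c.shape[0])
    return CovarianceEstimate(c, ridge_used=ridge_abs)


def logdet_psd(matrix: np.ndarray) -> float:
    """log-determinant via Cholesky; raises if not positive definite."""
    try:
        chol = np.linalg.cholesky(matrix)
    except np.linalg.LinAlgError as exc:
        raise NumericalSingularityError(
            "covariance matrix is not positive definite"
        ) from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def gaussian_entropy(cov: CovarianceEstimate | np.ndarray) -> float:
    """Differential entropy of a Gaussian with the given covariance, in nats.

    h = (1/2) logdet(cov) + (dim/2) (1 + log 2 pi).
    """
    m = cov.matrix if isinstance(cov, CovarianceEstimate) else np.asarray(cov, dtype=float)
    dim = m.shape[0]
    return 0.5 * logdet_psd(m) + 0.5 * dim * (1.0 + _LOG_2PI)


def mutual_information_from_cov(
    cov_a: np.ndarray, cov_b: np.ndarray, cov_joint: np.ndarray
) -> float:
    """Gaussian MI in nats from marginal and joint covariance matrices.

    I = (1/2) [logdet cov(a) + logdet cov(b) - logdet cov([a;b])];
    the (dim/2)(1 + log 2 pi) entropy constants cancel.
    """
    return 0.5 * (logdet_psd(cov_a) + logdet_psd(cov_b) - logdet_psd(cov_joint))


def _mi_windows(wa: WindowSet, wb: WindowSet, ridge: float, toeplitz_proj: bool = False) -> float:
    """Plug-in Gaussian MI between two aligned window sets.

    The joint covariance is ridged once, and the marginal covariances are
    read off its diagonal blocks, so the same absolute ridge applies to
    marginals and joint.  Fischer's inequality then guarantees the
    plug-in MI is nonnegative up to rounding.
    """
    _check_aligned(wa, wb)
    la = wa.window_length
    joint = joint_covariance(wa, wb, ridge=0.0).matrix
    if toeplitz_proj:
        joint[:la, :la] = _toeplitz_project(joint[:la, :la])
        joint[la:, la:] = _toeplitz_project(joint[la:, la:])
    if ridge > 0.0:
        joint = joint + ridge * float(np.mean(np.diag(joint))) * np.eye(joint.shape[0])
    return mutual_information_from_cov(joint[:la, :la], joint[la:, la:], joint)


def gaussian_mutual_information(
    wa: WindowSet, wb: WindowSet, ridge: float = 1e-6
) -> float:
    """Gaussian mutual information between two aligned window sets (nats)."""
    return _mi_windows(wa, wb, ridge)


def _check_aligned(wa: WindowSet, wb: WindowSet) -> None:
    if wa.values.shape != wb.values.shape:
        raise ValueError(
            f"window sets are not aligned: {wa.values.shape} vs {wb.values.shape}"
        )


def _prepare_windows(series: np.ndarray, config: SOCConfig) -> WindowSet:
    """Standardize and window one variable according to the config.

    1-D input: global standardization, then windowing.  2-D input
    (instances x time): each time index is standardized across instances
    and every instance row is windowed with the same offsets.
    """
    s = np.asarray(series, dtype=float)
    L = config.window_length
    if s.ndim == 1:
        z = standardize(s)
        if config.stride is not None:
            return build_window_set(z, L, config.stride)
        ws = None
        try:
            ws = build_window_set(z, L, L)
        except InsufficientDataError:
            pass
        if ws is None or ws.n_instances < config.m_min:
            # short series: overlap windows rather than refuse outright
            ws = build_window_set(z, L, 1)
        return ws
    if s.ndim == 2:
        z = standardize_instances(s)
        stride = config.stride if config.stride is not None else L
        rows = []
        for row in z:
            starts = np.arange(0, row.size - L + 1, stride)
            rows.extend(row[i : i + L] for i in starts)
        if len(rows) < 2:
            raise InsufficientDataError("instances too short for the window length")
        return WindowSet(np.stack(rows))
    raise ValueError("series must be 1-D or 2-D (instances x time)")


def soc_decide(
    x: np.ndarray, y: np.ndarray, config: Optional[SOCConfig] = None
) -> DecisionResult:
    """Decide the instantaneous causal direction between two series.

    Pipeline: standardize both variables, cut both into windows with
    shared offsets, estimate the shared coupling coefficient as the
    pooled lag-0 correlation, form residuals d = y - a x and e = x - a y,
    and evaluate C = 2 I(x, d) - 2 I(y, e).  C < 0 decides x -> y,
    C > 0 decides y -> x, |C| <= tie_tol is undetermined.
    """
    cfg = config or SOCConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    wx = _prepare_windows(x, cfg)
    wy = _prepare_windows(y, cfg)
    if wx.n_instances < cfg.m_min:
        raise InsufficientDataError(
            f"only {wx.n_instances} windows available; need >= {cfg.m_min} "
            f"(L={cfg.window_length})"
        )

    alpha = pooled_correlation(wx, wy)
    wd = residual_windows(wx, wy, alpha)
    we = residual_windows(wy, wx, alpha)

    ridge = cfg.ridge
    last_error: Optional[Exception] = None
    mi_xd = mi_ye = None
    while ridge <= cfg.ridge_max:
        try:
            mi_xd = _mi_windows(wx, wd, ridge, cfg.toeplitz)
            mi_ye = _mi_windows(wy, we, ridge, cfg.toeplitz)
            break
        except NumericalSingularityError as exc:
            last_error = exc
            ridge *= 10.0
    if mi_xd is None or mi_ye is None:
        raise NumericalSingularityError(
            "window covariances remain singular after ridge escalation"
        ) from last_error

    criterion = 2.0 * mi_xd - 2.0 * mi_ye
    if criterion < -cfg.tie_tol:
        direction = X_TO_Y
    elif criterion > cfg.tie_tol:
        direction = Y_TO_X
    else:
        direction = UNDETERMINED
    return DecisionResult(
        criterion_C=criterion,
        direction=direction,
        alpha_hat=alpha,
        mi_x_d=mi_xd,
        mi_y_e=mi_ye,
        method="soc",
        config={**cfg.to_dict(), "ridge_final": ridge},
    )
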