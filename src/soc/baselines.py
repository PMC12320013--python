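"""Reference direction detectors: pairwise LiNGAM and bivariate Granger.

Both baselines report their statistic through the shared ``DecisionResult``
container with the sign convention of the second-order criterion: a
negative ``criterion_C`` decides x -> y.

Pairwise LiNGAM infers direction from non-Gaussianity via the
likelihood-ratio statistic R = rho * E[x g(y) - g(x) y] with g = tanh
(a cumulant variant with g-terms x^3 y - x y^3 is available for
sensitivity checks); R > 0 decides x -> y.  Granger causality fits a
bivariate VAR with the order selected by AIC and compares the
log-variance-ratio statistics of the two targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    UNDETERMINED,
    X_TO_Y,
    Y_TO_X,
    DecisionResult,
    ZeroVarianceError,
    standardize,
)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class GrangerFit:
    """Residual variances of the full and own-lags-only VAR equations."""

    order_p: int
    aic: float
    resid_var_full_xy: float  # target y, predictors: lags of x and y
    resid_var_restricted_xy: float  # target y, predictors: lags of y only
    resid_var_full_yx: float
    resid_var_restricted_yx: float

    @property
    def gc_x_to_y(self) -> float:
        return float(np.log(self.resid_var_restricted_xy / self.resid_var_full_xy))

    @property
    def gc_y_to_x(self) -> float:
        return float(np.log(self.resid_var_restricted_yx / self.resid_var_full_yx))


def pwlingam_decide(
    x: np.ndarray, y: np.ndarray, nonlinearity: str = "tanh"
) -> DecisionResult:
    """Pairwise LiNGAM likelihood-ratio direction decision."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    xs = standardize(x)
    ys = standardize(y)
    rho = float(np.mean(xs * ys))
    if nonlinearity == "tanh":
        stat = rho * float(np.mean(xs * np.tanh(ys) - np.tanh(xs) * ys))
    elif nonlinearity == "cube":
        stat = rho * float(np.mean(xs**3 * ys - xs * ys**3))
    else:
        raise ValueError(f"unknown nonlinearity: {nonlinearity!r}")
    criterion = -stat  # negative ⇒ x -> y, matching the shared convention
    if criterion < -_TIE_TOL:
        direction = X_TO_Y
    elif criterion > _TIE_TOL:
        direction = Y_TO_X
    else:
        direction = UNDETERMINED
    return DecisionResult(
        criterion_C=criterion,
        direction=direction,
        alpha_hat=rho,
        mi_x_d=np.nan,
        mi_y_e=np.nan,
        method="pwlingam",
        config={"nonlinearity": nonlinearity},
    )


def _lag_matrix(z: np.ndarray, p: int, n_eff: int) -> np.ndarray:
    """Columns z_{t-1}, ..., z_{t-p} for the last n_eff time points."""
    n = z.size
    return np.column_stack([z[n - n_eff - k : n - k] for k in range(1, p + 1)])


def _ols_resid_var(target: np.ndarray, design: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(resid @ resid) / target.size


def fit_granger(x: np.ndarray, y: np.ndarray, p_max: int = 10) -> GrangerFit:
    """Fit bivariate VAR with AIC order selection; per-equation OLS.

    All candidate orders are fit on the same effective sample (the last
    n - p_max points) so their AICs are comparable.  AIC uses the full
    model's Gaussian log-likelihood: n_eff * log det(Sigma) + 2k with k
    the total parameter count of both equations.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    x = standardize(np.asarray(x, dtype=float))
    y = standardize(np.asarray(y, dtype=float))
    n = x.size
    n_eff = n - p_max
    if n_eff <= 10 * p_max:
        raise ValueError("series too short for the requested p_max")

    ones = np.ones((n_eff, 1))
    xt = x[-n_eff:]
    yt = y[-n_eff:]
    best = None
    for p in range(1, p_max + 1):
        lx = _lag_matrix(x, p, n_eff)
        ly = _lag_matrix(y, p, n_eff)
        full = np.hstack([ones, lx, ly])
        coef_x, _, _, _ = np.linalg.lstsq(full, xt, rcond=None)
        coef_y, _, _, _ = np.linalg.lstsq(full, yt, rcond=None)
        rx = xt - full @ coef_x
        ry = yt - full @ coef_y
        sigma = np.cov(np.vstack([rx, ry]), bias=True)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            raise ArithmeticError("degenerate residual covariance in VAR fit")
        k = 2 * (2 * p + 1)
        aic = n_eff * logdet + 2 * k
        if best is None or aic < best[0]:
            best = (aic, p)
    aic, p = best

    lx = _lag_matrix(x, p, n_eff)
    ly = _lag_matrix(y, p, n_eff)
    full = np.hstack([ones, lx, ly])
    var_full_xy = _ols_resid_var(yt, full)  # y on lags of both
    var_full_yx = _ols_resid_var(xt, full)
    var_restr_xy = _ols_resid_var(yt, np.hstack([ones, ly]))  # y on own lags
    var_restr_yx = _ols_resid_var(xt, np.hstack([ones, lx]))
    if min(var_full_xy, var_full_yx) <= 0:
        raise ArithmeticError("zero residual variance in VAR fit")
    return GrangerFit(
        order_p=p,
        aic=aic,
        resid_var_full_xy=var_full_xy,
        resid_var_restricted_xy=var_restr_xy,
        resid_var_full_yx=var_full_yx,
        resid_var_restricted_yx=var_restr_yx,
    )


def granger_decide(x: np.ndarray, y: np.ndarray, p_max: int = 10) -> DecisionResult:
    """Bivariate Granger direction decision: the larger GC statistic wins."""
    fit = fit_granger(x, y, p_max=p_max)
    gc_xy = fit.gc_x_to_y
    gc_yx = fit.gc_y_to_x
    criterion = gc_yx - gc_xy  # negative ⇒ x -> y
    if criterion < -_TIE_TOL:
        direction = X_TO_Y
    elif criterion > _TIE_TOL:
        direction = Y_TO_X
    else:
        direction = UNDETERMINED
    return DecisionResult(
        criterion_C=criterion,
        direction=direction,
        alpha_hat=np.nan,
        mi_x_d=gc_xy,
        mi_y_e=gc_yx,
        method="granger",
        config={"p_max": p_max, "order_p": fit.order_p},
    )
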