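"""Closed-form population quantities for the AR pair model.

For a regressor x following a stationary AR process and a disturbance d
following another AR process, with instantaneous coupling y = alpha*x + d,
all window covariances of the *standardized* variables are Toeplitz
matrices built from the processes' autocorrelation functions.  This gives
the population value of the decision criterion without any sampling:

    rho   = alpha * sigma_x / sigma_y          (lag-0 correlation)
    Rx    = Toeplitz(acf_x),  Rd = Toeplitz(acf_d)
    Ry    = rho^2 Rx + (1 - rho^2) Rd
    cov(d~) = (1 - rho^2) Rd                  residual of the true model
    cov(e~) = (1-rho^2) [ (1-rho^2) Rx + rho^2 Rd ]
    cross(x~, d~) = 0
    cross(y~, e~) = rho (1 - rho^2) (Rx - Rd)

so I(x, d) = 0 exactly and C = -2 I(y, e) <= 0 for the true direction,
with equality if and only if the regressor and the noise share the same
autocorrelation function (the identifiability boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz
from statsmodels.tsa.arima_process import arma_acf, arma_acovf

from .core import mutual_information_from_cov


def ar_autocorrelation(coefficients, lags: int) -> np.ndarray:
    """Autocorrelation function of a stationary AR process at lags 0..lags-1."""
    ar = np.r_[1.0, -np.asarray(coefficients, dtype=float)]
    return arma_acf(ar, np.array([1.0]), lags=lags)


def ar_variance(coefficients, innovation_scale: float = 1.0) -> float:
    """Stationary variance of an AR process with the given innovation scale."""
    ar = np.r_[1.0, -np.asarray(coefficients, dtype=float)]
    return float(arma_acovf(ar, np.array([1.0]), nobs=1, sigma2=innovation_scale**2)[0])


@dataclass(frozen=True)
class PopulationPair:
    """Population window covariances of the standardized coupled pair."""

    rho: float
    Rx: np.ndarray
    Rd: np.ndarray

    @property
    def Ry(self) -> np.ndarray:
        r2 = self.rho**2
        return r2 * self.Rx + (1.0 - r2) * self.Rd

    def residual_cov_true(self) -> np.ndarray:
        return (1.0 - self.rho**2) * self.Rd

    def residual_cov_reverse(self) -> np.ndarray:
        r2 = self.rho**2
        return (1.0 - r2) * ((1.0 - r2) * self.Rx + r2 * self.Rd)

    def cross_true(self) -> np.ndarray:
        return np.zeros_like(self.Rx)

    def cross_reverse(self) -> np.ndarray:
        return self.rho * (1.0 - self.rho**2) * (self.Rx - self.Rd)


def population_pair(
    regressor_coefficients,
    noise_coefficients,
    alpha: float,
    window_length: int,
    regressor_scale: float = 1.0,
    noise_scale: float = 1.0,
) -> PopulationPair:
    """Population covariance description of the coupled AR pair."""
    L = window_length
    Rx = toeplitz(ar_autocorrelation(regressor_coefficients, L))
    Rd = toeplitz(ar_autocorrelation(noise_coefficients, L))
    var_x = ar_variance(regressor_coefficients, regressor_scale)
    var_d = ar_variance(noise_coefficients, noise_scale)
    var_y = alpha**2 * var_x + var_d
    rho = alpha * np.sqrt(var_x / var_y)
    return PopulationPair(rho=float(rho), Rx=Rx, Rd=Rd)


def _mi_from_blocks(ca: np.ndarray, cb: np.ndarray, cross: np.ndarray) -> float:
    joint = np.block([[ca, cross], [cross.T, cb]])
    return mutual_information_from_cov(ca, cb, joint)


def analytic_criterion(
    regressor_coefficients,
    noise_coefficients,
    alpha: float,
    window_length: int = 5,
    regressor_scale: float = 1.0,
    noise_scale: float = 1.0,
) -> float:
    """Population decision criterion C for the true direction x -> y (nats).

    Negative whenever the regressor and noise autocorrelations differ at
    some lag within the window; exactly zero on the identifiability
    boundary where they coincide.
    """
    pop = population_pair(
        regressor_coefficients,
        noise_coefficients,
        alpha,
        window_length,
        regressor_scale,
        noise_scale,
    )
    mi_xd = _mi_from_blocks(pop.Rx, pop.residual_cov_true(), pop.cross_true())
    mi_ye = _mi_from_blocks(pop.Ry, pop.residual_cov_reverse(), pop.cross_reverse())
    return 2.0 * mi_xd - 2.0 * mi_ye
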