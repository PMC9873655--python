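"""The two competing envelope-spectrum models and their Bayesian setup.

A recording's band-limited envelope spectrum is explained either by a
long-range fractal law

    S(f) = A f^(-beta) + gamma^2

or by a short-memory ARMA(1,1)-type rational spectrum

    S(f) = A (1 + 2 theta cos(2 pi f tau) + theta^2)
             / (1 - 2 phi cos(2 pi f tau) + phi^2).

The measured spectrum is modelled as the chosen S(f) plus Gaussian scatter of
variance kappa*A, with kappa a fitted nuisance absorbing periodogram noise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

log = logging.getLogger(__name__)

#: Dynamic range of the log-uniform priors on A (relative to the data scale)
#: and on the dimensionless noise multiplier kappa.
LOGU_LO = 1e-6
LOGU_HI = 1e6

BETA_RANGE = (0.0, 4.0)
GAMMA_RANGE = (0.0, 10.0)
THETA_RANGE = (-2.0, 2.0)
PHI_RANGE = (0.0, 1.0)
TAU_RANGE = (0.0, 100.0)  # seconds; 1/tau stays above the 0.01 Hz band edge

#: Floor applied to the ARMA denominator at its removable singularity
#: (phi = 1 with the cosine at 1); keeps the spectrum finite.
_DENOM_FLOOR = 1e-12


@dataclass
class FractalParams:
    """Parameters of the fractal (power-law) spectrum."""

    A: float  # amplitude, power units
    beta: float  # spectral index
    gamma: float  # sqrt of the high-frequency white offset
    kappa: float = 1.0  # noise variance = kappa * A

    def validate(self) -> None:
        if self.A <= 0 or self.kappa <= 0:
            raise DomainError("A and kappa must be positive")
        if not BETA_RANGE[0] <= self.beta <= BETA_RANGE[1]:
            raise DomainError(f"beta outside {BETA_RANGE}")
        if not GAMMA_RANGE[0] <= self.gamma <= GAMMA_RANGE[1]:
            raise DomainError(f"gamma outside {GAMMA_RANGE}")


@dataclass
class ARMAParams:
    """Parameters of the short-memory rational spectrum."""

    A: float  # amplitude, power units
    theta: float  # oscillatory-strength (moving-average) parameter
    phi: float  # memory (autoregressive) parameter
    tau: float  # model timescale, seconds
    kappa: float = 1.0

    def validate(self) -> None:
        if self.A <= 0 or self.kappa <= 0:
            raise DomainError("A and kappa must be positive")
        if not THETA_RANGE[0] <= self.theta <= THETA_RANGE[1]:
            raise DomainError(f"theta outside {THETA_RANGE}")
        if not PHI_RANGE[0] <= self.phi <= PHI_RANGE[1]:
            raise DomainError(f"phi outside {PHI_RANGE}")
        if not TAU_RANGE[0] <= self.tau <= TAU_RANGE[1]:
            raise DomainError(f"tau outside {TAU_RANGE}")


def fractal_psd(f, params: FractalParams):
    """Evaluate A f^-beta + gamma^2. Requires f > 0 when beta > 0."""
    f = np.asarray(f, dtype=float)
    if params.beta > 0 and np.any(f <= 0):
        raise DomainError("fractal_psd needs f > 0 when beta > 0")
    return params.A * f ** (-params.beta) + params.gamma**2


def arma_psd(f, params: ARMAParams, denominator: str = "corrected"):
    """Evaluate the rational short-memory spectrum.

    ``denominator='corrected'`` (default) uses 1 - 2 phi cos(2 pi f tau) + phi^2,
    the standard ARMA(1,1) form, which is >= (1-phi)^2 >= 0 for all phi in
    [0, 1]. ``'as_printed'`` substitutes theta for phi inside the cosine term,
    which can go negative for |theta| > 1 and is provided only for sensitivity
    checks.
    """
    f = np.asarray(f, dtype=float)
    c = np.cos(2 * np.pi * f * params.tau)
    num = 1 + 2 * params.theta * c + params.theta**2
    if denominator == "corrected":
        den = 1 - 2 * params.phi * c + params.phi**2
    elif denominator == "as_printed":
        den = 1 - 2 * params.theta * c + params.phi**2
    else:
        raise DomainError(f"unknown denominator convention {denominator!r}")
    small = den < _DENOM_FLOOR
    if np.any(small):
        log.warning(
            "arma_psd denominator hit its floor at %d frequencies; capping", int(np.sum(small))
        )
        den = np.maximum(den, _DENOM_FLOOR)
    return params.A * num / den


def log_likelihood(data_powers, model_values, A: float, kappa: float) -> float:
    """Gaussian log-likelihood of the spectrum with variance kappa*A per bin."""
    var = kappa * A
    if var <= 0:
        raise DomainError("kappa * A must be positive")
    data = np.asarray(data_powers, dtype=float)
    model = np.asarray(model_values, dtype=float)
    if data.shape != model.shape:
        raise DomainError("model and data lengths differ")
    resid = data - model
    n = data.size
    return float(-0.5 * n * np.log(2 * np.pi * var) - resid.dot(resid) / (2 * var))


def _logu(u: float, lo: float, hi: float) -> float:
    return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))


def _check_cube(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise DomainError("unit-cube coordinates must lie in [0, 1]")
    return u


def prior_transform_fractal(u, data_scale: float = 1.0) -> FractalParams:
    """Map a unit-cube point to fractal parameters under the stated priors.

    A is log-uniform over 12 decades centred (geometrically) on ``data_scale``
    so the bracket contains the maximum-likelihood amplitude for any input;
    beta is uniform on [0, 4]; gamma uniform on [0, 10]; kappa log-uniform with
    the same dynamic range as A's dimensionless factor.
    """
    u = _check_cube(u)
    if u.shape != (4,):
        raise DomainError("fractal prior transform expects 4 coordinates")
    return FractalParams(
        A=data_scale * _logu(u[0], LOGU_LO, LOGU_HI),
        beta=BETA_RANGE[0] + u[1] * (BETA_RANGE[1] - BETA_RANGE[0]),
        gamma=GAMMA_RANGE[0] + u[2] * (GAMMA_RANGE[1] - GAMMA_RANGE[0]),
        kappa=data_scale * _logu(u[3], LOGU_LO, LOGU_HI),
    )


def prior_transform_arma(u, data_scale: float = 1.0) -> ARMAParams:
    """Map a unit-cube point to ARMA parameters under the stated priors.

    theta is uniform on [-2, 2] (a precedent-based bracket whose edges are
    never favoured), phi uniform on [0, 1], tau uniform on [0, 100] s so the
    generating process acts at least as fast as the lowest analysed frequency.
    """
    u = _check_cube(u)
    if u.shape != (5,):
        raise DomainError("ARMA prior transform expects 5 coordinates")
    return ARMAParams(
        A=data_scale * _logu(u[0], LOGU_LO, LOGU_HI),
        theta=THETA_RANGE[0] + u[1] * (THETA_RANGE[1] - THETA_RANGE[0]),
        phi=PHI_RANGE[0] + u[2] * (PHI_RANGE[1] - PHI_RANGE[0]),
        tau=TAU_RANGE[0] + u[3] * (TAU_RANGE[1] - TAU_RANGE[0]),
        kappa=data_scale * _logu(u[4], LOGU_LO, LOGU_HI),
    )
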