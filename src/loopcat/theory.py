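"""Analytic loop-catalysis theory.

The elastic free energy of a loop of contour ell and persistence length
l_p is F/kBT = eps_shape * l_p / ell with eps_shape a shape-dependent
numerical factor (2 pi^2 for a circle).  Integrating a circular element
of contour l_viral into a loop lengthens it, so the angular energy
change is approximately

    dU_angle/kBT = a/(ell + l_viral) - b/ell

with fitted length constants a, b.  Balancing the Boltzmann weight of
this gain against the probability of finding the loop (proportional to
ell) against integrating anywhere else (proportional to N - ell) gives
the in-loop fraction

    f_in(ell) = ell e^{-a/(ell+l_viral) + b/ell}
                / ( ell e^{-a/(ell+l_viral) + b/ell} + (N - ell) ).

All lengths on this side of the package are in base pairs; loop-length
independent contributions are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FinModelParams",
    "LoopEnergyParams",
    "CIRCLE_SHAPE_FACTOR",
    "loop_free_energy",
    "delta_u_model",
    "f_in_model",
    "FitResult",
    "fit_fin",
    "fit_delta_u",
]

CIRCLE_SHAPE_FACTOR = 2.0 * math.pi**2


@dataclass(frozen=True)
class FinModelParams:
    """Parameters of the in-loop fraction model (all lengths in bp)."""

    a: float
    b: float
    N: float           # substrate contour
    l_viral: float     # viral contour

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.l_viral) < 0 or self.N <= 0:
            raise ValueError("lengths must be non-negative and N positive")


@dataclass(frozen=True)
class LoopEnergyParams:
    shape_factor: float = CIRCLE_SHAPE_FACTOR
    l_p: float = 147.0     # bp by default; any unit consistent with ell

    def __post_init__(self) -> None:
        if self.shape_factor <= 0:
            raise ValueError("shape_factor must be positive")


def loop_free_energy(ell: float, params: LoopEnergyParams) -> float:
    """Elastic energy of looping an elastic rod: shape_factor * l_p / ell
    (ell and l_p in the same unit)."""
    if ell <= 0:
        raise ZeroDivisionError("loop length must be positive")
    return params.shape_factor * params.l_p / ell


def delta_u_model(ell, params: FinModelParams):
    """Angular energy change upon in-loop integration:
    a/(ell + l_viral) - b/ell, in kBT."""
    ell = np.asarray(ell, dtype=float)
    if np.any(ell <= 0):
        raise ZeroDivisionError("loop length must be positive")
    out = params.a / (ell + params.l_viral) - params.b / ell
    return float(out) if out.ndim == 0 else out


def f_in_model(ell, params: FinModelParams):
    """Fraction of integrations inside the looped region, in [0, 1]."""
    ell = np.asarray(ell, dtype=float)
    if np.any(ell <= 0):
        raise ZeroDivisionError("loop length must be positive")
    if np.any(ell > params.N):
        raise ValueError("loop length exceeds substrate length")
    w = ell * np.exp(-params.a / (ell + params.l_viral) + params.b / ell)
    out = w / (w + (params.N - ell))
    return float(out) if out.ndim == 0 else out


@dataclass
class FitResult:
    a: float
    b: float
    cov: np.ndarray            # 2x2 covariance of (a, b)
    residuals: np.ndarray
    success: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


_STARTS = [(100.0, 100.0), (600.0, 350.0), (1200.0, 150.0),
           (300.0, 800.0), (50.0, 30.0)]


def _multistart_fit(model, ell, y, sigma=None) -> FitResult:
    ell = np.asarray(ell, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(ell)) < 3:
        raise ValueError("need >= 3 distinct loop lengths")
    best = None
    for p0 in _STARTS:
        try:
            popt, pcov = curve_fit(model, ell, y, p0=p0, sigma=sigma,
                                   maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        res = y - model(ell, *popt)
        ssr = float(res @ res)
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov, res)
    if best is None:
        return FitResult(math.nan, math.nan, np.full((2, 2), math.nan),
                         np.full_like(y, math.nan), success=False)
    _, popt, pcov, res = best
    return FitResult(float(popt[0]), float(popt[1]), pcov, res,
                     success=True)


def fit_fin(ell_values, f_in_observed, N: float, l_viral: float,
            sigma=None) -> FitResult:
    """Nonlinear least squares of the f_in model with (a, b) free;
    l_viral is a known input, not a third parameter."""

    def model(ell, a, b):
        w = ell * np.exp(-a / (ell + l_viral) + b / ell)
        return w / (w + (N - ell))

    return _multistart_fit(model, ell_values, f_in_observed, sigma)


def fit_delta_u(ell_values, delta_u_observed, l_viral: float,
                sigma=None) -> FitResult:
    """Nonlinear least squares of dU(ell) = a/(ell + l_viral) - b/ell."""

    def model(ell, a, b):
        return a / (ell + l_viral) - b / ell

    return _multistart_fit(model, ell_values, delta_u_observed, sigma)
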