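"""Instrument-style viscoelasticity analytics with synthetic generators.

Reusable implementations of the standard bench analyses for soft-matrix
mechanics:

* Hertz spherical-indentation fit, ``F = (4/3)·E/(1−ν²)·√R·δ^{3/2}``,
  with grid-searched contact-point estimation;
* hysteresis area of a loading–unloading indentation cycle (viscous
  energy dissipation, nN·µm);
* loss tangent ``G″/G′`` of an oscillatory shear measurement;
* cell-shape circularity ``4π·A/P²``;
* relaxation half-time τ½ (shared with :mod:`fibrelax.rheometry`).

Synthetic generators produce force curves and relaxation records with
known ground truth for validating the estimators.

Units: δ in µm, F in nN, R in µm ⇒ 1 nN/µm² = 1 kPa, so fitted moduli
are converted to Pa explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .rheometry import RelaxationCurve, tau_half

log = logging.getLogger(__name__)

__all__ = [
    "ForceCurve", "OscillatorySweep", "ShapeContour",
    "hertz_fit", "hysteresis_area", "loss_tangent", "circularity",
    "synth_indentation", "synth_relaxation", "tau_half",
]


@dataclass
class ForceCurve:
    """Indent–retract force record: loading and unloading branches."""

    delta_load: np.ndarray     # µm, monotone increasing
    force_load: np.ndarray     # nN
    delta_unload: np.ndarray   # µm
    force_unload: np.ndarray   # nN
    tip_radius: float = 2.5    # µm (5 µm diameter sphere)
    poisson: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_load = np.asarray(self.delta_load, dtype=float)
        self.force_load = np.asarray(self.force_load, dtype=float)
        self.delta_unload = np.asarray(self.delta_unload, dtype=float)
        self.force_unload = np.asarray(self.force_unload, dtype=float)
        if np.any(self.delta_load < 0) or np.any(self.delta_unload < 0):
            raise ValueError("indentation depths must be non-negative")


@dataclass
class OscillatorySweep:
    """Single-frequency oscillatory shear readout."""

    omega: float      # rad/s
    g_storage: float  # Pa
    g_loss: float     # Pa

    def __post_init__(self) -> None:
        if self.g_storage <= 0:
            raise ValueError("storage modulus must be positive")
        if self.g_loss < 0:
            raise ValueError("loss modulus must be non-negative")


@dataclass
class ShapeContour:
    """Closed contour summarized by area (µm²) and perimeter (µm)."""

    area: float
    perimeter: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("area and perimeter must be positive")


class FitFailure(RuntimeError):
    """Raised when a force-curve fit cannot produce a physical modulus."""


def _hertz_coefficient(E_pa: float, nu: float, R: float) -> float:
    """Hertz prefactor A (nN/µm^1.5) such that F = A·δ^{3/2}."""
    return (4.0 / 3.0) * (E_pa * 1e-3 / (1.0 - nu**2)) * math.sqrt(R)


def hertz_fit(curve: ForceCurve, n_contact_grid: int = 50):
    """Fit the Hertz spherical-contact model to the loading branch.

    The contact point δ₀ is grid-searched over the lower half of the δ
    range; for each candidate, the amplitude of ``F = A (δ−δ₀)^{3/2}`` is
    solved in closed form by linear least squares and the candidate with
    the smallest residual wins.  Returns ``(E_pa, rms_residual_nN)``.
    """
    d = curve.delta_load
    F = curve.force_load
    if len(d) < 10:
        raise FitFailure("need >= 10 loading points")
    if np.all(F <= 0) or np.allclose(F, 0):
        raise FitFailure("degenerate (non-positive) loading branch")
    best = None
    for d0 in np.linspace(0.0, 0.5 * d.max(), n_contact_grid):
        mask = d > d0
        if mask.sum() < 10:
            continue
        x = (d[mask] - d0) ** 1.5
        y = F[mask]
        denom = float(x @ x)
        if denom == 0:
            continue
        A = float(x @ y) / denom
        if A <= 0:
            continue
        resid = float(np.sqrt(np.mean((y - A * x) ** 2)))
        if best is None or resid < best[0]:
            best = (resid, A, d0)
    if best is None:
        raise FitFailure("no admissible contact point found")
    resid, A, d0 = best
    E_pa = A * 1e3 * 0.75 * (1.0 - curve.poisson**2) / math.sqrt(
        curve.tip_radius)
    log.debug("hertz_fit: contact offset %.4f µm, residual %.3g nN", d0, resid)
    if E_pa <= 0:
        raise FitFailure("non-positive fitted modulus")
    return E_pa, resid


def hysteresis_area(curve: ForceCurve, n_grid: int = 500) -> float:
    """Energy dissipated per indent–retract cycle, nN·µm.

    Trapezoidal ``∫F dδ`` over the loading branch minus the unloading
    branch, both interpolated onto a common indentation grid.
    """
    lo = max(curve.delta_load.min(), curve.delta_unload.min())
    hi = min(curve.delta_load.max(), curve.delta_unload.max())
    if hi <= lo:
        raise ValueError("loading/unloading depth ranges do not overlap")
    grid = np.linspace(lo, hi, n_grid)
    iload = np.argsort(curve.delta_load)
    iunload = np.argsort(curve.delta_unload)
    f_load = np.interp(grid, curve.delta_load[iload],
                       curve.force_load[iload])
    f_unload = np.interp(grid, curve.delta_unload[iunload],
                         curve.force_unload[iunload])
    return float(np.trapezoid(f_load - f_unload, grid))


def loss_tangent(sweep: OscillatorySweep) -> float:
    """Loss tangent G″/G′ (dimensionless viscoelasticity index)."""
    return sweep.g_loss / sweep.g_storage


def circularity(shape: ShapeContour) -> float:
    """Shape circularity ``4π·area/perimeter²``, clipped to [0, 1].

    Equals 1 for a perfect circle; the isoperimetric inequality bounds
    true contours below 1 (tiny numerical excess is clipped and logged).
    """
    c = 4.0 * math.pi * shape.area / shape.perimeter**2
    if c > 1.0:
        log.info("circularity %.6f clipped to 1 (numerical excess)", c)
        c = 1.0
    return max(c, 0.0)


def synth_indentation(E_pa: float, dissipation: float = 0.0,
                      delta_max: float = 1.0, n: int = 200,
                      tip_radius: float = 2.5, poisson: float = 0.5,
                      rate: float = 1.0, noise_sd: float = 0.0,
                      rng: Optional[np.random.Generator] = None
                      ) -> ForceCurve:
    """Synthetic indent–retract force curve with known ground truth.

    Kelvin–Voigt-augmented Hertz response under a triangular depth
    schedule: ``F = A δ^{3/2} ± η·rate·√(R δ)`` with the ``+`` sign during
    loading (``η`` = ``dissipation``, nN·s/µm²).  ``noise_sd`` adds
    Gaussian force noise expressed as a fraction of the peak force.
    """
    if E_pa <= 0 or delta_max <= 0 or n < 10:
        raise ValueError("need positive modulus/depth and n >= 10")
    A = _hertz_coefficient(E_pa, poisson, tip_radius)
    d = np.linspace(0.0, delta_max, n)
    base = A * d**1.5
    visc = dissipation * rate * np.sqrt(tip_radius * d)
    f_load = base + visc
    f_unload = base - visc
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        scale = noise_sd * base.max()
        f_load = f_load + rng.normal(0.0, scale, size=n)
        f_unload = f_unload + rng.normal(0.0, scale, size=n)
    return ForceCurve(
        delta_load=d, force_load=f_load,
        delta_unload=d, force_unload=f_unload,
        tip_radius=tip_radius, poisson=poisson,
        meta={"E_pa": E_pa, "dissipation": dissipation,
              "noise_sd": noise_sd},
    )


def synth_relaxation(sigma_i, tau_i, sigma_inf: float = 0.0,
                     duration: float = 600.0, sample_dt: float = 0.1,
                     noise_sd: float = 0.0,
                     rng: Optional[np.random.Generator] = None
                     ) -> RelaxationCurve:
    """Prony-series relaxation record σ(t) = σ_∞ + Σ σᵢ e^{−t/τᵢ}.

    Emulates a rheometer stress-relaxation readout (600 s default).  The
    exact half-life of the noiseless normalized series is root-found and
    embedded as ground truth (``None`` when the floor σ_∞ keeps the
    normalized stress above 1/2).
    """
    sigma_i = np.atleast_1d(np.asarray(sigma_i, dtype=float))
    tau_i = np.atleast_1d(np.asarray(tau_i, dtype=float))
    if np.any(sigma_i <= 0) or np.any(tau_i <= 0) or sigma_inf < 0:
        raise ValueError("moduli and timescales must be positive")
    t = np.arange(0.0, duration + 0.5 * sample_dt, sample_dt)
    sig = sigma_inf + (sigma_i[None, :]
                       * np.exp(-t[:, None] / tau_i[None, :])).sum(axis=1)
    s0 = sig[0]

    def half(tt):
        return (sigma_inf + (sigma_i * np.exp(-tt / tau_i)).sum()) / s0 - 0.5

    truth = None
    if half(0.0) > 0 and sigma_inf / s0 < 0.5:
        hi = float(tau_i.max())
        while half(hi) > 0:
            hi *= 2.0
        truth = float(brentq(half, 0.0, hi))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        sig = sig + rng.normal(0.0, noise_sd * s0, size=len(t))
    return RelaxationCurve(
        times=t, stress=sig, valid=True,
        meta={"true_tau_half_s": truth, "sigma_inf": sigma_inf,
              "noise_sd": noise_sd},
    )
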