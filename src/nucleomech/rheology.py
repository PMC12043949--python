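"""Stress-relaxation and compression analysis of hydrogel substrates.

Alginate gels crosslinked covalently behave as nearly ideal elastic solids,
while ionic crosslinks exchange under load and dissipate stress.  Under a
constant compressive strain the stress of such a gel decays from its initial
value sigma_0 toward an equilibrium plateau.  The decay is modelled with a
two-element Maxwell-Wiechert solid: a spring (the plateau) in parallel with
two Maxwell arms, giving the biexponential

    sigma(t) = sigma_0 * (p + a1 * exp(-t / tau1) + a2 * exp(-t / tau2)),

with weights a1, a2 and plateau fraction p = 1 - a1 - a2, all in [0, 1].
The headline material parameter is the stress-relaxation half time tau_1/2:
the time under constant deformation at which the stress has fallen to half
its initial value.  It exists only when the plateau fraction is below 1/2.

The module also computes the initial elastic modulus as the slope of a
compression stress-strain ramp over the 5-10 % strain window, and normalizes
oscillatory frequency sweeps by the storage modulus at 1 rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DataError, InvalidParameterError

__all__ = [
    "RelaxationCurve",
    "MaxwellWiechertFit",
    "StressStrainCurve",
    "FrequencySweep",
    "mw_stress",
    "fit_relaxation",
    "half_time",
    "initial_modulus",
    "normalize_sweep",
]


@dataclass(frozen=True)
class RelaxationCurve:
    """Stress recorded over time while a compressive strain is held constant.

    Attributes
    ----------
    time : array, seconds, strictly increasing, starting at 0.
    stress : array, kPa.
    strain : the constant engineering strain held during relaxation.
    """

    time: np.ndarray
    stress: np.ndarray
    strain: float = 0.15

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "stress", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise DataError("time and stress must be equal-length 1-D arrays")
        if t.size < 10:
            raise DataError("relaxation curve needs at least 10 samples")
        if not np.all(np.diff(t) > 0) or t[0] < 0:
            raise DataError("time must be strictly increasing and start at t >= 0")
        if not np.all(np.isfinite(s)):
            raise DataError("stress contains non-finite values")


@dataclass(frozen=True)
class MaxwellWiechertFit:
    """Biexponential parameterization of a relaxation curve.

    ``tau_half`` is None when the plateau fraction is >= 0.5, i.e. the gel
    never relaxes to half its initial stress (the elastic, covalent case).
    """

    sigma0: float
    weights: tuple[float, float]
    taus: tuple[float, float]
    plateau: float
    tau_half: float | None
    residual_rmse: float

    def __post_init__(self):
        a1, a2 = self.weights
        for name, v in (("a1", a1), ("a2", a2), ("plateau", self.plateau)):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if abs(a1 + a2 + self.plateau - 1.0) > 1e-6:
            raise InvalidParameterError("weights and plateau must sum to 1")
        if min(self.taus) <= 0:
            raise InvalidParameterError("time constants must be positive")


@dataclass(frozen=True)
class StressStrainCurve:
    """Compression ramp: engineering strain (0-0.15) vs stress in kPa."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.strain, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", e)
        object.__setattr__(self, "stress", s)
        if e.shape != s.shape or e.ndim != 1:
            raise DataError("strain and stress must be equal-length 1-D arrays")
        if np.any(np.diff(e) < 0):
            raise DataError("strain must be nondecreasing")


@dataclass(frozen=True)
class FrequencySweep:
    """Oscillatory shear sweep: angular frequency vs storage/loss moduli."""

    omega: np.ndarray
    g_storage: np.ndarray
    g_loss: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.omega, dtype=float)
        gs = np.asarray(self.g_storage, dtype=float)
        gl = np.asarray(self.g_loss, dtype=float)
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "g_storage", gs)
        object.__setattr__(self, "g_loss", gl)
        if not (w.shape == gs.shape == gl.shape) or w.ndim != 1:
            raise DataError("omega, g_storage, g_loss must be equal-length 1-D arrays")
        if np.any(w <= 0):
            raise DataError("angular frequencies must be positive")


def mw_stress(t, fit: MaxwellWiechertFit) -> np.ndarray:
    """Evaluate the fitted Maxwell-Wiechert stress at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DataError("stress is defined for t >= 0 only")
    a1, a2 = fit.weights
    t1, t2 = fit.taus
    return fit.sigma0 * (fit.plateau + a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2))


def _model(t, sigma0, a1, a2, tau1, tau2):
    p = 1.0 - a1 - a2
    return sigma0 * (p + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2))


def fit_relaxation(curve: RelaxationCurve) -> MaxwellWiechertFit:
    """Fit the biexponential Maxwell-Wiechert model to a relaxation curve.

    Bound-constrained nonlinear least squares with a deterministic
    multi-start grid over time-constant pairs (tau in {t_max/100, t_max/10,
    t_max}); the start with the smallest residual wins, ties broken by
    smaller tau1.  The plateau is the free remainder 1 - a1 - a2, softly
    penalized into [0, 1].
    """
    t = curve.time
    s = curve.stress
    sigma0_guess = float(s[0])
    if sigma0_guess <= 0:
        raise DataError("initial stress must be positive")
    t_max = float(t[-1])
    scale = sigma0_guess

    def residuals(p):
        r = _model(t, *p) - s
        # soft barrier keeping a1 + a2 <= 1 so the plateau stays physical
        excess = max(0.0, p[1] + p[2] - 1.0)
        return np.append(r, 1e3 * scale * excess)

    lb = [1e-12, 0.0, 0.0, 1e-9, 1e-9]
    ub = [np.inf, 1.0, 1.0, np.inf, np.inf]
    tail = float(np.mean(s[-max(3, s.size // 10):])) / sigma0_guess
    relaxed = max(1e-3, min(1.0, 1.0 - tail))
    starts = []
    tau_grid = [t_max / 100.0, t_max / 10.0, t_max]
    for tau1 in tau_grid:
        for tau2 in tau_grid:
            if tau2 < tau1:
                continue
            starts.append([sigma0_guess, relaxed / 2, relaxed / 2, tau1, tau2])

    best = None
    best_cost = np.inf
    best_tau1 = np.inf
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        tau1_fit = min(sol.x[3], sol.x[4])
        if sol.cost < best_cost * (1 - 1e-12) or (
            np.isclose(sol.cost, best_cost, rtol=1e-9) and tau1_fit < best_tau1
        ):
            best, best_cost, best_tau1 = sol, sol.cost, tau1_fit
    if best is None:
        raise ConvergenceError("all multi-start fits failed", best_residual=None)

    sigma0, a1, a2, tau1, tau2 = best.x
    # canonical order: tau1 <= tau2
    if tau2 < tau1:
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
    a1 = float(np.clip(a1, 0.0, 1.0))
    a2 = float(np.clip(a2, 0.0, 1.0 - a1))
    plateau = 1.0 - a1 - a2
    rmse = float(np.sqrt(np.mean((_model(t, sigma0, a1, a2, tau1, tau2) - s) ** 2)))
    fit = MaxwellWiechertFit(
        sigma0=float(sigma0),
        weights=(a1, a2),
        taus=(float(tau1), float(tau2)),
        plateau=float(plateau),
        tau_half=None,
        residual_rmse=rmse,
    )
    th = half_time(fit)
    object.__setattr__(fit, "tau_half", th)
    return fit


def half_time(fit: MaxwellWiechertFit) -> float | None:
    """Time at which the fitted stress falls to half its initial value.

    Returns None when the plateau fraction is >= 0.5 (the model never
    reaches sigma_0 / 2); this is a reported outcome, not an error.
    """
    if fit.plateau >= 0.5:
        return None
    a1, a2 = fit.weights
    t1, t2 = fit.taus

    def f(t):
        return fit.plateau + a1 * math.exp(-t / t1) + a2 * math.exp(-t / t2) - 0.5

    hi = 100.0 * max(t1, t2)
    if f(hi) > 0:  # numerically flat tail; cannot bracket
        return None
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16))


def initial_modulus(curve: StressStrainCurve, window=(0.05, 0.10)) -> float:
    """Initial elastic modulus: OLS slope of stress vs strain in ``window``.

    The default window is the 5-10 % strain range of the compression ramp.
    """
    lo, hi = window
    sel = (curve.strain >= lo) & (curve.strain <= hi)
    if np.count_nonzero(sel) < 3:
        raise DataError(
            f"stress-strain curve has fewer than 3 samples in strain window [{lo}, {hi}]"
        )
    slope = np.polyfit(curve.strain[sel], curve.stress[sel], 1)[0]
    return float(slope)


def normalize_sweep(sweep: FrequencySweep) -> FrequencySweep:
    """Divide both moduli by the storage modulus at 1 rad/s.

    When the sweep has no sample exactly at 1 rad/s the normalizer is
    obtained by log-log linear interpolation of G' onto omega = 1.
    """
    logw = np.log10(sweep.omega)
    if np.any(sweep.g_storage <= 0):
        raise DataError("storage modulus must be positive for log interpolation")
    if not (logw.min() <= 0.0 <= logw.max()):
        raise DataError("sweep does not cover 1 rad/s and cannot be normalized")
    g1 = 10.0 ** float(np.interp(0.0, logw, np.log10(sweep.g_storage)))
    if g1 <= 0:
        raise DataError("storage modulus at 1 rad/s must be positive")
    return FrequencySweep(
        omega=sweep.omega.copy(),
        g_storage=sweep.g_storage / g1,
        g_loss=sweep.g_loss / g1,
    )
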