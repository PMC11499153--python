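"""Inverse problem: fit diffusion parameters to measured TMA⁺ curves.

The workflow mirrors the two-stage RTI protocol.  The electrode array is
first calibrated in dilute agar, where the medium is effectively free
(alpha = 1, lambda = 1, k' = 0), to determine the electrode transport
number n and the free diffusion coefficient D.  With (n, D) fixed, tissue
curves are then fitted for the extracellular volume fraction alpha, the
tortuosity lambda and the non-specific uptake k'.

Both fits minimise the sum of squared residuals (in mM²) between the
baseline-subtracted curve and the point-source pulse model, using the
Nelder–Mead simplex with bounded parameters and deterministic restarts
from perturbed initial guesses.  Residuals are taken over a fit window
running from the pulse onset to two pulse durations past the pulse end;
the pre-pulse baseline defines the subtracted offset and is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .ism_calibration import IsmCalibration, voltage_to_concentration
from .rti_model import DiffusionCurve, DiffusionParams, SourceConfig, pulse_increment_mM

__all__ = [
    "FitResult",
    "FitError",
    "fit_agar",
    "fit_tissue",
    "preprocess_curve",
    "TISSUE_BOUNDS",
]

#: Physiological tissue bounds: alpha in (0.01, 1], lambda in [1, 3],
#: k' in [0, 0.1] 1/s.
TISSUE_BOUNDS = {"alpha": (0.01, 1.0), "lam": (1.0, 3.0), "kprime": (0.0, 0.1)}
AGAR_BOUNDS = {"n_transport": (0.01, 1.0), "D": (1e-6, 1e-4)}

#: Default tissue initial guesses (physiological regime).
TISSUE_INIT = {"alpha": 0.2, "lam": 1.5, "kprime": 3e-3}

_BOUND_TOL = 1e-3


class FitError(ValueError):
    """Invalid input to a curve fit."""


@dataclass
class FitResult:
    """Outcome of one diffusion-curve fit."""

    params: DiffusionParams
    sse: float
    n_iter: int
    converged: bool
    fitted_window: tuple[float, float]
    at_bounds: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def bound_constrained(self) -> bool:
        return bool(self.at_bounds)


def _fit_window(curve: DiffusionCurve) -> np.ndarray:
    dur = curve.source.duration_s
    lo, hi = curve.t_on, curve.t_on + 3.0 * dur
    mask = (curve.t >= lo) & (curve.t <= hi)
    if mask.sum() < 10:
        raise FitError("curve too short: fewer than 10 samples in the fit window")
    if curve.t[-1] < curve.t_on + dur:
        raise FitError("curve ends before the pulse does")
    return mask

def _baseline(curve: DiffusionCurve) -> float:
    if curve.baseline_mM is not None:
        return curve.baseline_mM
    pre = curve.c_mM[curve.t < curve.t_on]
    if len(pre) == 0:
        return curve.source.c_baseline_mM
    return float(np.median(pre))


def _perturbed_starts(x0: np.ndarray, n_restarts: int) -> list[np.ndarray]:
    """Deterministic multiplicative perturbations around the nominal start."""
    starts = [x0]
    factors = ([1.25, 0.8, 1.1], [0.8, 1.2, 0.7], [1.15, 0.9, 1.4])
    for f in factors[:n_restarts]:
        starts.append(x0 * np.asarray(f[: len(x0)]))
    return starts


def _run_simplex(objective, starts, bounds, max_iter):
    best = None
    total_iter = 0
    any_success = False
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9 * (hi - lo))
        res = minimize(
            objective, x0, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"fatol": 1e-10, "xatol": 1e-9,
                     "maxiter": max_iter, "maxfev": 2 * max_iter},
        )
        total_iter += res.nit
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    return best, total_iter, any_success


def _flag_bounds(x, bounds, names):
    flagged = []
    for xi, (lo, hi), name in zip(x, bounds, names):
        if min(abs(xi - lo), abs(xi - hi)) < _BOUND_TOL:
            flagged.append(name)
    return flagged


def fit_agar(curve: DiffusionCurve, D_init: float = 1.2e-5,
             n_init: float = 0.3, *, n_restarts: int = 3,
             max_iter: int = 5000) -> FitResult:
    """Agar calibration: recover (n_transport, D) with alpha=lam=1, k'=0.

    The agar curve fixes the free-medium parameters exactly; only the
    transport number (overall amplitude) and the free diffusion
    coefficient (curve shape) are free.
    """
    if curve.medium_label != "agar":
        raise FitError(f"expected an agar curve, got '{curve.medium_label}'")
    mask = _fit_window(curve)
    base = _baseline(curve)
    data = curve.c_mM[mask] - base
    t_rel = curve.t[mask] - curve.t_on
    window = (float(curve.t[mask][0]), float(curve.t[mask][-1]))

    if np.max(np.abs(data)) < 1e-4 or np.std(data) < 1e-6:
        params = DiffusionParams.free_medium(D_init, n_init)
        return FitResult(params, float(np.sum(data**2)), 0, False, window,
                         message="no signal above baseline")

    def objective(theta):
        n, D = theta
        p = DiffusionParams.free_medium(D, n)
        model = pulse_increment_mM(t_rel, curve.source, p)
        return float(np.sum((model - data) ** 2))

    bounds = [AGAR_BOUNDS["n_transport"], AGAR_BOUNDS["D"]]
    starts = _perturbed_starts(np.array([n_init, D_init]), n_restarts)
    best, n_iter, ok = _run_simplex(objective, starts, bounds, max_iter)
    n_hat, D_hat = best.x
    params = DiffusionParams.free_medium(D_hat, n_hat)
    return FitResult(params, float(best.fun), n_iter, bool(ok), window,
                     at_bounds=_flag_bounds(best.x, bounds, ["n_transport", "D"]),
                     message=best.message)


def fit_tissue(curve: DiffusionCurve, n: float, D: float, *,
               free_D: bool = False, n_restarts: int = 3,
               max_iter: int = 5000,
               init: dict | None = None) -> FitResult:
    """Tissue fit: recover (alpha, lam, k') with (n, D) fixed from agar.

    ``free_D`` additionally frees D (the standard protocol holds it fixed
    at the agar value).  A parameter landing within 1e-3 of a bound is
    flagged in ``at_bounds``, not treated as failure.
    """
    if curve.medium_label != "tissue":
        raise FitError(f"expected a tissue curve, got '{curve.medium_label}'")
    mask = _fit_window(curve)
    base = _baseline(curve)
    data = curve.c_mM[mask] - base
    t_rel = curve.t[mask] - curve.t_on
    window = (float(curve.t[mask][0]), float(curve.t[mask][-1]))

    ini = dict(TISSUE_INIT)
    if init:
        ini.update(init)

    if np.max(np.abs(data)) < 1e-4 or np.std(data) < 1e-6:
        params = DiffusionParams(ini["alpha"], ini["lam"], ini["kprime"], D, n)
        return FitResult(params, float(np.sum(data**2)), 0, False, window,
                         message="no signal above baseline")

    names = ["alpha", "lam", "kprime"]
    bounds = [TISSUE_BOUNDS[k] for k in names]
    x0 = np.array([ini[k] for k in names])
    if free_D:
        names = names + ["D"]
        bounds = bounds + [AGAR_BOUNDS["D"]]
        x0 = np.append(x0, D)

    def objective(theta):
        alpha, lam, kprime = theta[:3]
        D_eff = theta[3] if free_D else D
        p = DiffusionParams(alpha, lam, kprime, D_eff, n)
        model = pulse_increment_mM(t_rel, curve.source, p)
        return float(np.sum((model - data) ** 2))

    starts = _perturbed_starts(x0, n_restarts)
    best, n_iter, ok = _run_simplex(objective, starts, bounds, max_iter)
    theta = best.x
    params = DiffusionParams(theta[0], theta[1], theta[2],
                             theta[3] if free_D else D, n)
    return FitResult(params, float(best.fun), n_iter, bool(ok), window,
                     at_bounds=_flag_bounds(theta, bounds, names),
                     message=best.message)


def preprocess_curve(raw_voltages, times, cal: IsmCalibration,
                     cfg: SourceConfig, *, t_on: float | None = None,
                     medium_label: str = "tissue",
                     min_baseline_s: float = 5.0) -> DiffusionCurve:
    """Voltage trace → :class:`DiffusionCurve` with baseline annotation.

    Voltages are converted through the inverse Nikolski transform; the
    baseline is the median concentration over the pre-pulse window.  If
    ``t_on`` is not given, onset is detected as the first crossing of
    baseline + 10% of the peak increment.  At least ``min_baseline_s``
    seconds of pre-pulse recording are required.
    """
    times = np.asarray(times, dtype=float)
    raw_voltages = np.asarray(raw_voltages, dtype=float)
    if times.shape != raw_voltages.shape:
        raise FitError("times and voltages must have equal length")
    conc = np.clip(voltage_to_concentration(raw_voltages, cal), 0.0, None)

    if t_on is None:
        c0 = float(np.median(conc[: max(5, len(conc) // 20)]))
        peak = float(np.max(conc))
        if peak - c0 <= 0:
            raise FitError("no rise detected: cannot locate pulse onset")
        above = np.nonzero(conc > c0 + 0.1 * (peak - c0))[0]
        if len(above) == 0:
            raise FitError("no rise detected: cannot locate pulse onset")
        t_on = float(times[above[0]])

    pre = times < t_on
    if pre.sum() == 0 or (t_on - times[0]) < min_baseline_s:
        raise FitError(
            f"need >= {min_baseline_s} s of pre-pulse baseline before t_on={t_on}")
    baseline = float(np.median(conc[pre]))
    return DiffusionCurve(t=times, c_mM=conc, source=cfg,
                          medium_label=medium_label,
                          baseline_mM=baseline, t_on=t_on)
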