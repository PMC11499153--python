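"""Ion-selective microelectrode (ISM) calibration via the Nikolski equation.

A TMA⁺-selective barrel referenced against its companion barrel produces a
voltage that follows the Nicolsky–Eisenmann relation with a lumped
interference term,

    V(c) = v0 + slope · log10(c + interference),

where ``slope`` is mV per decade of concentration (ideally Nernstian,
~58 mV at room temperature) and ``interference`` is the equivalent
background concentration (mM) contributed by other cations.  Electrodes
are calibrated before each experiment in five standards (0.1, 0.3, 1, 3,
10 mM TMA⁺); fitting that series yields the constants used to convert
recorded voltages into concentrations.

Voltages are assumed to be already referenced differentially against the
reference barrel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "IsmCalibration",
    "CalibrationSeries",
    "CalibrationFit",
    "CalibrationError",
    "nikolski_voltage",
    "voltage_to_concentration",
    "fit_calibration",
    "read_calibration_csv",
    "write_calibration_csv",
]

#: Standard five-solution calibration grid, mM.
CALIBRATION_GRID_MM = (0.1, 0.3, 1.0, 3.0, 10.0)


class CalibrationError(RuntimeError):
    """Raised when a calibration series cannot be fitted."""


@dataclass(frozen=True)
class IsmCalibration:
    """Nikolski transfer function of one electrode.

    v0 : voltage offset, mV (voltage at 1 mM for zero interference).
    slope : mV per decade of concentration, > 0 for a cation electrode.
    interference : equivalent background concentration, mM, >= 0.
    """

    v0: float
    slope: float
    interference: float = 0.0

    def __post_init__(self):
        if self.slope <= 0.0:
            raise ValueError("slope must be > 0 for a cation-selective electrode")
        if self.interference < 0.0:
            raise ValueError("interference must be >= 0")


@dataclass
class CalibrationSeries:
    """Measured (concentration, voltage) pairs for one electrode."""

    concentrations: np.ndarray  # mM
    voltages: np.ndarray        # mV

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.concentrations.shape != self.voltages.shape:
            raise ValueError("concentrations and voltages must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class CalibrationFit:
    """Fitted calibration constants plus fit diagnostics."""

    calibration: IsmCalibration
    residual_rms_mV: float
    n_points: int


def nikolski_voltage(c, cal: IsmCalibration):
    """Electrode voltage (mV) for concentration ``c`` (mM)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    arg = c + cal.interference
    if np.any(arg <= 0):
        raise ValueError("c + interference must be > 0 (log domain)")
    out = cal.v0 + cal.slope * np.log10(arg)
    return float(out) if out.ndim == 0 else out


def voltage_to_concentration(v, cal: IsmCalibration):
    """Inverse Nikolski transform, mV → mM, clipped at zero.

    Voltages far below the calibrated range map to concentrations below
    the interference level and are clipped to 0 mM.
    """
    v = np.asarray(v, dtype=float)
    out = np.maximum(10.0 ** ((v - cal.v0) / cal.slope) - cal.interference, 0.0)
    return float(out) if out.ndim == 0 else out


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """Least-squares fit of (v0, slope, interference) to a series.

    Requires at least 4 points spanning >= 1.5 decades.  v0 and slope are
    initialised from a log-linear fit of the top three concentrations,
    where the interference term is negligible; interference starts at 0
    and is bounded below by 0.
    """
    c = series.concentrations
    v = series.voltages
    if len(c) < 4:
        raise CalibrationError("need >= 4 calibration points")
    if np.log10(c[-1] / c[0]) < 1.5:
        raise CalibrationError("calibration series must span >= 1.5 decades")
    if np.ptp(v) < 1e-12:
        raise CalibrationError("degenerate series: all voltages identical")
    if np.any(np.diff(v) <= 0):
        warnings.warn("non-monotonic calibration voltages; fitting anyway",
                      stacklevel=2)

    # interference only bends the low end: top-3 points give slope/v0 init
    top = slice(-3, None)
    slope0, v00 = np.polyfit(np.log10(c[top]), v[top], 1)
    if slope0 <= 0:
        slope0 = 58.0

    def resid(theta):
        v0, slope, interf = theta
        return v0 + slope * np.log10(c + interf) - v

    try:
        sol = least_squares(
            resid,
            x0=[v00, slope0, 0.0],
            bounds=([-np.inf, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except Exception as exc:  # pragma: no cover - scipy failure modes
        raise CalibrationError(f"calibration fit failed: {exc}") from exc
    if not sol.success:
        raise CalibrationError(f"calibration fit did not converge: {sol.message}")
    v0, slope, interf = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return CalibrationFit(IsmCalibration(v0, slope, interf), rms, len(c))


def read_calibration_csv(path) -> CalibrationSeries:
    """Read a per-electrode CSV with columns concentration_mM, voltage_mV."""
    df = pd.read_csv(path)
    missing = {"concentration_mM", "voltage_mV"} - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    df = df.sort_values("concentration_mM")
    return CalibrationSeries(df["concentration_mM"].to_numpy(),
                             df["voltage_mV"].to_numpy())


def write_calibration_csv(path, series: CalibrationSeries) -> None:
    pd.DataFrame({
        "concentration_mM": series.concentrations,
        "voltage_mV": series.voltages,
    }).to_csv(path, index=False)
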