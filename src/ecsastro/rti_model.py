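"""Forward model of TMA⁺ iontophoresis around a point source.

The real-time iontophoresis (RTI) method releases tetramethylammonium
(TMA⁺) from a current-driven micropipette and records the concentration
transient at an ion-selective microelectrode 50–100 µm away.  In a porous
medium with extracellular volume fraction ``alpha``, tortuosity ``lam``
and first-order non-specific uptake ``kprime``, the concentration
increment produced by a point source of strength Q (mol/s) switched on at
t = 0 is

    C(r, t) = (Q λ²)/(8 π D α r) · [ e^{+rλ√(k′/D)} erfc(rλ/(2√(Dt)) + √(k′t))
                                    + e^{−rλ√(k′/D)} erfc(rλ/(2√(Dt)) − √(k′t)) ]

which is the Green-function solution of the porous-medium diffusion
equation ∂C/∂t = (D/λ²)∇²C − k′C + (Q/α)δ(r).  In free medium
(α = 1, λ = 1, k′ = 0) this reduces to C = Q/(4πDr)·erfc(r/(2√(Dt))).

A finite current pulse is handled by linear superposition of an "on" and a
delayed negative "on" solution.  All quantities are in cm / s / mol·cm⁻³ /
A internally; see :mod:`ecsastro.units` for converters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, erfcx

from .units import FARADAY, mM_to_mol_per_cm3

__all__ = [
    "DiffusionParams",
    "SourceConfig",
    "DiffusionCurve",
    "source_rate",
    "concentration_on",
    "concentration_pulse",
    "steady_state",
    "R_MIN_CM",
]

#: Separations below 1 µm are unphysical for 50–100 µm electrode arrays.
R_MIN_CM = 1e-4


@dataclass(frozen=True)
class DiffusionParams:
    """Physical unknowns of one RTI fit.

    Parameters
    ----------
    alpha : float
        Extracellular volume fraction (ECS volume / total tissue volume),
        in (0, 1].  Free medium: 1.
    lam : float
        Tortuosity, λ² = free / apparent diffusion coefficient, ≥ 1.
    kprime : float
        Non-specific uptake rate of the probe, 1/s, ≥ 0.
    D : float
        Free diffusion coefficient of TMA⁺, cm²/s (~1.2e-5 at room temp).
    n_transport : float
        Electrode transport number — fraction of the iontophoretic current
        carried by TMA⁺, in (0, 1].
    """

    alpha: float
    lam: float
    kprime: float
    D: float
    n_transport: float

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lam < 1.0:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if self.kprime < 0.0:
            raise ValueError(f"kprime must be >= 0, got {self.kprime}")
        if self.D <= 0.0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if not 0.0 < self.n_transport <= 1.0:
            raise ValueError(f"n_transport must be in (0, 1], got {self.n_transport}")

    @classmethod
    def free_medium(cls, D: float, n_transport: float) -> "DiffusionParams":
        """Agar / free-solution parameters: alpha=1, lam=1, kprime=0."""
        return cls(alpha=1.0, lam=1.0, kprime=0.0, D=D, n_transport=n_transport)


@dataclass(frozen=True)
class SourceConfig:
    """Iontophoresis protocol constants.

    Defaults follow the standard acute-slice protocol: a 200 nA / 24 s
    current step on a continuously applied 20 nA bias, 100 µm tip
    separation, 0.1 mM TMA⁺ background in the bath.
    """

    i_step: float = 200e-9          # A
    i_bias: float = 20e-9           # A
    duration_s: float = 24.0        # s
    r: float = 100e-4               # cm (100 µm)
    z_valence: int = 1
    faraday: float = FARADAY        # C/mol
    c_baseline: float = mM_to_mol_per_cm3(0.1)  # mol/cm³

    def __post_init__(self):
        if not self.i_step > self.i_bias >= 0.0:
            raise ValueError("require i_step > i_bias >= 0")
        if self.duration_s <= 0.0:
            raise ValueError("duration_s must be > 0")
        if self.r <= 0.0:
            raise ValueError("r must be > 0")
        if self.z_valence < 1:
            raise ValueError("z_valence must be >= 1")

    @property
    def c_baseline_mM(self) -> float:
        return self.c_baseline * 1e6


@dataclass
class DiffusionCurve:
    """A sampled concentration-vs-time record.

    ``t`` is in seconds on an absolute clock with the pulse onset at
    ``t_on``; ``c_mM`` is the measured concentration in mM (baseline
    included).  ``baseline_mM`` is the estimated pre-pulse baseline.
    """

    t: np.ndarray
    c_mM: np.ndarray
    source: SourceConfig
    medium_label: str = "tissue"
    baseline_mM: float | None = None
    t_on: float = 0.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.c_mM = np.asarray(self.c_mM, dtype=float)
        if self.t.shape != self.c_mM.shape:
            raise ValueError("t and c_mM must have equal length")
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("curve needs at least two samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.c_mM < 0):
            raise ValueError("concentrations must be >= 0")


def source_rate(cfg: SourceConfig, *, n_transport: float,
                use_step_only: bool = True) -> float:
    """Molar release rate Q = I·n/(zF) of the iontophoretic source, mol/s.

    With ``use_step_only`` the effective current is the step amplitude
    above the bias (i_step − i_bias): the continuously applied bias is
    treated as an already-equilibrated contribution to the measured
    baseline, and linear superposition makes the step the only transient
    source.
    """
    current = cfg.i_step - cfg.i_bias if use_step_only else cfg.i_step
    if current <= 0.0:
        raise ValueError(f"effective current must be positive, got {current}")
    if not 0.0 <= n_transport <= 1.0:
        raise ValueError("n_transport must be in [0, 1]")
    return current * n_transport / (cfg.z_valence * cfg.faraday)


def _on_terms(r: float, t: np.ndarray, p: DiffusionParams) -> np.ndarray:
    """Bracketed erfc combination, overflow-safe.

    With u = rλ/(2√(Dt)) and s = √(k′t) the exponent rλ√(k′/D) equals 2us,
    so e^{+2us}·erfc(u+s) = erfcx(u+s)·e^{−(u²+s²)} — evaluated through the
    scaled complementary error function because 2us can exceed 700.  The
    second term only needs scaling when u ≥ s.
    """
    u = r * p.lam / (2.0 * np.sqrt(p.D * t))
    s = np.sqrt(p.kprime * t)
    damp = np.exp(-(u * u + s * s))
    term1 = erfcx(u + s) * damp
    x2 = u - s
    safe = x2 >= 0
    term2 = np.where(
        safe,
        erfcx(np.where(safe, x2, 0.0)) * damp,
        np.exp(-2.0 * u * s) * erfc(x2),
    )
    return term1 + term2


def concentration_on(r: float, t, Q: float, p: DiffusionParams):
    """Concentration increment at distance r for a source on since t=0.

    Parameters are in internal units (r in cm, t in s, Q in mol/s); the
    result is in mol/cm³.  ``C(r, 0) = 0`` by definition.
    """
    if r <= 0.0:
        raise ValueError("r must be > 0 (point-source singularity at r=0)")
    if r < R_MIN_CM:
        raise ValueError(f"r = {r} cm is below the {R_MIN_CM} cm physical limit")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    if np.any(pos):
        amp = Q * p.lam**2 / (8.0 * np.pi * p.D * p.alpha * r)
        out[pos] = amp * _on_terms(r, t_arr[pos], p)
    return float(out[0]) if scalar else out


def concentration_pulse(r: float, t, cfg: SourceConfig, p: DiffusionParams,
                        *, use_step_only: bool = True):
    """Total concentration (baseline + increment) for a finite pulse.

    Superposition of a source switched on at t = 0 and an equal negative
    source switched on at t = duration; times before 0 return the
    baseline.  Result in mol/cm³.
    """
    Q = source_rate(cfg, n_transport=p.n_transport, use_step_only=use_step_only)
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    out = np.full_like(t_arr, cfg.c_baseline)
    on = t_arr > 0
    if np.any(on):
        out[on] += concentration_on(r, t_arr[on], Q, p)
    off = t_arr > cfg.duration_s
    if np.any(off):
        out[off] -= concentration_on(r, t_arr[off] - cfg.duration_s, Q, p)
    return float(out[0]) if scalar else out


def pulse_increment_mM(t, cfg: SourceConfig, p: DiffusionParams,
                       *, use_step_only: bool = True):
    """Pulse concentration increment above baseline, in mM, at cfg.r."""
    c = concentration_pulse(cfg.r, t, cfg, p, use_step_only=use_step_only)
    return (np.asarray(c) - cfg.c_baseline) * 1e6


def steady_state(r: float, Q: float, p: DiffusionParams) -> float:
    """t → ∞ limit of :func:`concentration_on`:  Qλ²/(4πDαr)·e^{−rλ√(k′/D)}."""
    if r <= 0.0:
        raise ValueError("r must be > 0")
    return (Q * p.lam**2 / (4.0 * np.pi * p.D * p.alpha * r)
            * np.exp(-r * p.lam * np.sqrt(p.kprime / p.D)))
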