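"""Synthetic test data with known ground truth.

Three generators emulate the experimental inputs:

* **Diffusion traces** — TMA⁺ concentration transients from the
  point-source pulse model at the standard protocol (200 nA / 24 s step
  on a 20 nA bias, 0.1 mM background, 50–100 µm separation), passed
  through a Nikolski electrode transfer function, with multiplicative
  Gaussian noise (electrode noise scales with signal) and linear baseline
  drift in mV.
* **Calibration series** — Nikolski voltages on the five-standard grid
  (0.1, 0.3, 1, 3, 10 mM) plus additive voltage noise.
* **Astrocyte image series** — an anti-aliased ellipsoidal soma with
  tapering processes rendered into z-stacks (0.41 × 0.41 × 0.5 µm
  voxels), scaled isotropically to follow a programmed volume profile,
  with per-stack photobleaching, xy drift and Poisson–Gaussian noise.
  The acquisition schedule mirrors the swelling protocol: baseline
  stacks, stacks at 5-min intervals during high-K⁺ treatment, then
  washout stacks.

Every generator is deterministic under a fixed seed and returns the
ground truth alongside the artifact, so each downstream stage has an
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ism_calibration import (CALIBRATION_GRID_MM, CalibrationSeries,
                              IsmCalibration, nikolski_voltage)
from .morphometry import DEFAULT_VOXEL_UM, ImageTimeSeries, VolumeTimecourse
from .rti_model import (DiffusionCurve, DiffusionParams, SourceConfig,
                        pulse_increment_mM)

__all__ = [
    "CurveSimConfig",
    "CellSimConfig",
    "SimulatedTrace",
    "simulate_diffusion_trace",
    "simulate_calibration",
    "simulate_cell_series",
    "DEFAULT_TISSUE_PARAMS",
    "DEFAULT_CALIBRATION",
]

#: Physiological tissue regime used as simulation default.
DEFAULT_TISSUE_PARAMS = DiffusionParams(alpha=0.19, lam=1.6, kprime=5e-3,
                                        D=1.2e-5, n_transport=0.35)
#: A realistic near-Nernstian electrode.
DEFAULT_CALIBRATION = IsmCalibration(v0=10.0, slope=58.0, interference=0.05)


@dataclass
class CurveSimConfig:
    """Configuration of one simulated diffusion recording."""

    params_true: DiffusionParams = DEFAULT_TISSUE_PARAMS
    source: SourceConfig = field(default_factory=SourceConfig)
    sample_rate: float = 10.0          # Hz
    noise_sigma_rel: float = 0.0       # multiplicative, on concentration
    drift_mV_per_min: float = 0.0      # linear baseline drift on voltage
    seed: int = 0
    t_pre_s: float = 10.0              # pre-pulse baseline recorded
    t_post_factor: float = 2.0         # decay recorded, × pulse duration

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.noise_sigma_rel < 0:
            raise ValueError("noise_sigma_rel must be >= 0")
        if self.t_pre_s < 5.0:
            raise ValueError("need >= 5 s of pre-pulse baseline")


@dataclass
class SimulatedTrace:
    """Raw voltage trace plus the noiseless ground-truth curve."""

    times: np.ndarray
    voltage_mV: np.ndarray
    truth: DiffusionCurve
    config: CurveSimConfig


def simulate_diffusion_trace(cfg: CurveSimConfig,
                             cal: IsmCalibration = DEFAULT_CALIBRATION,
                             *, medium_label: str = "tissue") -> SimulatedTrace:
    """Simulate one RTI recording (voltage trace + ground-truth curve)."""
    src = cfg.source
    dur = src.duration_s
    n = int(round((cfg.t_pre_s + dur * (1 + cfg.t_post_factor)) * cfg.sample_rate))
    t = -cfg.t_pre_s + np.arange(n + 1) / cfg.sample_rate

    clean_mM = src.c_baseline_mM + pulse_increment_mM(t, src, cfg.params_true)
    rng = np.random.default_rng(cfg.seed)
    noisy_mM = clean_mM * (1.0 + cfg.noise_sigma_rel * rng.standard_normal(t.shape))
    noisy_mM = np.clip(noisy_mM, 1e-6, None)  # log-domain guard
    voltage = nikolski_voltage(noisy_mM, cal) + cfg.drift_mV_per_min * (t / 60.0)

    truth = DiffusionCurve(t=t, c_mM=clean_mM, source=src,
                           medium_label=medium_label,
                           baseline_mM=src.c_baseline_mM, t_on=0.0)
    return SimulatedTrace(times=t, voltage_mV=voltage, truth=truth, config=cfg)


def simulate_calibration(cal_true: IsmCalibration = DEFAULT_CALIBRATION,
                         noise_mV: float = 0.0, seed: int = 0,
                         grid_mM=CALIBRATION_GRID_MM) -> CalibrationSeries:
    """Five-standard calibration series with additive voltage noise."""
    if noise_mV < 0:
        raise ValueError("noise_mV must be >= 0")
    grid = np.asarray(grid_mM, dtype=float)
    v = nikolski_voltage(grid, cal_true)
    rng = np.random.default_rng(seed)
    return CalibrationSeries(grid, v + noise_mV * rng.standard_normal(grid.shape))


# ---------------------------------------------------------------------------
# astrocyte phantom


@dataclass
class CellSimConfig:
    """Configuration of one simulated astrocyte acquisition series.

    The default schedule follows the swelling protocol: three baseline
    stacks, four stacks at 5-min intervals during treatment, and washout
    stacks at +20/+40 min after treatment end.  ``volume_profile_pct``
    must be 100 at the reference (last baseline) timepoint.
    """

    soma_axes_um: tuple = (4.0, 3.4, 3.0)   # (x, y, z) semi-axes
    n_processes: int = 5
    volume_profile_pct: tuple = (100, 100, 100, 140, 200, 270, 340, 160, 100)
    timepoints_min: tuple = (-10, -5, 0, 5, 10, 15, 20, 40, 60)
    n_baseline: int = 3
    bleach_per_stack: float = 0.02          # fractional decay per stack
    drift_px_per_frame: tuple = (0.3, -0.2)  # (dy, dx)
    snr: float = 5.0                        # photons per intensity unit
    read_noise: float = 2.0                 # additive Gaussian, a.u.
    voxel_size: tuple = DEFAULT_VOXEL_UM    # (x, y, z) µm
    shape: tuple = (28, 128, 128)           # (z, y, x) voxels
    amplitude: float = 150.0
    background: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if len(self.volume_profile_pct) != len(self.timepoints_min):
            raise ValueError("one volume value per timepoint required")
        if abs(self.volume_profile_pct[self.reference_index] - 100) > 1e-9:
            raise ValueError("volume_profile_pct must be 100 at the reference")
        if min(self.soma_axes_um) <= 0:
            raise ValueError("soma axes must be > 0")

    @property
    def reference_index(self) -> int:
        return self.n_baseline - 1


def _render_cell(cfg: CellSimConfig, scale: float, center_yx,
                 supersample: int = 4) -> np.ndarray:
    """Render one noiseless stack of the cell at linear scale ``scale``.

    Occupancy is computed per z-slice on a ``supersample``× finer xy grid
    and block-averaged back (anti-aliasing).  Processes are straight
    tapering cylinders radiating in the soma's equatorial plane.
    """
    nz, ny, nx = cfg.shape
    vx, vy, vz = cfg.voxel_size
    ax, ay, az = (a * scale for a in cfg.soma_axes_um)
    cy, cx = center_yx
    cz = nz / 2.0

    if (ax / vx > nx / 2 - 2) or (ay / vy > ny / 2 - 2) or (az / vz > nz / 2 - 1):
        raise ValueError("soma larger than the imaging field")

    s = supersample
    # supersampled pixel-centre coordinates, µm, relative to the cell centre
    xs = (np.arange(nx * s) + 0.5) / s - 0.5
    ys = (np.arange(ny * s) + 0.5) / s - 0.5
    x_um = (xs - cx) * vx
    y_um = (ys - cy) * vy
    X, Y = np.meshgrid(x_um, y_um)

    # process geometry (scaled isotropically with the soma)
    angles = np.linspace(0.0, 2 * np.pi, cfg.n_processes, endpoint=False) + 0.35
    proc_len = 12.0 * scale
    proc_r0, proc_r1 = 1.1 * scale, 0.35 * scale
    radial = np.sqrt(X**2 + Y**2) + 1e-9

    stack = np.empty((nz, ny, nx), dtype=np.float64)
    for iz in range(nz):
        z_um = (iz - cz) * vz
        inside = np.zeros_like(X, dtype=bool)
        # ellipsoid cross-section at this z
        zz = (z_um / az) ** 2
        if zz < 1.0:
            f = np.sqrt(1.0 - zz)
            inside |= (X / (ax * f)) ** 2 + (Y / (ay * f)) ** 2 <= 1.0
        # processes: cylinders of tapering radius in the equatorial plane
        for th in angles:
            ux, uy = np.cos(th), np.sin(th)
            along = X * ux + Y * uy
            perp = np.abs(-X * uy + Y * ux)
            start = 0.5 * min(ax, ay)
            seg = (along >= start) & (along <= proc_len + start)
            frac = np.clip((along - start) / proc_len, 0.0, 1.0)
            rad = proc_r0 + (proc_r1 - proc_r0) * frac
            dist3 = np.sqrt(perp**2 + z_um**2)
            inside |= seg & (dist3 <= rad)
        # block-average s×s supersamples → occupancy in [0, 1]
        occ = inside.reshape(ny, s, nx, s).mean(axis=(1, 3))
        stack[iz] = cfg.background + cfg.amplitude * occ
    return stack


def simulate_cell_series(cfg: CellSimConfig):
    """Render the full acquisition series.

    Returns ``(ImageTimeSeries, VolumeTimecourse)`` where the time course
    is the programmed ground truth (vol%, and the analytic equatorial
    soma cross-section π·ax·ay·f² as the Ss reference).
    """
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape
    stacks = []
    dy, dx = cfg.drift_px_per_frame
    for i, vol in enumerate(cfg.volume_profile_pct):
        f = (vol / 100.0) ** (1.0 / 3.0)
        center = (ny / 2.0 + dy * i, nx / 2.0 + dx * i)
        stack = _render_cell(cfg, f, center)
        stack *= (1.0 - cfg.bleach_per_stack) ** i
        if cfg.snr > 0:
            stack = rng.poisson(stack * cfg.snr) / cfg.snr
        if cfg.read_noise > 0:
            stack = stack + cfg.read_noise * rng.standard_normal(stack.shape)
        stacks.append(np.clip(stack, 0.0, None))

    series = ImageTimeSeries(stacks=stacks, voxel_size=cfg.voxel_size,
                             timepoints=np.asarray(cfg.timepoints_min, float),
                             n_baseline=cfg.n_baseline)
    profile = np.asarray(cfg.volume_profile_pct, dtype=float)
    scales = (profile / 100.0) ** (2.0 / 3.0)
    ss_truth = np.pi * cfg.soma_axes_um[0] * cfg.soma_axes_um[1] * scales
    truth = VolumeTimecourse(t=np.asarray(cfg.timepoints_min, float),
                             vol_pct=profile, ss=ss_truth)
    return series, truth
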