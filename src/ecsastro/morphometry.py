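"""3D confocal morphometry: z-stacks → normalized cell-volume time courses.

Fluorescent (EGFP) astrocytes are imaged as z-stacks at successive
timepoints.  Each stack is reduced to a 2D frame by average-intensity
projection along z; the frame series is registered by translation,
corrected for acquisition-induced photobleaching (a straight line fitted
to total intensity over the baseline stacks), and the soma is segmented on
each frame by Isodata intermeans thresholding.  The segmented soma area Ss
(µm²) yields the volume estimate under isotropic scaling,

    Vs ∝ Ss^{3/2},    vol% = 100 · (Ss / Ss_ref)^{3/2},

normalized to 100% at the reference timepoint (the last pre-treatment
stack by default).  ROI fluorescence is tracked as the integral intensity
inside a small circular ROI in the soma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageTimeSeries",
    "VolumeTimecourse",
    "EmptyMaskError",
    "average_projection",
    "register_timestack",
    "bleach_correct",
    "isodata_threshold",
    "soma_mask",
    "volume_timecourse",
    "roi_intensity",
    "area_fraction",
    "measure_volume_timecourse",
]

DEFAULT_VOXEL_UM = (0.41, 0.41, 0.5)


class EmptyMaskError(ValueError):
    """Segmentation produced no soma component at the seed point."""


@dataclass
class ImageTimeSeries:
    """Ordered fluorescence z-stacks with voxel geometry.

    stacks : list of 3D arrays, (z, y, x), all the same shape.
    voxel_size : (x, y, z) in µm.
    timepoints : acquisition times in minutes, non-decreasing.
    n_baseline : number of pre-treatment stacks (used for bleach fitting).
    """

    stacks: list
    voxel_size: tuple = DEFAULT_VOXEL_UM
    timepoints: np.ndarray | None = None
    n_baseline: int = 3

    def __post_init__(self):
        if len(self.stacks) == 0:
            raise ValueError("need at least one stack")
        shape = self.stacks[0].shape
        for s in self.stacks:
            if s.ndim != 3 or s.shape != shape:
                raise ValueError("all stacks must be 3D with identical shape")
        if self.timepoints is None:
            self.timepoints = np.arange(len(self.stacks), dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if len(self.timepoints) != len(self.stacks):
            raise ValueError("one timepoint per stack required")
        if np.any(np.diff(self.timepoints) < 0):
            raise ValueError("timepoints must be non-decreasing")
        if self.n_baseline < 2:
            raise ValueError("n_baseline >= 2 required for bleach fitting")

    @property
    def pixel_area_um2(self) -> float:
        return self.voxel_size[0] * self.voxel_size[1]


@dataclass
class VolumeTimecourse:
    """Per-cell normalized soma volume and ROI fluorescence vs time."""

    t: np.ndarray          # min
    vol_pct: np.ndarray    # % of reference
    ss: np.ndarray         # soma area per frame, µm²
    fi: np.ndarray | None = None  # ROI integral intensity, a.u.

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vol_pct = np.asarray(self.vol_pct, dtype=float)
        self.ss = np.asarray(self.ss, dtype=float)


def average_projection(stack: np.ndarray) -> np.ndarray:
    """Average-intensity projection along z; returns a float 2D frame."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty 3D array (z, y, x)")
    return stack.mean(axis=0, dtype=np.float64)


def register_timestack(frames, *, upsample_factor: int = 50):
    """Translation-register a frame series to its first frame.

    Returns ``(aligned, shifts)`` where ``shifts[i]`` is the (dy, dx)
    displacement of frame i relative to frame 0 (subpixel, via
    upsampled phase cross-correlation); aligned frames have that shift
    removed by bilinear interpolation.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) < 2:
        raise ValueError("need >= 2 frames to register")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share one shape")
    ref = frames[0]
    aligned = [ref.copy()]
    shifts = [np.zeros(2)]
    for f in frames[1:]:
        if np.ptp(f) < 1e-12 or np.ptp(ref) < 1e-12:
            warnings.warn("featureless frame: assuming zero shift", stacklevel=2)
            correction = np.zeros(2)
        else:
            correction, _, _ = phase_cross_correlation(
                ref, f, upsample_factor=upsample_factor, normalization=None)
        aligned.append(ndimage.shift(f, correction, order=1, mode="nearest"))
        # report the frame's displacement (the negated correction)
        shifts.append(-np.asarray(correction, dtype=float))
    return aligned, np.array(shifts)


def bleach_correct(frames, n_baseline: int):
    """Divide frames by the linear photobleaching trend of the baseline.

    A straight line is fitted to total frame intensity versus acquisition
    index over the first ``n_baseline`` frames (all pre-treatment, so any
    trend is acquisition-induced).  Every frame is divided by the line's
    predicted decay relative to frame 0.  If the baseline trend increases,
    no correction is applied (factor capped at 1.0) and a warning is
    issued.

    Returns ``(corrected_frames, decay_factors)``.
    """
    if n_baseline < 2:
        raise ValueError("n_baseline >= 2 required to fit a bleaching line")
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) < n_baseline:
        raise ValueError("fewer frames than n_baseline")
    totals = np.array([f.sum() for f in frames])
    idx = np.arange(len(frames), dtype=float)
    slope, intercept = np.polyfit(idx[:n_baseline], totals[:n_baseline], 1)
    if intercept <= 0:
        raise ValueError("non-positive baseline intensity")
    decay = (slope * idx + intercept) / intercept
    if slope > 1e-9 * intercept:
        warnings.warn("baseline intensity increases: bleach correction skipped",
                      stacklevel=2)
        decay = np.minimum(decay, 1.0)
    elif slope > 0:  # numerically flat baseline
        decay = np.ones_like(decay)
    decay = np.maximum(decay, 1e-3)
    return [f / d for f, d in zip(frames, decay)], decay


def isodata_threshold(frame: np.ndarray, *, n_bins: int = 256,
                      max_iter: int = 200) -> float:
    """Isodata (iterative intermeans) threshold of a 2D frame.

    The histogram spans the frame's min–max range in ``n_bins`` bins.
    Starting from the mid-range value, the threshold is repeatedly
    replaced by the mean of the two class means (pixels <= T and > T)
    until it moves by less than half a bin.  At the fixed point
    T = (mean_low + mean_high) / 2.
    """
    vals = np.asarray(frame, dtype=np.float64).ravel()
    mn, mx = float(vals.min()), float(vals.max())
    if mx - mn < 1e-12:
        raise ValueError("constant frame has no threshold")
    counts, edges = np.histogram(vals, bins=n_bins, range=(mn, mx))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    csum = np.cumsum(counts)
    cmass = np.cumsum(counts * centers)
    total_n, total_m = csum[-1], cmass[-1]

    T = 0.5 * (mn + mx)
    for _ in range(max_iter):
        # bin index of T, half-up so a threshold on a bin edge rounds up
        i = min(int(np.floor((T - mn) / width + 0.5)), n_bins - 1)
        n_low = csum[i]
        if n_low == 0 or n_low == total_n:
            # walk inward until both classes are populated
            nz = np.nonzero(counts)[0]
            i = nz[0] if n_low == 0 else nz[-1] - 1
            n_low = csum[i]
        m_low = cmass[i] / n_low
        m_high = (total_m - cmass[i]) / (total_n - n_low)
        T_new = 0.5 * (m_low + m_high)
        if abs(T_new - T) < 0.5 * width:
            return float(T_new)
        T = T_new
    return float(T)


def soma_mask(frame: np.ndarray, threshold: float, seed_point,
              *, pixel_size_um=(0.41, 0.41)):
    """Supra-threshold connected component containing the seed point.

    ``seed_point`` is (row, col).  Components are 8-connected.  Returns
    ``(mask, ss_um2)`` where ``ss_um2`` is pixel count × pixel area.
    """
    frame = np.asarray(frame)
    r, c = int(seed_point[0]), int(seed_point[1])
    if not (0 <= r < frame.shape[0] and 0 <= c < frame.shape[1]):
        raise ValueError("seed_point outside the frame")
    binary = frame > threshold
    if not binary[r, c]:
        raise EmptyMaskError("seed point is below threshold: empty soma mask")
    labels = label(binary, connectivity=2)
    mask = labels == labels[r, c]
    ss = float(mask.sum()) * pixel_size_um[0] * pixel_size_um[1]
    return mask, ss


def volume_timecourse(ss_series, t_series, reference_index: int = 0,
                      fi=None) -> VolumeTimecourse:
    """Soma areas → normalized volume percent, vol% = 100·(Ss/Ss_ref)^{3/2}."""
    ss = np.asarray(ss_series, dtype=float)
    t = np.asarray(t_series, dtype=float)
    if ss.shape != t.shape:
        raise ValueError("ss_series and t_series must have equal length")
    ref = ss[reference_index]
    if ref <= 0:
        raise ValueError("reference soma area must be > 0")
    vol_pct = 100.0 * (ss / ref) ** 1.5
    return VolumeTimecourse(t=t, vol_pct=vol_pct, ss=ss,
                            fi=None if fi is None else np.asarray(fi, float))


def _circle_mask(shape, center, diameter_um, pixel_size_um):
    r0, c0 = center
    radius_px_r = (diameter_um / 2.0) / pixel_size_um[1]
    radius_px_c = (diameter_um / 2.0) / pixel_size_um[0]
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - r0) / radius_px_r) ** 2 + ((cc - c0) / radius_px_c) ** 2 <= 1.0


def roi_intensity(frames, center, diameter_um: float = 2.0,
                  *, pixel_size_um=(0.41, 0.41)) -> np.ndarray:
    """Integral intensity inside a circular ROI, per frame.

    ``center`` is (row, col).  The ROI (pixel centres within the circle)
    must lie fully inside the frame.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    shape = frames[0].shape
    r0, c0 = center
    rad_r = (diameter_um / 2.0) / pixel_size_um[1]
    rad_c = (diameter_um / 2.0) / pixel_size_um[0]
    if (r0 - rad_r < 0 or r0 + rad_r > shape[0] - 1
            or c0 - rad_c < 0 or c0 + rad_c > shape[1] - 1):
        raise ValueError("ROI clipped by the frame border")
    mask = _circle_mask(shape, center, diameter_um, pixel_size_um)
    return np.array([f[mask].sum() for f in frames])


def area_fraction(frame: np.ndarray, region_mask: np.ndarray):
    """Fluorescence-positive fraction and mean gray value within a region.

    The region is thresholded by Isodata on its own histogram; the
    fraction is positive pixels / region pixels, and the mean gray value
    is computed over the positive (segmented) pixels only.
    """
    frame = np.asarray(frame, dtype=np.float64)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != frame.shape:
        raise ValueError("region_mask must match frame shape")
    vals = frame[region_mask]
    if vals.size == 0:
        raise ValueError("empty region mask")
    thr = isodata_threshold(vals.reshape(1, -1))
    positive = vals > thr
    fraction = float(positive.mean())
    mean_gray = float(vals[positive].mean()) if positive.any() else float("nan")
    return fraction, mean_gray


def measure_volume_timecourse(series: ImageTimeSeries, seed_point,
                              *, roi_center=None, roi_diameter_um: float = 2.0,
                              reference_index: int | None = None) -> VolumeTimecourse:
    """Full morphometry pipeline on one imaged cell.

    Projection → registration → bleach correction → Isodata segmentation
    at the seed → Ss^{3/2} volume normalization.  ``seed_point`` (row,
    col) and ``roi_center`` are in the coordinates of the first frame;
    the reference timepoint defaults to the last baseline stack.
    """
    if reference_index is None:
        reference_index = series.n_baseline - 1
    frames = [average_projection(s) for s in series.stacks]
    aligned, _ = register_timestack(frames)
    corrected, _ = bleach_correct(aligned, series.n_baseline)
    px = (series.voxel_size[0], series.voxel_size[1])
    ss = []
    for f in corrected:
        thr = isodata_threshold(f)
        _, s = soma_mask(f, thr, seed_point, pixel_size_um=px)
        ss.append(s)
    fi = None
    if roi_center is not None:
        fi = roi_intensity(corrected, roi_center, roi_diameter_um,
                           pixel_size_um=px)
    return volume_timecourse(ss, series.timepoints, reference_index, fi=fi)
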