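"""Experiment-level aggregation and percent-change summaries.

Per-cell (volume) or per-slice (diffusion-parameter) time courses are
grouped into mean ± SEM tables, and effect sizes are summarised as percent
drops from the initial value and washout recovery percentages.  Inferential
statistics are intentionally not implemented here: the pipeline exports
tidy per-unit tables for standard statistical tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupTimecourse",
    "WashoutRecovery",
    "aggregate_group",
    "percent_drop",
    "washout_recovery",
    "tidy_table",
]


@dataclass
class GroupTimecourse:
    """Per-timepoint mean ± SEM of a tracked quantity across units."""

    label: str
    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "mean": self.mean,
                             "sem": self.sem, "n": self.n})


@dataclass
class WashoutRecovery:
    """Recovery percentage with the convention that produced it."""

    value_pct: float
    convention: str


def aggregate_group(series, label: str = "") -> GroupTimecourse:
    """Mean and SEM (sd/√n, ddof=1) across units sharing a time grid.

    ``series`` is a list of (t, values) pairs or objects with ``t`` and
    ``vol_pct`` attributes.  A single-unit group gets SEM 0 by convention
    (flagged with a warning).
    """
    if len(series) == 0:
        raise ValueError("empty group")
    pairs = []
    for s in series:
        if hasattr(s, "t") and hasattr(s, "vol_pct"):
            pairs.append((np.asarray(s.t, float), np.asarray(s.vol_pct, float)))
        else:
            t, v = s
            pairs.append((np.asarray(t, float), np.asarray(v, float)))
    t0 = pairs[0][0]
    for t, _ in pairs[1:]:
        if t.shape != t0.shape or not np.allclose(t, t0):
            raise ValueError("all units must share one time grid")
    values = np.vstack([v for _, v in pairs])
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n == 1:
        warnings.warn("single-unit group: SEM set to 0 by convention",
                      stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = values.std(axis=0, ddof=1) / math.sqrt(n)
    return GroupTimecourse(label=label, t=t0, mean=mean, sem=sem, n=n)


def percent_drop(initial: float, at_time: float, *, rounded: bool = True):
    """Percent decrease from ``initial`` to ``at_time``.

    Returns 100·(initial − at_time)/initial, signed (negative means an
    increase), rounded half-away-from-zero to the nearest integer percent
    for reporting unless ``rounded=False``.
    """
    if initial <= 0:
        raise ValueError("initial value must be > 0")
    pct = 100.0 * (initial - at_time) / initial
    if not rounded:
        return pct
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def washout_recovery(initial: float, peak: float, end_value: float,
                     convention: str = "fraction-of-deficit") -> WashoutRecovery:
    """Recovery at the end of washout, relative to the treatment peak.

    Conventions:

    * ``"fraction-of-deficit"`` — 100·(end − peak)/(initial − peak):
      the fraction of the treatment-induced change undone; 100% means a
      full return to the initial value.
    * ``"ratio-to-peak"`` — 100·end/peak, the raw value relative to the
      peak (the peak itself is 100%).

    The chosen convention is recorded in the result.
    """
    if convention == "fraction-of-deficit":
        if peak == initial:
            raise ValueError("peak equals initial: zero deficit")
        value = 100.0 * (end_value - peak) / (initial - peak)
    elif convention == "ratio-to-peak":
        if peak == 0:
            raise ValueError("zero peak value")
        value = 100.0 * end_value / peak
    else:
        raise ValueError(f"unknown convention '{convention}'")
    return WashoutRecovery(value_pct=float(value), convention=convention)


def tidy_table(groups) -> pd.DataFrame:
    """Stack group time courses into one tidy frame (one row per group×t)."""
    frames = []
    for g in groups:
        df = g.to_frame()
        df.insert(0, "group", g.label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
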