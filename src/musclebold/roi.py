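"""Rectangular muscle ROIs and ROI-mean time-course analysis.

A time course is the mean R2* over the valid voxels of a rectangular ROI
replicated across a slice range, per frame. The analysis chain is:

1. baseline value: mean over the frames whose onset time lies in a resting
   window (default 15-30 s, half-open);
2. percent change: ``(R2* - baseline) / baseline * 100``;
3. cycle average: elementwise mean of the percent-change series over the
   final cycles (default: last three, discarding the first to avoid
   carry-over effects), aligned at cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .paradigm import AcquisitionParams, ExerciseParadigm
from .series import R2StarSeries

__all__ = [
    "RoiSpec",
    "RoiTimeCourse",
    "extract_roi_timecourse",
    "baseline_value",
    "percent_change",
    "cycle_average",
    "analyze_roi",
    "DEFAULT_BASELINE_WINDOW",
]

#: resting window (s, half-open on frame onset times) used for the baseline
DEFAULT_BASELINE_WINDOW = (15.0, 30.0)


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned rectangle replicated over a half-open slice range."""

    name: str
    origin: tuple[int, int]
    width: int
    height: int
    slices: tuple[int, int]

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"{self.name}: width/height must be >= 1")
        if self.slices[1] <= self.slices[0] or self.slices[0] < 0:
            raise ValueError(f"{self.name}: invalid slice range {self.slices}")

    def voxel_slices(self, acq: AcquisitionParams) -> tuple[slice, slice, slice]:
        x0, y0 = self.origin
        if x0 < 0 or y0 < 0 or x0 + self.width > acq.matrix_x or y0 + self.height > acq.matrix_y:
            raise ValueError(f"ROI {self.name} exceeds matrix bounds")
        if self.slices[1] > acq.n_slices:
            raise ValueError(f"ROI {self.name} exceeds slice count")
        return (
            slice(x0, x0 + self.width),
            slice(y0, y0 + self.height),
            slice(self.slices[0], self.slices[1]),
        )

    @property
    def n_voxels(self) -> int:
        return self.width * self.height * (self.slices[1] - self.slices[0])


@dataclass
class RoiTimeCourse:
    """ROI-mean R2* time course and its derived series for one muscle."""

    muscle: str
    times: np.ndarray
    r2star_mean: np.ndarray
    baseline: Optional[float] = None
    pct_change: Optional[np.ndarray] = None
    cycle_times: Optional[np.ndarray] = None
    cycle_avg: Optional[np.ndarray] = None
    n_voxels_valid: int = 0
    extras: dict = field(default_factory=dict)


def extract_roi_timecourse(r2s: R2StarSeries, roi: RoiSpec) -> RoiTimeCourse:
    """Per-frame mean R2* over the valid voxels of the ROI.

    Raises if the ROI contains no valid voxel.
    """
    sl = roi.voxel_slices(r2s.acq)
    mask = r2s.mask[sl]
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError(f"ROI {roi.name} has no valid voxels")
    vals = r2s.values[sl]          # (w, h, nz, t)
    mean = vals[mask].mean(axis=0)  # (t,)
    return RoiTimeCourse(
        muscle=roi.name,
        times=r2s.times,
        r2star_mean=mean,
        n_voxels_valid=n_valid,
    )


def baseline_value(
    times: Sequence[float],
    values: Sequence[float],
    window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> float:
    """Mean of the frames whose onset time falls in ``[window[0], window[1])``.

    With TR = 3 s and the default window this selects frames 5-9.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    sel = (t >= window[0]) & (t < window[1])
    if not sel.any():
        raise ValueError(f"baseline window {window} contains no frames")
    return float(v[sel].mean())


def percent_change(values: Sequence[float], baseline: float) -> np.ndarray:
    """``(values - baseline) / baseline * 100``; baseline must be positive."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return (np.asarray(values, dtype=float) - baseline) / baseline * 100.0


def cycle_average(
    values: Sequence[float],
    paradigm: ExerciseParadigm,
    acq: AcquisitionParams,
    use_cycles: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean over selected cycles, aligned at cycle start.

    ``use_cycles`` are 0-based cycle indices; the default takes the last
    three. Returns ``(within_cycle_times, averaged_values)``. The cycle and
    baseline durations must align with the frame grid.
    """
    v = np.asarray(values, dtype=float)
    frames_per_cycle = paradigm.cycle_duration / acq.tr
    first_frame = paradigm.baseline_duration / acq.tr
    if abs(frames_per_cycle - round(frames_per_cycle)) > 1e-9 or \
       abs(first_frame - round(first_frame)) > 1e-9:
        raise ValueError("paradigm durations are not multiples of TR; cycles misaligned")
    fpc, f0 = round(frames_per_cycle), round(first_frame)
    if use_cycles is None:
        n_use = min(3, paradigm.n_cycles)
        use_cycles = range(paradigm.n_cycles - n_use, paradigm.n_cycles)
    use_cycles = list(use_cycles)
    if not use_cycles or min(use_cycles) < 0 or max(use_cycles) >= paradigm.n_cycles:
        raise ValueError(f"use_cycles {use_cycles} outside [0, {paradigm.n_cycles})")
    if f0 + paradigm.n_cycles * fpc > v.size:
        raise ValueError("series too short for paradigm")
    stack = np.stack([v[f0 + k * fpc : f0 + (k + 1) * fpc] for k in use_cycles])
    within_times = np.arange(fpc) * acq.tr
    return within_times, stack.mean(axis=0)


def analyze_roi(
    r2s: R2StarSeries,
    roi: RoiSpec,
    paradigm: ExerciseParadigm,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    use_cycles: Optional[Sequence[int]] = None,
) -> RoiTimeCourse:
    """Full ROI chain: extraction, baseline, percent change, cycle average."""
    tc = extract_roi_timecourse(r2s, roi)
    tc.baseline = baseline_value(tc.times, tc.r2star_mean, baseline_window)
    tc.pct_change = percent_change(tc.r2star_mean, tc.baseline)
    tc.cycle_times, tc.cycle_avg = cycle_average(tc.pct_change, paradigm, r2s.acq, use_cycles)
    return tc
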