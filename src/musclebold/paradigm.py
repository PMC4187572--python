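"""Acquisition parameters, exercise paradigm and the frame/time/phase mapping.

Every frame of the 4D series is timestamped at its acquisition onset,
``t = frame_index * TR``, and assigned to exactly one phase of the
block-design exercise paradigm (baseline, then ``n_cycles`` cycles of
exercise followed by recovery). All phase intervals are half-open
``[start, end)`` so boundary frames are never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "AcquisitionParams",
    "ExerciseParadigm",
    "FramePhase",
    "frame_time",
    "classify_frames",
]

BASELINE = "baseline"
EXERCISE = "exercise"
RECOVERY = "recovery"
POST = "post"


@dataclass(frozen=True)
class AcquisitionParams:
    """Dual-echo EPI acquisition geometry and timing.

    Parameters
    ----------
    tr : float
        Repetition time in seconds (one volume per TR).
    te1, te2 : float
        First and second echo times in seconds; ``te2 > te1 > 0``.
    matrix_x, matrix_y : int
        In-plane matrix size in voxels.
    fov_x, fov_y : float
        In-plane field of view in mm.
    n_slices : int
        Number of contiguous slices.
    slice_thickness : float
        Slice thickness in mm.
    n_frames : int
        Number of acquired volumes (time points).
    """

    tr: float
    te1: float
    te2: float
    matrix_x: int
    matrix_y: int
    fov_x: float
    fov_y: float
    n_slices: int
    slice_thickness: float
    n_frames: int

    def __post_init__(self) -> None:
        if not self.te2 > self.te1 > 0:
            raise ValueError(f"require te2 > te1 > 0, got te1={self.te1}, te2={self.te2}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.matrix_x < 1 or self.matrix_y < 1 or self.n_slices < 1:
            raise ValueError("matrix and slice counts must be >= 1")
        if self.fov_x <= 0 or self.fov_y <= 0 or self.slice_thickness <= 0:
            raise ValueError("fov and slice thickness must be positive")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")

    @property
    def voxel_x(self) -> float:
        """In-plane voxel edge along x, mm."""
        return self.fov_x / self.matrix_x

    @property
    def voxel_y(self) -> float:
        """In-plane voxel edge along y, mm."""
        return self.fov_y / self.matrix_y

    @property
    def delta_te(self) -> float:
        """Echo-time difference ``te2 - te1`` in seconds."""
        return self.te2 - self.te1

    @property
    def duration(self) -> float:
        """Total acquisition duration in seconds."""
        return self.n_frames * self.tr


@dataclass(frozen=True)
class ExerciseParadigm:
    """Block-design plantar-flexion paradigm: baseline then repeated cycles.

    Each cycle is ``exercise_duration`` seconds of contraction followed by
    ``recovery_duration`` seconds of rest. ``contraction_rate`` (Hz) is
    metadata only; it does not enter the analysis.
    """

    baseline_duration: float
    n_cycles: int
    exercise_duration: float
    recovery_duration: float
    contraction_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0 or self.exercise_duration <= 0 or self.recovery_duration <= 0:
            raise ValueError("all durations must be positive")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")

    @property
    def cycle_duration(self) -> float:
        return self.exercise_duration + self.recovery_duration

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.n_cycles * self.cycle_duration


@dataclass(frozen=True)
class FramePhase:
    """Phase label for one frame: which block its onset time falls in."""

    frame_index: int
    time: float
    phase: str
    cycle_index: Optional[int]


def frame_time(frame_index: int, acq: AcquisitionParams) -> float:
    """Onset time of a frame in seconds (``frame_index * tr``)."""
    if not 0 <= frame_index < acq.n_frames:
        raise IndexError(f"frame_index {frame_index} outside [0, {acq.n_frames})")
    return frame_index * acq.tr


def classify_frames(paradigm: ExerciseParadigm, acq: AcquisitionParams) -> list[FramePhase]:
    """Assign every frame to baseline / exercise / recovery / post.

    Frames are labelled by their onset time with half-open intervals:
    ``[0, baseline)`` is baseline; within cycle ``k`` the first
    ``exercise_duration`` seconds are exercise and the rest recovery.
    Frames beyond the paradigm are labelled ``"post"`` and ignored by the
    analysis stages.

    Raises
    ------
    ValueError
        If the paradigm is longer than the acquisition.
    """
    if paradigm.total_duration > acq.duration:
        raise ValueError(
            f"paradigm lasts {paradigm.total_duration} s but acquisition only "
            f"{acq.duration} s ({acq.n_frames} frames at TR={acq.tr} s)"
        )
    out: list[FramePhase] = []
    for i in range(acq.n_frames):
        t = i * acq.tr
        if t < paradigm.baseline_duration:
            out.append(FramePhase(i, t, BASELINE, None))
            continue
        u = t - paradigm.baseline_duration
        cycle = int(u // paradigm.cycle_duration)
        if cycle >= paradigm.n_cycles:
            out.append(FramePhase(i, t, POST, None))
            continue
        within = u - cycle * paradigm.cycle_duration
        phase = EXERCISE if within < paradigm.exercise_duration else RECOVERY
        out.append(FramePhase(i, t, phase, cycle))
    return out
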