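"""Study presets: acquisition, paradigm, phantom geometry, ROIs and defaults.

The ``study`` preset reproduces the published acquisition (TR 3 s, TE 21/60
ms, 80x80 matrix over a 200 mm FOV, ten 5 mm slices, 60 s baseline plus four
210 s cycles of 90 s plantar flexion at 0.3 Hz + 120 s recovery, 300 volumes)
with ROI sizes of 32x6 (medial gastrocnemius), 16x6 (lateral gastrocnemius)
and 25x6 (soleus) voxels on the middle six slices; medial+lateral combine
into a 48x6 gastrocnemius ROI. The ``fast`` preset halves the in-plane
matrix (40x40, 5 mm voxels) and scales the rectangles accordingly for quick
simulation studies.

Phantom muscle rectangles extend one to three voxels beyond their ROI on
each free edge, mirroring the conservative ROI placement used when drawing
ROIs inside a muscle boundary, so that spatial smoothing does not mix
background signal into ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .paradigm import AcquisitionParams, ExerciseParadigm
from .roi import RoiSpec
from .synth import ActivationTruth, TissueSpec

__all__ = ["Preset", "get_preset", "study_paradigm", "study_acquisition", "DEFAULT_TRUTH"]

MUSCLE_S0 = 1000.0         # arbitrary signal units
BACKGROUND_S0 = 500.0      # 2:1 muscle/background contrast
MUSCLE_R2S = 30.0          # s^-1
BACKGROUND_R2S = 25.0      # s^-1

# Default injected dynamics: visit-2, 15% MVC group-mean amplitudes with
# half the amplitude recovered in the window and a 40 s time constant.
DEFAULT_TRUTH: Mapping[str, ActivationTruth] = {
    "soleus": ActivationTruth(amplitude=5.12, deficit=2.56, tau=40.0),
    "medial_gastrocnemius": ActivationTruth(amplitude=6.04, deficit=3.02, tau=40.0),
    "lateral_gastrocnemius": ActivationTruth(amplitude=6.04, deficit=3.02, tau=40.0),
}


@dataclass(frozen=True)
class Preset:
    name: str
    acq: AcquisitionParams
    paradigm: ExerciseParadigm
    tissues: tuple[TissueSpec, ...]
    rois: tuple[RoiSpec, ...]

    def roi(self, name: str) -> RoiSpec:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)


def study_paradigm() -> ExerciseParadigm:
    return ExerciseParadigm(
        baseline_duration=60.0,
        n_cycles=4,
        exercise_duration=90.0,
        recovery_duration=120.0,
        contraction_rate=0.3,
    )


def study_acquisition(matrix: int = 80, n_frames: int = 300) -> AcquisitionParams:
    return AcquisitionParams(
        tr=3.0,
        te1=0.021,
        te2=0.060,
        matrix_x=matrix,
        matrix_y=matrix,
        fov_x=200.0,
        fov_y=200.0,
        n_slices=10,
        slice_thickness=5.0,
        n_frames=n_frames,
    )


def _study_preset() -> Preset:
    acq = study_acquisition(80)
    mid6 = (2, 8)  # middle six of ten slices, 0-based half-open
    tissues = (
        TissueSpec("background", BACKGROUND_S0, BACKGROUND_R2S),
        TissueSpec("medial_gastrocnemius", MUSCLE_S0, MUSCLE_R2S, region=(8, 7, 34, 12)),
        TissueSpec("lateral_gastrocnemius", MUSCLE_S0, MUSCLE_R2S, region=(42, 7, 20, 12)),
        TissueSpec("soleus", MUSCLE_S0, MUSCLE_R2S, region=(24, 37, 31, 12)),
    )
    rois = (
        RoiSpec("medial_gastrocnemius", origin=(10, 10), width=32, height=6, slices=mid6),
        RoiSpec("lateral_gastrocnemius", origin=(42, 10), width=16, height=6, slices=mid6),
        RoiSpec("gastrocnemius", origin=(10, 10), width=48, height=6, slices=mid6),
        RoiSpec("soleus", origin=(27, 40), width=25, height=6, slices=mid6),
    )
    return Preset("study", acq, study_paradigm(), tissues, rois)


def _fast_preset() -> Preset:
    acq = study_acquisition(40)
    mid6 = (2, 8)
    tissues = (
        TissueSpec("background", BACKGROUND_S0, BACKGROUND_R2S),
        TissueSpec("medial_gastrocnemius", MUSCLE_S0, MUSCLE_R2S, region=(4, 3, 17, 7)),
        TissueSpec("lateral_gastrocnemius", MUSCLE_S0, MUSCLE_R2S, region=(21, 3, 12, 7)),
        TissueSpec("soleus", MUSCLE_S0, MUSCLE_R2S, region=(10, 24, 18, 8)),
    )
    rois = (
        RoiSpec("medial_gastrocnemius", origin=(5, 5), width=16, height=3, slices=mid6),
        RoiSpec("lateral_gastrocnemius", origin=(21, 5), width=8, height=3, slices=mid6),
        RoiSpec("gastrocnemius", origin=(5, 5), width=24, height=3, slices=mid6),
        RoiSpec("soleus", origin=(13, 26), width=12, height=3, slices=mid6),
    )
    return Preset("fast", acq, study_paradigm(), tissues, rois)


def get_preset(name: str) -> Preset:
    """Return the named preset (``study`` or ``fast``)."""
    if name == "study":
        return _study_preset()
    if name == "fast":
        return _fast_preset()
    raise KeyError(f"unknown preset {name!r} (expected 'study' or 'fast')")
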