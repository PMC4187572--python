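"""Synthetic dual-echo EPI generator: a calf phantom with known oxygenation dynamics.

The phantom is a stack of axial slices containing rectangular muscle
regions (soleus, medial and lateral gastrocnemius) on a background
compartment. Each tissue has a proton-density-weighted signal ``s0`` and a
baseline relaxation rate R2*; muscles additionally carry an injected
percent-change profile p(t) locked to the exercise paradigm:

* baseline phase: p = 0
* exercise phase of each cycle: linear ramp up to the peak amplitude A at
  the exercise/recovery boundary (cycle 0 ramps from 0; later cycles ramp
  from the value where the previous recovery ended, which makes cycles
  1..n-1 exactly periodic)
* recovery phase: ``(A - D) + D * exp(-t_rec / tau)`` where D is the amount
  recovered within the recovery window as tau -> 0 and t_rec is time since
  exercise end.

The noiseless magnitude signal obeys monoexponential decay,
``S(TE, t) = s0 * exp(-TE * R2*(t))`` with
``R2*(t) = r2star_baseline * (1 + p(t)/100)``, so the dual-echo log-ratio
recovers R2*(t) exactly — the oracle every downstream stage is tested
against. Optional Rician noise models magnitude-MRI noise:
``sqrt((S + n1)^2 + n2^2)`` with iid Gaussian n1, n2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .paradigm import AcquisitionParams, ExerciseParadigm
from .series import DualEchoSeries

__all__ = [
    "TissueSpec",
    "ActivationTruth",
    "NoiseSpec",
    "percent_change_profile",
    "generate_dual_echo",
    "sigma_for_snr",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class TissueSpec:
    """A rectangular tissue compartment replicated over a slice range.

    ``region`` is ``(x0, y0, width, height)`` in voxels; ``slices`` is a
    half-open ``(z0, z1)`` range. ``region=None`` marks the background
    compartment, which fills every voxel not claimed by a muscle.
    """

    label: str
    s0: float
    r2star_baseline: float
    region: Optional[tuple[int, int, int, int]] = None
    slices: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError(f"{self.label}: s0 must be positive")
        if self.r2star_baseline <= 0:
            raise ValueError(f"{self.label}: r2star_baseline must be positive")

    def voxel_slices(self, acq: AcquisitionParams) -> tuple[slice, slice, slice]:
        if self.region is None:
            raise ValueError(f"{self.label} has no rectangular region")
        x0, y0, w, h = self.region
        z0, z1 = self.slices if self.slices is not None else (0, acq.n_slices)
        if x0 < 0 or y0 < 0 or x0 + w > acq.matrix_x or y0 + h > acq.matrix_y:
            raise ValueError(f"{self.label} region {self.region} exceeds matrix "
                             f"{acq.matrix_x}x{acq.matrix_y}")
        if z0 < 0 or z1 > acq.n_slices:
            raise ValueError(f"{self.label} slices {self.slices} exceed {acq.n_slices}")
        return slice(x0, x0 + w), slice(y0, y0 + h), slice(z0, z1)


@dataclass(frozen=True)
class ActivationTruth:
    """Injected oxygenation dynamics for one muscle.

    amplitude : peak percent change A of R2* relative to baseline (>= 0).
    deficit : percent recovered during the recovery window, D (0 <= D <= A);
        the recovery curve decays from A toward the plateau A - D.
    tau : recovery time constant in seconds.
    """

    amplitude: float
    deficit: float
    tau: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.deficit <= self.amplitude:
            raise ValueError("require 0 <= deficit <= amplitude")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: ``none``, ``gaussian`` (additive) or ``rician`` (magnitude)."""

    model: str = "rician"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def percent_change_profile(
    paradigm: ExerciseParadigm, truth: ActivationTruth, times: Sequence[float]
) -> np.ndarray:
    """Evaluate the injected percent-change profile p(t) at the given times.

    Pure function of the paradigm and ground truth; see the module docstring
    for the piecewise form. Cycles after the first are exactly periodic.
    """
    t = np.asarray(times, dtype=float)
    a, d, tau = truth.amplitude, truth.deficit, truth.tau
    p = np.zeros_like(t)
    # value at which every recovery ends (= start of each ramp after cycle 0)
    end_val = (a - d) + d * np.exp(-paradigm.recovery_duration / tau)

    active = t >= paradigm.baseline_duration
    u = t[active] - paradigm.baseline_duration
    cycle = np.floor(u / paradigm.cycle_duration).astype(int)
    within = u - cycle * paradigm.cycle_duration
    in_paradigm = cycle < paradigm.n_cycles
    cycle = np.clip(cycle, 0, paradigm.n_cycles - 1)

    start = np.where(cycle == 0, 0.0, end_val)
    exercising = within < paradigm.exercise_duration
    ramp = start + (a - start) * within / paradigm.exercise_duration
    t_rec = within - paradigm.exercise_duration
    rec = (a - d) + d * np.exp(-np.maximum(t_rec, 0.0) / tau)
    vals = np.where(exercising, ramp, rec)
    # frames past the paradigm keep the final recovery value
    vals = np.where(in_paradigm, vals, end_val)
    p[active] = vals
    return p


def sigma_for_snr(snr: float, tissues: Sequence[TissueSpec], acq: AcquisitionParams) -> float:
    """Noise sigma giving the requested SNR on the baseline echo-1 muscle signal.

    SNR is defined against the mean noiseless echo-1 baseline signal over the
    muscle compartments (s0 * exp(-TE1 * R2*_baseline)).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    ref = [t.s0 * np.exp(-acq.te1 * t.r2star_baseline) for t in tissues if t.label != BACKGROUND]
    if not ref:
        raise ValueError("no muscle tissues to define SNR against")
    return float(np.mean(ref) / snr)


def generate_dual_echo(
    acq: AcquisitionParams,
    paradigm: ExerciseParadigm,
    tissues: Sequence[TissueSpec],
    truth: Mapping[str, ActivationTruth],
    noise: NoiseSpec = NoiseSpec(model="none"),
) -> tuple[DualEchoSeries, pd.DataFrame]:
    """Generate a dual-echo dataset plus its ground-truth table.

    Returns the series and a tidy table with one row per tissue recording
    s0, baseline R2* and (for muscles with injected dynamics) A, D and tau.
    Identical ``noise.seed`` gives bit-identical output.
    """
    shape = (acq.matrix_x, acq.matrix_y, acq.n_slices, acq.n_frames)
    times = np.arange(acq.n_frames) * acq.tr

    background = [t for t in tissues if t.region is None]
    if len(background) != 1:
        raise ValueError("exactly one background tissue (region=None) required")
    muscles = [t for t in tissues if t.region is not None]
    # muscles must not overlap
    occupancy = np.zeros(shape[:3], dtype=np.int8)
    for t in muscles:
        occupancy[t.voxel_slices(acq)] += 1
    if occupancy.max() > 1:
        raise ValueError("muscle regions overlap")

    echo1 = np.empty(shape)
    echo2 = np.empty(shape)
    rows = []
    for tissue in [background[0]] + muscles:
        tr_truth = truth.get(tissue.label)
        if tr_truth is None:
            p = np.zeros(acq.n_frames)
        else:
            p = percent_change_profile(paradigm, tr_truth, times)
        r2s_t = tissue.r2star_baseline * (1.0 + p / 100.0)
        s1_t = tissue.s0 * np.exp(-acq.te1 * r2s_t)
        s2_t = tissue.s0 * np.exp(-acq.te2 * r2s_t)
        if tissue.region is None:
            echo1[...] = s1_t
            echo2[...] = s2_t
        else:
            sl = tissue.voxel_slices(acq)
            echo1[sl] = s1_t
            echo2[sl] = s2_t
        rows.append({
            "tissue": tissue.label,
            "s0": tissue.s0,
            "r2star_baseline": tissue.r2star_baseline,
            "amplitude_pct": tr_truth.amplitude if tr_truth else 0.0,
            "deficit_pct": tr_truth.deficit if tr_truth else 0.0,
            "tau_s": tr_truth.tau if tr_truth else np.nan,
        })

    if noise.model != "none" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        for echo in (echo1, echo2):
            n1 = rng.normal(0.0, noise.sigma, shape)
            if noise.model == "gaussian":
                echo += n1
            else:
                n2 = rng.normal(0.0, noise.sigma, shape)
                np.hypot(echo + n1, n2, out=echo)

    return DualEchoSeries(echo1, echo2, acq), pd.DataFrame(rows)
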