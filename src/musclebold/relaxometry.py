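"""Dual-echo R2* relaxometry.

With monoexponential transverse decay, two echoes determine the effective
relaxation rate uniquely:

    R2* = ln(S(TE1) / S(TE2)) / (TE2 - TE1)

R2* rises when deoxyhemoglobin accumulates, so it serves as an inverse
proxy for tissue oxygenation. The log requires strictly positive signals;
voxels below a small signal threshold in any frame are masked for the whole
run rather than producing NaNs mid-time-course.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .series import DualEchoSeries, R2StarSeries

__all__ = ["r2star_from_dual_echo", "r2star_series", "default_epsilon"]

ArrayLike = Union[float, np.ndarray]


def r2star_from_dual_echo(s1: ArrayLike, s2: ArrayLike, te1: float, te2: float) -> ArrayLike:
    """Two-point R2* estimate in s^-1; NaN where either signal is non-positive.

    Invariant to common scaling of both echoes (coil-gain immunity).
    """
    if not te2 > te1:
        raise ValueError(f"require te2 > te1, got {te1}, {te2}")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    valid = (s1 > 0) & (s2 > 0)
    out = np.full(np.broadcast(s1, s2).shape, np.nan)
    out[valid] = np.log(s1[valid] / s2[valid]) / (te2 - te1)
    if out.ndim == 0:
        return float(out)
    return out


def default_epsilon(series: DualEchoSeries) -> float:
    """Positivity guard: 1e-6 of the median signal across both echoes."""
    med = 0.5 * (np.median(series.echo1) + np.median(series.echo2))
    return 1e-6 * float(med)


def r2star_series(series: DualEchoSeries, epsilon: Optional[float] = None) -> R2StarSeries:
    """Voxelwise, framewise R2* with a whole-run validity mask.

    A voxel is valid only if both echoes exceed ``epsilon`` in every frame,
    so valid time courses are hole-free. Invalid voxels hold NaN.
    """
    if epsilon is None:
        epsilon = default_epsilon(series)
    acq = series.acq
    valid_frames = (series.echo1 > epsilon) & (series.echo2 > epsilon)
    mask = valid_frames.all(axis=3)
    values = np.full(series.echo1.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        values[mask] = (
            np.log(series.echo1[mask] / series.echo2[mask]) / acq.delta_te
        )
    return R2StarSeries(values, mask, acq)
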