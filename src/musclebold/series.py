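"""In-memory containers for dual-echo signal data and derived R2* maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paradigm import AcquisitionParams

__all__ = ["DualEchoSeries", "R2StarSeries"]


@dataclass
class DualEchoSeries:
    """Paired 4D magnitude arrays, one per echo, shape ``(x, y, z, t)``.

    Both arrays share the acquisition geometry in ``acq``; echo 1 was
    acquired at ``acq.te1`` and echo 2 at ``acq.te2``.
    """

    echo1: np.ndarray
    echo2: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        e1, e2 = np.asarray(self.echo1), np.asarray(self.echo2)
        if e1.shape != e2.shape:
            raise ValueError(f"echo shapes differ: {e1.shape} vs {e2.shape}")
        expected = (self.acq.matrix_x, self.acq.matrix_y, self.acq.n_slices, self.acq.n_frames)
        if e1.shape != expected:
            raise ValueError(f"echo shape {e1.shape} does not match acquisition {expected}")
        self.echo1, self.echo2 = e1, e2

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.echo1.shape


@dataclass
class R2StarSeries:
    """Per-voxel effective transverse relaxation rate time series, s^-1.

    ``values`` has shape ``(x, y, z, t)``. ``mask`` is a per-voxel boolean
    (True = valid): a voxel whose signal fails the positivity guard in ANY
    frame is invalid for the whole run, so valid time courses have no holes.
    """

    values: np.ndarray
    mask: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        v, m = np.asarray(self.values), np.asarray(self.mask, dtype=bool)
        if v.shape[:3] != m.shape:
            raise ValueError(f"mask shape {m.shape} does not match values {v.shape[:3]}")
        self.values, self.mask = v, m

    @property
    def times(self) -> np.ndarray:
        """Frame onset times in seconds."""
        return np.arange(self.values.shape[3]) * self.acq.tr
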