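"""NIfTI-1 and config file I/O.

Image data are written as uncompressed float64 NIfTI-1 with the voxel
geometry in the affine/zooms and TR as the fourth zoom, so generated data
round-trip bit-exactly. Acquisition and paradigm parameters travel in a
YAML sidecar whose keys mirror the dataclass field names (units: seconds,
mm, Hz).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import yaml

from .paradigm import AcquisitionParams, ExerciseParadigm
from .roi import RoiSpec
from .series import DualEchoSeries, R2StarSeries

__all__ = [
    "save_dual_echo",
    "load_dual_echo",
    "save_r2star",
    "load_r2star",
    "save_params",
    "load_params",
    "rois_from_config",
]

PathLike = Union[str, Path]


def _affine(acq: AcquisitionParams) -> np.ndarray:
    return np.diag([acq.voxel_x, acq.voxel_y, acq.slice_thickness, 1.0])


def _image(data: np.ndarray, acq: AcquisitionParams, descrip: str) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(acq))
    img.header.set_xyzt_units("mm", "sec")
    if data.ndim == 4:
        img.header.set_zooms((acq.voxel_x, acq.voxel_y, acq.slice_thickness, acq.tr))
    img.header["descrip"] = descrip.encode()[:79]
    return img


def save_params(
    path: PathLike,
    acq: AcquisitionParams,
    paradigm: Optional[ExerciseParadigm] = None,
    extra: Optional[dict] = None,
) -> None:
    """Write acquisition (+ optional paradigm and extras) to one YAML file."""
    doc: dict = {"acquisition": dataclasses.asdict(acq)}
    if paradigm is not None:
        doc["paradigm"] = dataclasses.asdict(paradigm)
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path: PathLike) -> tuple[AcquisitionParams, Optional[ExerciseParadigm], dict]:
    """Read acquisition/paradigm YAML; returns (acq, paradigm-or-None, extras)."""
    doc = yaml.safe_load(Path(path).read_text())
    acq = AcquisitionParams(**doc["acquisition"])
    paradigm = ExerciseParadigm(**doc["paradigm"]) if "paradigm" in doc else None
    extras = {k: v for k, v in doc.items() if k not in ("acquisition", "paradigm")}
    return acq, paradigm, extras


def rois_from_config(entries: list[dict]) -> list[RoiSpec]:
    """Build ROI specs from config entries (name, origin, width, height, slices)."""
    return [
        RoiSpec(
            name=e["name"],
            origin=tuple(e["origin"]),
            width=e["width"],
            height=e["height"],
            slices=tuple(e["slices"]),
        )
        for e in entries
    ]


def save_dual_echo(
    series: DualEchoSeries,
    out_dir: PathLike,
    paradigm: Optional[ExerciseParadigm] = None,
    stem: str = "",
) -> dict[str, Path]:
    """Write echo1/echo2 NIfTI plus a params YAML into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "echo1": out / f"{stem}echo1.nii",
        "echo2": out / f"{stem}echo2.nii",
        "params": out / f"{stem}params.yaml",
    }
    nib.save(_image(series.echo1, series.acq, f"dual-echo TE={series.acq.te1}s"), paths["echo1"])
    nib.save(_image(series.echo2, series.acq, f"dual-echo TE={series.acq.te2}s"), paths["echo2"])
    save_params(paths["params"], series.acq, paradigm)
    return paths


def load_dual_echo(
    echo1_path: PathLike, echo2_path: PathLike, params_path: PathLike
) -> tuple[DualEchoSeries, Optional[ExerciseParadigm]]:
    """Read a dual-echo dataset written by :func:`save_dual_echo`."""
    for p in (echo1_path, echo2_path, params_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    acq, paradigm, _ = load_params(params_path)
    e1 = np.asarray(nib.load(str(echo1_path)).dataobj, dtype=np.float64)
    e2 = np.asarray(nib.load(str(echo2_path)).dataobj, dtype=np.float64)
    return DualEchoSeries(e1, e2, acq), paradigm


def save_r2star(r2s: R2StarSeries, out_dir: PathLike, stem: str = "") -> dict[str, Path]:
    """Write the R2* 4D map (s^-1) and its validity mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"r2star": out / f"{stem}r2star.nii", "mask": out / f"{stem}r2star_mask.nii"}
    nib.save(_image(r2s.values, r2s.acq, "R2* map, 1/s"), paths["r2star"])
    nib.save(_image(r2s.mask.astype(np.float64), r2s.acq, "R2* validity mask"), paths["mask"])
    save_params(out / f"{stem}r2star_params.yaml", r2s.acq)
    paths["params"] = out / f"{stem}r2star_params.yaml"
    return paths


def load_r2star(r2star_path: PathLike, mask_path: PathLike, params_path: PathLike) -> R2StarSeries:
    acq, _, _ = load_params(params_path)
    values = np.asarray(nib.load(str(r2star_path)).dataobj, dtype=np.float64)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0.5
    return R2StarSeries(values, mask, acq)
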