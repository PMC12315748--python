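"""NIfTI / JSON / TSV serialization helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .rois import LabelVolume
from .tacs import FrameSchedule

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_labels",
    "load_labels",
    "save_schedule",
    "load_schedule",
]


def save_nifti(arr: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vs


def save_labels(vol: LabelVolume, nifti_path, json_path) -> None:
    save_nifti(vol.data.astype(np.int16), vol.voxel_size_mm, nifti_path)
    Path(json_path).write_text(vol.labels_json())


def load_labels(nifti_path, json_path) -> LabelVolume:
    data, vs = load_nifti(nifti_path)
    labels = LabelVolume.labels_from_json(Path(json_path).read_text())
    return LabelVolume(np.asarray(data, dtype=np.int32), vs, labels)


def save_schedule(schedule: FrameSchedule, path) -> None:
    Path(path).write_text(schedule.to_json())


def load_schedule(path) -> FrameSchedule:
    return FrameSchedule.from_json(Path(path).read_text())
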