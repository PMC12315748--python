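"""Region machinery: label volumes, mm-aware morphology (erosion, shell
construction), composite regions, and regional sampling of dynamic volumes
into time-activity curves.

Morphology is distance-transform based and aware of physical voxel size, so
the same physical operation is obtained on grids of different resolution.
Left/right region pairs are merged by pooling voxels before averaging
(volume-weighted), and identical region definitions applied to test and
retest volumes yield voxel-identical masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .tacs import FrameSchedule, TimeActivityCurve

__all__ = [
    "RegionInfo",
    "LabelVolume",
    "RegionSpec",
    "erode_mask",
    "dilate_mask",
    "build_extracerebral_shell",
    "composite_region",
    "subtract_mask",
    "meta_temporal_constituents",
    "resolve_mask",
    "sample_regions",
]

# The six structures pooled into the meta-temporal composite.
meta_temporal_constituents = (
    "entorhinal",
    "parahippocampus",
    "amygdala",
    "fusiform",
    "inferior_temporal",
    "middle_temporal",
)


@dataclass(frozen=True)
class RegionInfo:
    name: str
    role: str = "target"  # reference | target | extracerebral | other
    hemisphere: str | None = None


@dataclass
class LabelVolume:
    """3-D integer region map with physical voxel size and a label dictionary."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    labels: dict[int, RegionInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        if self.data.ndim != 3:
            raise ValueError("label data must be 3-D")
        if self.data.min() < 0:
            raise ValueError("labels must be nonnegative (0 = background)")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        present = set(np.unique(self.data).tolist())
        for lid in self.labels:
            if lid not in present:
                raise ValueError(f"named region {lid} ({self.labels[lid].name}) is empty")

    def id_of(self, name: str) -> int:
        for lid, info in self.labels.items():
            if info.name == name:
                return lid
        raise KeyError(f"unknown region name {name!r}")

    def mask(self, ids) -> np.ndarray:
        ids = [ids] if np.isscalar(ids) else list(ids)
        for lid in ids:
            if lid not in self.labels:
                raise KeyError(f"unknown region id {lid}")
        return np.isin(self.data, ids)

    def names(self, role: str | None = None) -> list[str]:
        return [i.name for i in self.labels.values() if role is None or i.role == role]

    def labels_json(self) -> str:
        return json.dumps(
            {
                str(lid): {"name": i.name, "role": i.role, "hemisphere": i.hemisphere}
                for lid, i in sorted(self.labels.items())
            },
            indent=1,
        )

    @staticmethod
    def labels_from_json(text: str) -> dict[int, RegionInfo]:
        raw = json.loads(text)
        return {
            int(k): RegionInfo(v["name"], v.get("role", "target"), v.get("hemisphere"))
            for k, v in raw.items()
        }


@dataclass(frozen=True)
class RegionSpec:
    """A named region built from label ids plus optional morphology."""

    name: str
    label_ids: tuple[int, ...]
    erode_mm: float = 0.0
    role: str = "target"
    subtract_names: tuple[str, ...] = ()  # region names removed after union

    def __post_init__(self) -> None:
        if self.erode_mm < 0:
            raise ValueError("erosion distance must be nonnegative")


def erode_mask(mask: np.ndarray, voxel_size_mm, distance_mm: float,
               name: str = "region") -> np.ndarray:
    """Remove voxels within ``distance_mm`` of the mask boundary.

    Distance to the boundary *surface* is estimated from the Euclidean
    distance transform (physical voxel size) minus half the mean voxel size,
    since the boundary runs between voxel centers; voxels strictly farther
    than distance_mm survive. The surface offset keeps eroded volumes stable
    under grid refinement. distance 0 is the identity.
    """
    if distance_mm < 0:
        raise ValueError("erosion distance must be nonnegative")
    mask = np.asarray(mask, dtype=bool)
    if distance_mm == 0:
        return mask.copy()
    half_voxel = float(np.mean(voxel_size_mm)) / 2.0
    dist = distance_transform_edt(mask, sampling=voxel_size_mm)
    out = mask & (dist > distance_mm + half_voxel)
    if not out.any():
        raise ValueError(f"eroding {name!r} by {distance_mm} mm leaves no voxels")
    return out


def dilate_mask(mask: np.ndarray, voxel_size_mm, distance_mm: float) -> np.ndarray:
    """Add all voxels within ``distance_mm`` of the mask."""
    mask = np.asarray(mask, dtype=bool)
    if distance_mm <= 0:
        return mask.copy()
    dist = distance_transform_edt(~mask, sampling=voxel_size_mm)
    return mask | (dist <= distance_mm)


def build_extracerebral_shell(
    cortical_mask: np.ndarray,
    voxel_size_mm,
    thickness_mm: float = 5.0,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Shell obtained by dilating the cortical surface outward.

    The cortical mask is dilated by ``thickness_mm`` and every brain voxel is
    removed, so the shell is strictly outside the brain and disjoint from all
    cerebral regions. ``brain_mask`` defaults to the cortical mask itself.
    """
    cortical_mask = np.asarray(cortical_mask, dtype=bool)
    if not cortical_mask.any():
        raise ValueError("cortical mask is empty")
    if thickness_mm <= 0:
        raise ValueError("shell thickness must be positive (empty shell)")
    brain = cortical_mask if brain_mask is None else np.asarray(brain_mask, dtype=bool)
    shell = dilate_mask(cortical_mask, voxel_size_mm, thickness_mm) & ~brain
    if not shell.any():
        raise ValueError("extracerebral shell is empty")
    return shell


def subtract_mask(mask: np.ndarray, removed: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` not in ``removed`` (e.g. inferior cerebellum =
    cerebellar grey minus superior-cerebellum mask)."""
    return np.asarray(mask, dtype=bool) & ~np.asarray(removed, dtype=bool)


def composite_region(vol: LabelVolume, name: str, constituents,
                     role: str = "target") -> RegionSpec:
    """Union of existing regions (given by name or id) as a new RegionSpec."""
    ids = []
    for c in constituents:
        lid = vol.id_of(c) if isinstance(c, str) else int(c)
        if lid not in vol.labels:
            raise KeyError(f"unknown region id {lid}")
        ids.append(lid)
    return RegionSpec(name=name, label_ids=tuple(ids), role=role)


def meta_temporal_spec(vol: LabelVolume) -> RegionSpec:
    """Preset meta-temporal composite (six temporal-lobe structures)."""
    return composite_region(vol, "meta_temporal", meta_temporal_constituents)


def resolve_mask(vol: LabelVolume, spec: RegionSpec,
                 aux_masks: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Boolean mask for a RegionSpec: union of ids, optional subtraction of
    auxiliary masks (by name), then mm-aware erosion."""
    mask = vol.mask(spec.label_ids)
    for name in spec.subtract_names:
        if aux_masks is None or name not in aux_masks:
            raise KeyError(f"auxiliary mask {name!r} not provided")
        mask = subtract_mask(mask, aux_masks[name])
    if spec.erode_mm > 0:
        mask = erode_mask(mask, vol.voxel_size_mm, spec.erode_mm, name=spec.name)
    if not mask.any():
        raise ValueError(f"region {spec.name!r} is empty after morphology")
    return mask


def sample_regions(
    img: np.ndarray,
    vol: LabelVolume,
    specs,
    schedule: FrameSchedule,
    aux_masks: dict[str, np.ndarray] | None = None,
) -> dict[str, TimeActivityCurve]:
    """Pooled-voxel mean TAC per region from a 4-D (x, y, z, frame) image.

    Regions spanning both hemispheres are merged by pooling voxels before
    averaging, i.e. the volume-weighted mean of the hemisphere means.
    """
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., None]
    if img.shape[:3] != vol.data.shape:
        raise ValueError(f"grid mismatch: image {img.shape[:3]} vs labels {vol.data.shape}")
    if img.shape[3] != schedule.n_frames:
        raise ValueError(
            f"frame count mismatch: image {img.shape[3]} vs schedule {schedule.n_frames}"
        )
    out: dict[str, TimeActivityCurve] = {}
    flat = img.reshape(-1, img.shape[3])
    for spec in specs:
        mask = resolve_mask(vol, spec, aux_masks)
        values = flat[mask.ravel()].mean(axis=0, dtype=np.float64)
        out[spec.name] = TimeActivityCurve(schedule, values.astype(float), region=spec.name)
    return out
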