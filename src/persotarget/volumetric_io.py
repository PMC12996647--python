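"""Volume I/O, voxel/world coordinate transforms, and mask construction.

All coordinates handed to users are world millimetres (RAS+, MNI
convention); voxel indices are 0-based and internal.  Distances are always
computed in world mm, never voxel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

# Sphere centers (MNI mm) defining the seed-based algorithm's DLPFC search
# region: BA9, BA46, the "5 cm" TMS site, and the F3 beam site.
RSA_DLPFC_SPHERE_CENTERS_MM = (
    (-36.0, 39.0, 43.0),
    (-44.0, 40.0, 29.0),
    (-41.0, 16.0, 54.0),
    (-37.0, 26.0, 49.0),
)
RSA_DLPFC_SPHERE_RADIUS_MM = 20.0

SGACC_SPHERE_CENTER_MM = (6.0, 16.0, -10.0)
SGACC_SPHERE_RADIUS_MM = 10.0


class VolumeError(ValueError):
    """Raised for malformed volumes, geometries, or mask requests."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid shape plus the affine mapping voxel indices to world mm.

    The affine is the standard homogeneous 4x4 NIfTI matrix; voxel sizes
    are derived from its linear part.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise VolumeError("affine is not invertible")
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise VolumeError(f"bad dims {self.dims}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(n) for n in np.linalg.norm(self.affine[:3, :3], axis=0))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VolumeGeometry)
            and self.dims == other.dims
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self):
        return hash(self.dims)

    def voxel_centers_mm(self, idx: np.ndarray) -> np.ndarray:
        """World-mm coordinates of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def voxel_to_world(idx: Sequence[int], geom: VolumeGeometry) -> np.ndarray:
    """Map a voxel index triple to world mm via the affine."""
    idx = np.asarray(idx, dtype=float)
    if np.any(idx < 0) or np.any(idx >= np.asarray(geom.dims)):
        raise VolumeError(f"voxel index {tuple(idx)} outside dims {geom.dims}")
    return geom.affine[:3, :3] @ idx + geom.affine[:3, 3]


def world_to_voxel(point_mm: Sequence[float], geom: VolumeGeometry) -> tuple[int, int, int]:
    """Map a world-mm point to the nearest voxel index (rounds to nearest)."""
    inv = np.linalg.inv(geom.affine)
    p = np.asarray(point_mm, dtype=float)
    idx = inv[:3, :3] @ p + inv[:3, 3]
    idx = np.round(idx).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(geom.dims)):
        raise VolumeError(f"world point {tuple(p)} maps outside the volume")
    return tuple(int(i) for i in idx)


@dataclass
class BoldRun:
    """One run's 4D BOLD time series with geometry and acquisition metadata."""

    data: np.ndarray
    geometry: VolumeGeometry
    tr: float
    subject_id: str = ""
    day: int = 1
    phase: str = "LR"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise VolumeError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[:3] != self.geometry.dims:
            raise VolumeError(
                f"data shape {self.data.shape[:3]} != geometry dims {self.geometry.dims}"
            )
        if self.data.shape[3] < 2:
            raise VolumeError("need at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("BOLD data contains non-finite values")
        if self.day not in (1, 2):
            raise VolumeError(f"day must be 1 or 2, got {self.day}")
        if self.phase not in ("LR", "RL"):
            raise VolumeError(f"phase must be LR or RL, got {self.phase}")

    @property
    def nt(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(
            data=data,
            geometry=self.geometry,
            tr=self.tr,
            subject_id=self.subject_id,
            day=self.day,
            phase=self.phase,
        )

    def truncated(self, nt: int) -> "BoldRun":
        """First ``nt`` volumes only (data-length robustness checks)."""
        if not 2 <= nt <= self.nt:
            raise VolumeError(f"cannot truncate {self.nt} volumes to {nt}")
        return self.with_data(self.data[..., :nt])


@dataclass
class BinaryMask:
    """Boolean 3D volume sharing a geometry."""

    data: np.ndarray
    geometry: VolumeGeometry
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.geometry.dims:
            raise VolumeError(
                f"mask shape {self.data.shape} != geometry dims {self.geometry.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer indices of true voxels, in C order."""
        return np.argwhere(self.data)

    def world_coords_mm(self) -> np.ndarray:
        return self.geometry.voxel_centers_mm(self.voxel_indices())

    def require_nonempty(self) -> "BinaryMask":
        if self.n_voxels == 0:
            raise VolumeError(f"mask {self.name or '<unnamed>'} is empty")
        return self


@dataclass
class WeightMap:
    """Real-valued 3D volume (e.g. a group connectivity weighting mask)."""

    data: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.dims:
            raise VolumeError(
                f"weight map shape {self.data.shape} != geometry dims {self.geometry.dims}"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, kind: str = "auto", metadata_sidecar: bool = True):
    """Read a NIfTI-1 file as a :class:`BoldRun`, :class:`BinaryMask` or
    :class:`WeightMap`.

    Parameters
    ----------
    path:
        ``.nii`` / ``.nii.gz`` file.  4D files always yield a BoldRun;
        3D files yield a mask (``kind='mask'``), a weight map
        (``kind='weight'``), or a mask if integer-valued 0/1
        (``kind='auto'``).
    metadata_sidecar:
        If True and ``<stem>.json`` exists beside the file, its
        ``subject``/``day``/``phase``/``tr`` fields populate run metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if np.all(np.isnan(data)):
        raise VolumeError(f"{path}: volume is all-NaN")
    geom = VolumeGeometry(dims=tuple(data.shape[:3]), affine=np.asarray(img.affine))
    if data.ndim == 4:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
        meta = {}
        sidecar = path.parent / (path.name.replace(".nii.gz", "").replace(".nii", "") + ".json")
        if metadata_sidecar and sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return BoldRun(
            data=data.astype(float),
            geometry=geom,
            tr=float(meta.get("tr", tr)),
            subject_id=str(meta.get("subject", "")),
            day=int(meta.get("day", 1)),
            phase=str(meta.get("phase", "LR")),
        )
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected 3D or 4D volume, got {data.ndim}D")
    if kind == "weight":
        return WeightMap(data=data.astype(float), geometry=geom)
    if kind == "mask" or (
        kind == "auto" and np.issubdtype(data.dtype, np.integer) and set(np.unique(data)) <= {0, 1}
    ):
        return BinaryMask(data=data > 0, geometry=geom, name=path.name)
    return WeightMap(data=data.astype(float), geometry=geom)


def write_volume(obj, path) -> Path:
    """Write a BoldRun / BinaryMask / WeightMap as NIfTI-1 (+ JSON sidecar
    for runs).  Masks are written as uint8."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, BoldRun):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.geometry.affine)
        zooms = list(obj.geometry.voxel_size) + [obj.tr]
        img.header.set_zooms(zooms)
        nib.save(img, str(path))
        sidecar = path.parent / (path.name.replace(".nii.gz", "").replace(".nii", "") + ".json")
        sidecar.write_text(
            json.dumps(
                {"subject": obj.subject_id, "day": obj.day, "phase": obj.phase, "tr": obj.tr}
            )
        )
    elif isinstance(obj, BinaryMask):
        nib.save(nib.Nifti1Image(obj.data.astype(np.uint8), obj.geometry.affine), str(path))
    elif isinstance(obj, WeightMap):
        nib.save(nib.Nifti1Image(obj.data.astype(np.float32), obj.geometry.affine), str(path))
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    return path


# ---------------------------------------------------------------------------
# Mask construction


def make_sphere_mask(
    center_mm: Sequence[float],
    radius_mm: float,
    geom: VolumeGeometry,
    name: str = "sphere",
) -> BinaryMask:
    """Spherical mask: voxel included iff its center lies within
    ``radius_mm`` (inclusive) of ``center_mm`` in world coordinates."""
    if radius_mm <= 0:
        raise VolumeError(f"radius must be positive, got {radius_mm}")
    nx, ny, nz = geom.dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = geom.voxel_centers_mm(idx)
    d2 = np.sum((centers - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
    inside = (d2 <= radius_mm**2).reshape(geom.dims)
    mask = BinaryMask(data=inside, geometry=geom, name=name)
    if mask.n_voxels == 0:
        raise VolumeError(
            f"sphere at {tuple(center_mm)} r={radius_mm}mm contains no voxel centers"
        )
    return mask


def build_rsa_dlpfc_mask(gray_matter: BinaryMask) -> BinaryMask:
    """DLPFC search mask for the seed-based algorithm: the union of four
    20-mm spheres (BA9, BA46, "5 cm" site, F3 beam site) intersected with
    the supplied gray-matter mask."""
    geom = gray_matter.geometry
    union = np.zeros(geom.dims, dtype=bool)
    for c in RSA_DLPFC_SPHERE_CENTERS_MM:
        try:
            union |= make_sphere_mask(c, RSA_DLPFC_SPHERE_RADIUS_MM, geom).data
        except VolumeError:
            continue  # sphere entirely off-grid on small test volumes
    combined = union & gray_matter.data
    mask = BinaryMask(data=combined, geometry=geom, name="rsa_dlpfc")
    if mask.n_voxels == 0:
        raise VolumeError("RSA DLPFC mask is empty after gray-matter intersection")
    return mask


def make_sgacc_sphere_mask(geom: VolumeGeometry) -> BinaryMask:
    """The 10-mm sgACC seed sphere at MNI (6, 16, -10)."""
    return make_sphere_mask(SGACC_SPHERE_CENTER_MM, SGACC_SPHERE_RADIUS_MM, geom, name="sgacc")


def load_label_mask(atlas: np.ndarray | WeightMap, labels: Iterable[int],
                    geom: VolumeGeometry | None = None, name: str = "label") -> BinaryMask:
    """Mask of atlas voxels whose integer label is in ``labels``."""
    if isinstance(atlas, WeightMap):
        geom = atlas.geometry
        values = atlas.data
    else:
        values = np.asarray(atlas)
        if geom is None:
            raise VolumeError("geometry required when atlas is a bare array")
    if not np.allclose(values, np.round(values)):
        raise VolumeError("atlas is not an integer label volume")
    values = np.round(values).astype(int)
    labels = set(int(l) for l in labels)
    present = set(np.unique(values).tolist())
    missing = labels - present
    if missing:
        raise VolumeError(f"labels {sorted(missing)} absent from atlas")
    return BinaryMask(data=np.isin(values, list(labels)), geometry=geom, name=name)
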