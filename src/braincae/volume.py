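"""Gray-matter volumes: grids, standardization, cropping and NIfTI I/O.

A :class:`GreyMatterVolume` holds one subject's 3D gray-matter map
together with a binary GM mask on a shared :class:`VolumeGrid`.  The
central operation is per-subject intensity standardization: in-mask
voxels are mapped to zero mean and unit standard deviation (population
SD, computed over mask voxels only) and everything outside the mask is
set exactly to zero.  This is the standard voxel-based-morphometry
style normalization applied to smoothed, modulated GM maps before they
enter the autoencoder.

Voxel indices are 0-based and bounding boxes are half-open; world
coordinates exist only through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "GreyMatterVolume",
    "DegenerateVolumeError",
    "GridMismatchError",
    "CohortError",
    "standardize",
    "crop_to_bbox",
    "resampled_grid_shape",
    "MNI152_15MM_SHAPE",
    "write_volume",
    "read_volume",
    "read_cohort",
    "write_cohort",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = [
    "id", "site", "diagnosis", "age", "dose",
    "positive_score", "negative_score", "onset_age", "duration",
]


class DegenerateVolumeError(ValueError):
    """Raised when a volume cannot be standardized (empty mask or zero SD)."""


class GridMismatchError(ValueError):
    """Raised when volumes of one cohort do not share a single grid."""


class CohortError(ValueError):
    """Raised on covariate/volume id mismatches."""


@dataclass(frozen=True)
class VolumeGrid:
    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"non-positive grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"non-positive voxel size {self.voxel_size_mm}")
        if self.affine is None:
            aff = np.diag(list(self.voxel_size_mm) + [1.0])
            object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float) -> "VolumeGrid":
        return cls(tuple(shape), (voxel_size_mm,) * 3)

    def __eq__(self, other):
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.affine, other.affine)
        )


@dataclass
class GreyMatterVolume:
    data: np.ndarray
    mask: np.ndarray
    grid: VolumeGrid
    subject_id: str = ""
    standardized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}")


def standardize(volume: GreyMatterVolume) -> GreyMatterVolume:
    """Map in-mask voxels to zero mean / unit (population) SD; zero off-mask.

    Idempotent in the sense that an already mean-0/SD-1 masked volume is
    a fixed point, and invariant to positive affine rescaling of the
    in-mask intensities.
    """
    if volume.standardized:
        raise ValueError(f"volume {volume.subject_id!r} is already standardized")
    m = volume.mask
    if not m.any():
        raise DegenerateVolumeError(f"volume {volume.subject_id!r} has an empty mask")
    vals = volume.data[m]
    mu = float(vals.mean(dtype=np.float64))
    sigma = float(vals.std(dtype=np.float64))  # population SD
    if sigma == 0.0:
        raise DegenerateVolumeError(
            f"volume {volume.subject_id!r} is constant inside the mask (sigma=0)")
    out = np.zeros_like(volume.data)
    out[m] = ((vals - mu) / sigma).astype(np.float32)
    return replace(volume, data=out, standardized=True)


def crop_to_bbox(volume: GreyMatterVolume, bbox) -> GreyMatterVolume:
    """Crop data and mask to a half-open bounding box ((d0,d1),(h0,h1),(w0,w1))."""
    bbox = tuple((int(a), int(b)) for a, b in bbox)
    for (a, b), n in zip(bbox, volume.grid.shape):
        if not (0 <= a < b <= n):
            raise ValueError(f"bbox {bbox} outside grid {volume.grid.shape}")
    sl = tuple(slice(a, b) for a, b in bbox)
    new_shape = tuple(b - a for a, b in bbox)
    origin = np.array([a for a, _ in bbox], dtype=float)
    affine = volume.grid.affine.copy()
    affine[:, 3] = volume.grid.affine @ np.append(origin, 1.0)
    grid = VolumeGrid(new_shape, volume.grid.voxel_size_mm, affine)
    return replace(volume, data=volume.data[sl].copy(), mask=volume.mask[sl].copy(),
                   grid=grid)


def resampled_grid_shape(shape, old_voxel_mm: float, new_voxel_mm: float):
    """Voxel counts after re-gridding a field of view at a new spacing.

    The physical extent ``shape * old_voxel_mm`` is divided by the new
    spacing and rounded to the nearest voxel.  The MNI152 2 mm field of
    view (91 x 109 x 91) re-gridded at 1.5 mm gives 121 x 145 x 121.
    """
    return tuple(int(np.rint(s * old_voxel_mm / new_voxel_mm)) for s in shape)


#: Standard-space grid at 1.5 mm used for full-scale GM maps.
MNI152_15MM_SHAPE = resampled_grid_shape((91, 109, 91), 2.0, 1.5)


# -- NIfTI I/O --------------------------------------------------------


def write_volume(path, volume: GreyMatterVolume) -> None:
    """Write data (and mask as a sidecar) as NIfTI-1.

    The mask is stored next to the data file as ``<stem>_mask.nii[.gz]``.
    """
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.grid.affine)
    img.header.set_zooms(volume.grid.voxel_size_mm)
    nib.save(img, str(path))
    mimg = nib.Nifti1Image(volume.mask.astype(np.uint8), volume.grid.affine)
    mimg.header.set_zooms(volume.grid.voxel_size_mm)
    nib.save(mimg, str(_mask_path(path)))


def _mask_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_mask" + suf)
    raise ValueError(f"not a NIfTI path: {path}")


def read_volume(path, subject_id: str = "", standardized: bool = False,
                mask: np.ndarray | None = None) -> GreyMatterVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VolumeGrid(data.shape, zooms, np.asarray(img.affine))
    if mask is None:
        mpath = _mask_path(path)
        if mpath.exists():
            mask = np.asarray(nib.load(str(mpath)).dataobj) > 0
        else:
            mask = data != 0
    return GreyMatterVolume(data=data, mask=mask, grid=grid,
                            subject_id=subject_id or path.name.split(".")[0],
                            standardized=standardized)


def read_cohort(paths, covariates_csv) -> tuple[list[GreyMatterVolume], pd.DataFrame]:
    """Read an id-matched cohort; order follows the covariates CSV.

    ``paths`` maps subject id -> NIfTI path (or is a list of paths whose
    stems are the ids).  All volumes must share one grid; missing
    covariate values (patient-only fields of healthy subjects) are kept
    as NaN.
    """
    cov = pd.read_csv(covariates_csv, dtype={"id": str, "site": str})
    if cov["id"].duplicated().any():
        raise CohortError("duplicate subject ids in covariates table")
    if isinstance(paths, dict):
        by_id = {str(k): Path(v) for k, v in paths.items()}
    else:
        by_id = {Path(p).name.split(".")[0]: Path(p) for p in paths}
    missing = [i for i in cov["id"] if i not in by_id]
    if missing:
        raise CohortError(f"covariate ids without a volume: {missing}")
    extra = [i for i in by_id if i not in set(cov["id"])]
    if extra:
        raise CohortError(f"volumes without a covariate row: {sorted(extra)}")
    volumes = []
    grid = None
    for sid in cov["id"]:
        vol = read_volume(by_id[sid], subject_id=sid)
        if grid is None:
            grid = vol.grid
        elif vol.grid != grid:
            raise GridMismatchError(
                f"{by_id[sid]} grid {vol.grid.shape} differs from cohort grid {grid.shape}")
        volumes.append(vol)
    return volumes, cov


def write_cohort(outdir, volumes, covariates: pd.DataFrame,
                 compress: bool = True) -> dict[str, Path]:
    """Write one NIfTI per subject plus the covariates CSV; returns id->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".nii.gz" if compress else ".nii"
    paths = {}
    for vol in volumes:
        p = outdir / f"{vol.subject_id}{suffix}"
        write_volume(p, vol)
        paths[vol.subject_id] = p
    covariates.to_csv(outdir / "covariates.csv", index=False,
                      columns=COVARIATE_COLUMNS)
    return paths
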