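"""Reading, writing, resampling, normalising and masking 3D MRI volumes.

All volumes are carried as :class:`Volume` objects holding the scalar grid,
the voxel spacing in millimetres and the NIfTI voxel-to-world affine.  Binary
tumour regions of interest are :class:`ROIMask` objects tied to a reference
volume.  A per-subject bundle of co-registered modalities plus demographics
is a :class:`SubjectRecord`.

Co-registration and skull stripping are external preconditions: this module
verifies grid congruence between modalities and raises when volumes disagree,
it never registers.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

MODALITY_TAGS = ("FLAIR", "T1", "T2", "FA", "MD", "DWI-derived")


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but statistically degenerate
    (empty mask, zero variance, both masks empty, ...)."""


class GridMismatchError(ValueError):
    """Raised when two objects that must share a voxel grid do not."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    modality_tag: str = "FLAIR"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume grid must be 3D, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class ROIMask:
    """A binary grid aligned voxel-for-voxel with its reference volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass
class SubjectRecord:
    """One subject: co-registered modality volumes, tumour mask, demographics."""

    subject_id: str
    volumes: Mapping[str, Volume]
    mask: ROIMask
    age: float
    sex: str
    label: str
    scanner_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.label not in ("mutant", "wildtype"):
            raise ValueError(f"label must be 'mutant' or 'wildtype', got {self.label!r}")
        if self.age < 18:
            raise ValueError("cohort inclusion requires age >= 18 years")
        shapes = {m: v.shape for m, v in self.volumes.items()}
        ref = self.mask.shape
        bad = {m: s for m, s in shapes.items() if s != ref}
        if bad:
            raise GridMismatchError(
                f"subject {self.subject_id}: volumes not on the mask grid {ref}: {bad}"
            )

    @property
    def y(self) -> int:
        """Binary target: 1 for IDH mutant (positive class), 0 for wildtype."""
        return 1 if self.label == "mutant" else 0


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, modality_tag: str = "FLAIR") -> Volume:
    """Read a 3D NIfTI-1/2 image into a :class:`Volume`.

    Spacing comes from the header pixdims, the affine from the header;
    integer payloads are promoted to float32.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got {data.ndim}D with shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=img.affine, modality_tag=modality_tag)


def write_volume(vol: Volume, path) -> None:
    """Write a Volume as NIfTI, preserving float32 payloads bit-exactly."""
    data = vol.data
    if data.dtype not in (np.float32, np.float64):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path) -> ROIMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIMask(data=data > 0.5, spacing=spacing, affine=img.affine)


def write_mask(mask: ROIMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling

def _resample_grid(data: np.ndarray, spacing, target_mm: float, order: int) -> np.ndarray:
    if target_mm <= 0:
        raise ValueError(f"target spacing must be > 0 mm, got {target_mm}")
    zoom = [s / target_mm for s in spacing]
    out_shape = [math.ceil(n * z) for n, z in zip(data.shape, zoom)]
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return data.copy()
    # world coordinate of output voxel j along an axis is j*target; the source
    # voxel index is j*target/spacing — an affine map with zero offset.
    matrix = np.diag([target_mm / s for s in spacing])
    out = ndimage.affine_transform(
        data.astype(float), matrix, offset=0.0, output_shape=tuple(out_shape),
        order=order, mode="nearest",
    )
    return out


def resample_isotropic(vol: Volume, target_mm: float = 1.0) -> Volume:
    """Resample to an isotropic grid by trilinear interpolation in world space."""
    out = _resample_grid(vol.data, vol.spacing, target_mm, order=1)
    affine = vol.affine.copy()
    scale = np.array([target_mm / s for s in vol.spacing])
    affine[:3, :3] = affine[:3, :3] * scale[np.newaxis, :]
    return Volume(out, (target_mm,) * 3, affine, vol.modality_tag)


def resample_mask(mask: ROIMask, target_mm: float = 1.0) -> ROIMask:
    """Resample a binary mask with nearest-neighbour interpolation (stays binary)."""
    out = _resample_grid(mask.data.astype(np.uint8), mask.spacing, target_mm, order=0)
    affine = mask.affine.copy()
    scale = np.array([target_mm / s for s in mask.spacing])
    affine[:3, :3] = affine[:3, :3] * scale[np.newaxis, :]
    return ROIMask(out > 0.5, (target_mm,) * 3, affine)


# ---------------------------------------------------------------------------
# Normalisation and masking


def zscore_normalize(vol: Volume, support: ROIMask | None = None) -> Volume:
    """Z-score a volume: subtract the mean and divide by the sample (n-1) sd.

    The support defaults to the nonzero (brain) voxels of the volume, which is
    robust to zero-padded background; pass an explicit mask or a full-true
    mask for whole-grid normalisation.
    """
    if support is None:
        sup = vol.data != 0
    else:
        if support.shape != vol.shape:
            raise GridMismatchError("support mask grid differs from volume grid")
        sup = support.data
    vals = vol.data[sup].astype(np.float64)
    if vals.size < 2:
        raise DegenerateInputError("z-score support must contain at least 2 voxels")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero variance over the z-score support")
    out = (vol.data.astype(np.float64) - mu) / sd
    return Volume(out, vol.spacing, vol.affine, vol.modality_tag)


def mask_bounding_box(mask: ROIMask, margin_vox: int = 0) -> tuple[slice, slice, slice]:
    """Axis-aligned bounding box of the true voxels, dilated by a voxel margin
    and clipped to grid bounds."""
    if mask.n_voxels == 0:
        raise DegenerateInputError("empty mask has no bounding box")
    slices = []
    for ax in range(3):
        proj = mask.data.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - margin_vox, 0)
        hi = min(int(idx[-1]) + margin_vox + 1, mask.shape[ax])
        slices.append(slice(lo, hi))
    return tuple(slices)


def apply_mask_and_crop(vol: Volume, mask: ROIMask, margin_vox: int = 8) -> Volume:
    """Zero voxels outside the ROI and crop to the dilated mask bounding box.

    The margin keeps tumour boundary context in view of the conv stack's
    receptive field.
    """
    if vol.shape != mask.shape:
        raise GridMismatchError(
            f"volume grid {vol.shape} differs from mask grid {mask.shape}"
        )
    box = mask_bounding_box(mask, margin_vox)
    masked = np.where(mask.data, vol.data, 0.0)
    return Volume(masked[box], vol.spacing, vol.affine, vol.modality_tag)


def preprocess_subject(rec: SubjectRecord, target_mm: float = 1.0) -> SubjectRecord:
    """Resample every modality to an isotropic grid (trilinear), the mask by
    nearest neighbour, then z-score each volume over its nonzero support.

    Raises :class:`GridMismatchError` if the modalities do not land on one
    grid — co-registration is an upstream precondition, not performed here.
    """
    volumes = {}
    for tag, vol in rec.volumes.items():
        iso = resample_isotropic(vol, target_mm)
        volumes[tag] = zscore_normalize(iso)
    mask = resample_mask(rec.mask, target_mm)
    return SubjectRecord(
        subject_id=rec.subject_id, volumes=volumes, mask=mask,
        age=rec.age, sex=rec.sex, label=rec.label, scanner_id=rec.scanner_id,
    )


def dice_coefficient(a: ROIMask, b: ROIMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|), symmetric, in [0, 1]."""
    if a.shape != b.shape:
        raise GridMismatchError("masks must share a grid shape")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise DegenerateInputError("Dice is undefined for two empty masks")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)
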