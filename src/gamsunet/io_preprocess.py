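"""NIfTI I/O, slice extraction, normalization, resizing, augmentation, splits.

The pipeline mirrors the 2D slice-wise protocol used for ultra-high-field
T1-weighted volumes: per-volume z-scoring, axial slicing along the third
voxel axis (no reorientation to a canonical frame is attempted), bicubic
in-plane resizing of images with nearest-neighbour resizing of the binary
masks, flip/rotation augmentation on the training set only, and a
subject-level train/test split.  Each emitted slice carries its original
in-plane dimensions and voxel spacing so that volumetry can undo the
resize later.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

DEFAULT_TARGET = 256
ROTATION_RANGE_DEG = 15.0
AUGMENT_PROB = 0.5


@dataclass
class ImageVolume:
    """A 3D intensity grid with physical metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")


@dataclass
class MaskVolume:
    """Binary labels on the same grid as a paired :class:`ImageVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        vals = np.unique(self.labels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask labels must be binary, found {vals}")


@dataclass
class SliceSample:
    """One normalized 2D axial slice with provenance for volumetry."""

    image: np.ndarray
    mask: np.ndarray
    subject_id: str
    slice_index: int
    orig_dims: tuple[int, int]
    orig_spacing: tuple[float, float, float]

    def __post_init__(self):
        if not np.all(np.isfinite(self.image)):
            raise ValueError("slice image contains non-finite values")
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValueError("slice mask must be binary")
        if self.slice_index < 0 or min(self.orig_dims) < 1:
            raise ValueError("invalid slice provenance")


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subjects overlap")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_nifti(path: str | Path, as_mask: bool = False, subject_id: str | None = None):
    """Load a NIfTI volume; masks are binarized by ``label > 0``.

    Spacing comes from the header pixdim fields, the affine from the
    header's best available transform.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    if as_mask:
        return MaskVolume((data > 0).astype(np.uint8), spacing, img.affine, sid)
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite voxels")
    return ImageVolume(data, spacing, img.affine, sid)


def write_nifti(volume: ImageVolume | MaskVolume, path: str | Path) -> None:
    if isinstance(volume, MaskVolume):
        data = volume.labels.astype(np.uint8)
    else:
        data = np.asarray(volume.voxels)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "image_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# normalization / slicing / resizing
# ---------------------------------------------------------------------------

def znormalize(volume: ImageVolume) -> ImageVolume:
    """Zero-mean unit-variance scaling over all voxels of the volume."""
    v = np.asarray(volume.voxels, dtype=np.float64)
    std = v.std()
    if std == 0:
        raise ValueError(f"{volume.subject_id or 'volume'}: zero variance, cannot z-score")
    return replace(volume, voxels=(v - v.mean()) / std)


def resize_slice(image2d: np.ndarray, mask2d: np.ndarray,
                 target: int = DEFAULT_TARGET) -> tuple[np.ndarray, np.ndarray]:
    """Bicubic image resize and nearest-neighbour mask resize to target x target.

    Nearest-neighbour (rather than bicubic) is used for the mask so the
    label set stays binary.
    """
    image2d = np.asarray(image2d, dtype=np.float64)
    mask2d = np.asarray(mask2d)
    if image2d.ndim != 2 or image2d.size == 0 or mask2d.shape != image2d.shape:
        raise ValueError("inputs must be matching non-empty 2D arrays")
    if image2d.shape == (target, target):
        return image2d.copy(), mask2d.astype(np.uint8).copy()
    img = _sk_resize(image2d, (target, target), order=3, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(mask2d.astype(np.float64), (target, target), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return img, (msk > 0.5).astype(np.uint8)


def extract_slices(image: ImageVolume, mask: MaskVolume,
                   target: int = DEFAULT_TARGET) -> list[SliceSample]:
    """Every axial slice (third voxel axis), peripheral slices included."""
    if image.voxels.shape != mask.labels.shape:
        raise ValueError(
            f"image {image.voxels.shape} and mask {mask.labels.shape} dims differ"
        )
    dx, dy, dz = image.voxels.shape
    out = []
    for k in range(dz):
        img2d, msk2d = resize_slice(image.voxels[:, :, k], mask.labels[:, :, k], target)
        out.append(SliceSample(
            image=img2d, mask=msk2d, subject_id=image.subject_id, slice_index=k,
            orig_dims=(dx, dy), orig_spacing=image.spacing,
        ))
    return out


# ---------------------------------------------------------------------------
# augmentation / splitting
# ---------------------------------------------------------------------------

def augment(sample: SliceSample, rng: np.random.Generator) -> SliceSample:
    """Random horizontal flip and rotation, identically on image and mask.

    Flip and rotation each fire with probability 0.5; the angle is uniform
    in +-15 degrees.  The image is interpolated bilinearly, the mask with
    nearest neighbour so it stays binary.  Training-phase only by
    construction: the inference pipeline never calls this.
    """
    img, msk = sample.image, sample.mask
    if rng.random() < AUGMENT_PROB:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    if rng.random() < AUGMENT_PROB:
        angle = rng.uniform(-ROTATION_RANGE_DEG, ROTATION_RANGE_DEG)
        img = _sk_rotate(img, angle, order=1, mode="edge", preserve_range=True)
        msk = (_sk_rotate(msk.astype(np.float64), angle, order=0, mode="edge",
                          preserve_range=True) > 0.5).astype(np.uint8)
    return replace(sample, image=img, mask=msk)


def split_subjects(subject_ids: list[str], n_train: int, n_test: int, seed: int) -> SplitSpec:
    """Reproducible subject-level partition (e.g. 8 train / 4 test)."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if n_train + n_test > len(ids):
        raise ValueError(
            f"cannot split {len(ids)} subjects into {n_train} train + {n_test} test"
        )
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(ids))
    return SplitSpec(tuple(perm[:n_train]), tuple(perm[n_train:n_train + n_test]), seed)


def load_subject(manifest_row, target: int = DEFAULT_TARGET) -> list[SliceSample]:
    """Manifest row -> normalized, resized slice samples for one subject."""
    image = read_nifti(manifest_row["image_path"], subject_id=manifest_row["subject_id"])
    mask = read_nifti(manifest_row["mask_path"], as_mask=True,
                      subject_id=manifest_row["subject_id"])
    return extract_slices(znormalize(image), mask, target=target)
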