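"""NIfTI reading/writing and the slice-based preprocessing pipeline.

Pipeline order: load per-modality volumes -> map BraTS label codes
{0,1,2,4} to contiguous classes {0,1,2,3} -> min-max normalize each
volume to [0,1] -> slice axially -> resize (bilinear image / nearest
mask) -> one-hot encode -> shuffle and yield batches.

Volumes are kept in their native orientation; coordinates are 0-based
voxel indices. A dataset manifest is a CSV with one row per subject
listing the subject id and the paths of the four modality files plus
the label file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "MODALITIES", "CLASS_MAP", "INVERSE_CLASS_MAP", "VolumeSample", "SlicePair",
    "load_nifti", "save_nifti", "map_classes", "unmap_classes", "one_hot",
    "normalize", "resize_pair", "extract_slices", "batch_generator",
    "read_manifest", "write_manifest", "load_subject",
]

MODALITIES = ("flair", "t1", "t1ce", "t2")
CLASS_MAP = {0: 0, 1: 1, 2: 2, 4: 3}
INVERSE_CLASS_MAP = {v: k for k, v in CLASS_MAP.items()}


@dataclass
class VolumeSample:
    """One subject: four co-registered modality volumes plus labels."""

    subject_id: str
    modalities: dict  # name -> 3-D float array
    labels: np.ndarray  # 3-D integer array, BraTS codes {0,1,2,4}
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shapes = {m: v.shape for m, v in self.modalities.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"modalities disagree on shape: {shapes}")
        if self.labels.shape != next(iter(shapes.values())):
            raise ValueError(
                f"label shape {self.labels.shape} != modality shape {next(iter(shapes.values()))}")


@dataclass
class SlicePair:
    """One 2-D training example: image (H,W,C) and one-hot mask (H,W,K)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape[:2]} spatial shapes differ")


def load_nifti(path):
    """Load a 3-D NIfTI volume; returns (array, voxel spacing in mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def save_nifti(array, path, spacing=(1.0, 1.0, 1.0), like=None):
    """Write a 3-D array as NIfTI-1, optionally copying ``like``'s affine/header."""
    array = np.asarray(array)
    if like is not None:
        ref = nib.load(str(like))
        img = nib.Nifti1Image(array, ref.affine, ref.header.copy())
        img.header.set_data_dtype(array.dtype)
    else:
        affine = np.diag(list(spacing) + [1.0])
        img = nib.Nifti1Image(array, affine)
        img.header.set_zooms(spacing)
    nib.save(img, str(path))


def map_classes(labels: np.ndarray) -> np.ndarray:
    """Map BraTS label codes {0,1,2,4} to contiguous classes {0,1,2,3}."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    bad = np.setdiff1d(present, list(CLASS_MAP))
    if bad.size:
        raise ValueError(f"unexpected label value(s) {bad.tolist()}; expected subset of {{0,1,2,4}}")
    mapped = labels.copy()
    mapped[labels == 4] = 3
    return mapped


def unmap_classes(labels: np.ndarray) -> np.ndarray:
    """Inverse mapping {0,1,2,3} -> {0,1,2,4} for writing predictions."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), list(INVERSE_CLASS_MAP))
    if bad.size:
        raise ValueError(f"unexpected mapped label value(s) {bad.tolist()}")
    out = labels.copy()
    out[labels == 3] = 4
    return out


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Per-pixel indicator encoding; channel c marks class c."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(
            f"labels must lie in [0, {num_classes}), got range "
            f"[{labels.min()}, {labels.max()}]")
    return np.eye(num_classes, dtype=np.float64)[labels]


def normalize(image: np.ndarray) -> np.ndarray:
    """Min-max scale a volume to [0, 1]; a constant volume maps to zeros."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def resize_pair(image: np.ndarray, mask: np.ndarray, target: tuple):
    """Resize an image/mask pair to ``target`` (H, W).

    The image is bilinearly interpolated; the mask uses nearest-neighbor
    so labels are never blended and one-hot masks stay one-hot.
    """
    th, tw = target
    if th % 16 or tw % 16:
        raise ValueError(f"target size {target} must be divisible by 16")
    if image.shape[:2] == (th, tw):
        return image, mask
    image_r = _sk_resize(image, (th, tw) + image.shape[2:], order=1,
                         preserve_range=True, anti_aliasing=False)
    mask_r = _sk_resize(mask, (th, tw) + mask.shape[2:], order=0,
                        preserve_range=True, anti_aliasing=False)
    return image_r, mask_r.astype(mask.dtype)


def extract_slices(sample: VolumeSample, num_classes: int = 4,
                   target_size: tuple | None = None,
                   modalities: tuple = MODALITIES,
                   drop_empty: bool = False) -> list:
    """Axial slices of a subject as preprocessed :class:`SlicePair` objects.

    Each modality volume is min-max normalized as a whole before
    slicing; the requested modalities are stacked as channels.
    ``drop_empty`` discards slices whose mask is entirely background.
    """
    mapped = map_classes(sample.labels)
    normed = {m: normalize(sample.modalities[m]) for m in modalities}
    pairs = []
    for k in range(sample.labels.shape[2]):
        label_slice = mapped[:, :, k]
        if drop_empty and not label_slice.any():
            continue
        image = np.stack([normed[m][:, :, k] for m in modalities], axis=-1)
        mask = one_hot(label_slice, num_classes)
        if target_size is not None:
            image, mask = resize_pair(image, mask, target_size)
        pairs.append(SlicePair(image=image, mask=mask))
    return pairs


class batch_generator:
    """Re-iterable stream of (image batch, mask batch) arrays.

    Shuffles the slice order with the given seed once at construction;
    every slice appears exactly once per epoch and iteration order is
    identical across epochs and across instances built with the same
    seed.
    """

    def __init__(self, slices: list, batch_size: int = 4, seed: int = 0,
                 shuffle: bool = True):
        if not slices:
            raise ValueError("empty slice list")
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.slices = list(slices)
        self.batch_size = batch_size
        order = np.arange(len(self.slices))
        if shuffle:
            np.random.default_rng(seed).shuffle(order)
        self.order = order

    def __len__(self):
        return (len(self.slices) + self.batch_size - 1) // self.batch_size

    def __iter__(self):
        for start in range(0, len(self.order), self.batch_size):
            idx = self.order[start : start + self.batch_size]
            yield (np.stack([self.slices[i].image for i in idx]),
                   np.stack([self.slices[i].mask for i in idx]))


def write_manifest(rows: list, path) -> None:
    """Write a dataset manifest CSV: subject_id + per-modality and label paths."""
    fields = ["subject_id", *MODALITIES, "seg"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path) -> list:
    """Read a manifest CSV back as a list of row dicts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"manifest {path} is empty")
    return rows


def load_subject(row: dict, base_dir=None) -> VolumeSample:
    """Load one manifest row into a :class:`VolumeSample`."""
    base = Path(base_dir) if base_dir else Path(".")
    modalities = {}
    spacing = (1.0, 1.0, 1.0)
    for m in MODALITIES:
        vol, spacing = load_nifti(base / row[m])
        modalities[m] = np.asarray(vol, dtype=np.float64)
    labels, _ = load_nifti(base / row["seg"])
    return VolumeSample(subject_id=row["subject_id"], modalities=modalities,
                        labels=np.asarray(labels).astype(np.int64), spacing=spacing)
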