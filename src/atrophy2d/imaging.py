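"""NIfTI I/O and the 2D preprocessing chain.

A 3D volume is reduced to an ordered stack of axial 2D slices the way a
thick-slice clinical acquisition would sample it: find the axial extent of
the head, take every `stride`-th slice across that extent (paired label
slices share the same indices), then per-slice Z-score normalization for the
network input and morphological closing (square kernel, default 5) to smooth
label masks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.morphology import closing, footprint_rectangle

log = logging.getLogger(__name__)

__all__ = [
    "BrainVolume",
    "SliceStack",
    "read_volume",
    "write_volume",
    "extract_slices",
    "znormalize",
    "close_mask",
]


@dataclass
class BrainVolume:
    """A 3D grid with voxel spacing in mm and an axial-axis designation."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    axial_axis: int = 2

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim} dims")
        if any(s <= 0 for s in self.voxel_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_mm}")
        if self.axial_axis not in (0, 1, 2):
            raise ValueError(f"axial axis must be 0, 1 or 2, got {self.axial_axis}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_mm) + [1.0])

    @property
    def n_axial(self) -> int:
        return self.data.shape[self.axial_axis]

    def axial_slice(self, index: int) -> np.ndarray:
        return np.take(self.data, index, axis=self.axial_axis)


@dataclass
class SliceStack:
    """Ordered axial 2D images sampled from one subject's volume."""

    subject_id: str
    images: np.ndarray              # (n_slices, H, W)
    indices: np.ndarray             # source axial indices, strictly increasing
    labels: np.ndarray | None = None  # (n_slices, H, W) integer labels
    normalized: bool = False

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, H, W) array")
        if len(self.indices) != len(self.images):
            raise ValueError("one source index per slice required")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("source indices must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.images.shape:
                raise ValueError("label slices must align with image slices")

    def __len__(self) -> int:
        return len(self.images)


def read_volume(path: str | Path, labels: bool = False) -> BrainVolume:
    """Read a NIfTI volume; with labels=True the data must be integral."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3 spatial dims, got {data.ndim}")
    if labels:
        if not np.all(np.equal(np.mod(data, 1), 0)):
            raise TypeError(f"{path}: label volume contains non-integer values")
        data = data.astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BrainVolume(data=data, voxel_mm=spacing, affine=np.asarray(img.affine))


def write_volume(path: str | Path, volume: BrainVolume, labels: bool = False) -> Path:
    path = Path(path)
    data = volume.data
    if labels:
        if not np.all(np.equal(np.mod(data, 1), 0)):
            raise TypeError("label volume contains non-integer values")
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, affine=volume.affine)
    img.header.set_zooms(volume.voxel_mm)
    nib.save(img, str(path))
    return path


def _head_extent(volume: BrainVolume, frac: float, pct: float) -> tuple[int, int]:
    """Axial index range of the head: a slice belongs to the head when more
    than `frac` of its pixels exceed the volume's `pct`-percentile intensity."""
    threshold = float(np.percentile(volume.data, pct))
    counts = []
    for i in range(volume.n_axial):
        sl = volume.axial_slice(i)
        counts.append(np.count_nonzero(sl > threshold) / sl.size)
    is_head = np.asarray(counts) > frac
    idx = np.flatnonzero(is_head)
    if idx.size == 0:
        raise ValueError("empty head extent: no axial slice exceeds the "
                         f"threshold rule (>{frac:.3%} of pixels above "
                         f"percentile {pct})")
    return int(idx[0]), int(idx[-1])


def extract_slices(
    volume: BrainVolume,
    labels: BrainVolume | None = None,
    stride: int = 15,
    subject_id: str = "S0",
    head_frac: float = 0.005,
    head_pct: float = 5.0,
    offset: int = 0,
) -> SliceStack:
    """Sample every `stride`-th axial slice across the head extent.

    Selected indices are head_start + offset, +stride, ... while <= head_end
    (both ends of the extent inclusive). Paired label slices, when a label
    volume is given, are taken at exactly the same indices. A 480-slice
    volume whose head spans 300 slices yields 20 slices at stride 15.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    start, end = _head_extent(volume, head_frac, head_pct)
    if labels is not None and labels.data.shape != volume.data.shape:
        raise ValueError("label volume shape differs from intensity volume")
    indices = np.arange(start + offset, end + 1, stride, dtype=np.int64)
    if indices.size == 0:
        log.warning("stride %d exceeds head extent [%d, %d]; returning the "
                    "single slice at head start", stride, start, end)
        indices = np.array([start], dtype=np.int64)
    images = np.stack([volume.axial_slice(int(i)) for i in indices])
    lab = None
    if labels is not None:
        lab = np.stack([labels.axial_slice(int(i)) for i in indices])
    return SliceStack(subject_id=subject_id, images=images, indices=indices,
                      labels=lab)


def znormalize(image: np.ndarray) -> np.ndarray:
    """Whole-slice Z-score normalization: (x - mean) / SD.

    A constant slice has SD 0; it maps to all zeros (SD treated as 1) with a
    warning, so degenerate slices never produce NaNs downstream.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot normalize an empty image")
    mean = image.mean()
    sd = image.std()
    if sd == 0:
        warnings.warn("constant slice: Z-score SD treated as 1", stacklevel=2)
        sd = 1.0
    return (image - mean) / sd


def close_mask(mask: np.ndarray, kernel_size: int = 5) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a square
    structuring element. Extensive (output superset of input) and idempotent."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel size must be an odd positive integer, "
                         f"got {kernel_size}")
    mask = np.asarray(mask).astype(bool)
    return closing(mask, footprint_rectangle((kernel_size, kernel_size)))


def save_stack(stack: SliceStack, out_dir: str | Path) -> None:
    """Store a slice stack as NIfTI plus a JSON sidecar of source indices."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol = BrainVolume(np.moveaxis(stack.images, 0, -1).astype(np.float32))
    write_volume(out / f"{stack.subject_id}_slices.nii.gz", vol)
    if stack.labels is not None:
        lvol = BrainVolume(np.moveaxis(stack.labels, 0, -1))
        write_volume(out / f"{stack.subject_id}_labels.nii.gz", lvol, labels=True)
    sidecar = {"subject_id": stack.subject_id,
               "source_indices": stack.indices.tolist(),
               "normalized": stack.normalized}
    (out / f"{stack.subject_id}_slices.json").write_text(
        json.dumps(sidecar, indent=2))
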