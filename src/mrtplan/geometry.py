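"""Tumor segmentation and volume-versus-depth reduction.

Contrast-enhanced volumetric images are segmented by a global intensity
threshold (optionally keeping only the largest 6-connected component),
converted to physical volumes via the voxel spacing, and reduced to a
tumor-volume profile along the beam (depth) axis measured from the skin
surface.

Conventions: voxel indices are 0-based; a voxel's physical position is
its center; depth bins are half-open [lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumetricImage",
    "SegmentationResult",
    "TumorVolumeProfile",
    "segment_threshold",
    "mask_volume",
    "volume_vs_depth",
]


@dataclass(frozen=True)
class VolumetricImage:
    """3-D intensity array with physical voxel spacing and beam-axis metadata."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beam_axis: int = 2

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("image must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if self.beam_axis not in (0, 1, 2):
            raise ValueError("beam axis must be 0, 1 or 2")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    threshold: float
    kept_largest_component: bool


@dataclass(frozen=True)
class TumorVolumeProfile:
    """Tumor volume per half-open depth bin, depths from the skin surface."""

    bin_edges_mm: np.ndarray
    volume_mm3: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_mm, dtype=float)
        vols = np.asarray(self.volume_mm3, dtype=float)
        if edges.ndim != 1 or len(edges) != len(vols) + 1:
            raise ValueError("need n+1 bin edges for n volumes")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(vols < 0):
            raise ValueError("bin volumes must be >= 0")
        object.__setattr__(self, "bin_edges_mm", edges)
        object.__setattr__(self, "volume_mm3", vols)

    @property
    def bin_centers_mm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_mm[:-1] + self.bin_edges_mm[1:])

    @property
    def total_volume_mm3(self) -> float:
        return float(self.volume_mm3.sum())


def segment_threshold(
    image: VolumetricImage, threshold: float, keep_largest: bool = True
) -> SegmentationResult:
    """Segment by global intensity threshold (voxels with intensity >= threshold).

    With ``keep_largest`` only the largest 6-connected component
    survives, suppressing noise speckle; an empty thresholded mask then
    raises (no tumor found).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = image.data >= threshold
    if keep_largest:
        if not mask.any():
            raise ValueError(f"no voxels at or above threshold {threshold}; no tumor found")
        labels, n = ndimage.label(mask)  # default structure = 6-connectivity in 3-D
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return SegmentationResult(mask=mask, threshold=float(threshold),
                              kept_largest_component=keep_largest)


def mask_volume(result: SegmentationResult, spacing_mm: tuple[float, float, float]) -> float:
    """Physical mask volume: voxel count times voxel volume (mm^3)."""
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("voxel spacing must be strictly positive")
    return float(result.mask.sum()) * float(np.prod(spacing_mm))


def volume_vs_depth(
    result: SegmentationResult,
    image: VolumetricImage,
    skin_depth_offset_mm: float = 0.0,
    bin_width_mm: float | None = None,
) -> TumorVolumeProfile:
    """Reduce a segmentation to tumor volume per depth bin along the beam axis.

    The depth of slice i is ``origin + i * spacing`` along the beam axis
    plus ``skin_depth_offset_mm`` (the distance from the skin surface to
    the first slice). Bins are half-open [lo, hi) of ``bin_width_mm``
    (default: the slice spacing, lossless at native resolution); bin
    volumes sum exactly to the total mask volume.
    """
    if result.mask.shape != image.data.shape:
        raise ValueError("mask and image shapes differ")
    axis = image.beam_axis
    spacing = image.spacing_mm[axis]
    if bin_width_mm is None:
        bin_width_mm = spacing
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")

    n_slices = image.data.shape[axis]
    slice_depth = image.origin_mm[axis] + skin_depth_offset_mm + np.arange(n_slices) * spacing
    counts = np.moveaxis(result.mask, axis, 0).reshape(n_slices, -1).sum(axis=1)

    start = slice_depth[0]
    idx = np.floor((slice_depth - start) / bin_width_mm + 1e-9).astype(int)
    n_bins = int(idx.max()) + 1
    volumes = np.bincount(idx, weights=counts, minlength=n_bins) * image.voxel_volume_mm3
    edges = start + bin_width_mm * np.arange(n_bins + 1)
    return TumorVolumeProfile(bin_edges_mm=edges, volume_mm3=volumes)
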