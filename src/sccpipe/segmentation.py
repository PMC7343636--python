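"""Volumetric fluorescent-cell segmentation.

Chain: 3D Gaussian smoothing (kernel size 8 voxels, i.e. sigma = 2 voxels)
-> global Otsu binarization on a 256-bin histogram -> connected components
under 26-connectivity -> removal of objects of 4 or fewer voxels.  One
connected component is counted as one cell; per-object total fluorescence is
summed over the object's voxels from the *pre-smoothing* normalized
intensities (smoothing is a detection aid, not a quantification step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegenerateInputError, ValidationError
from .io import ImageStack

__all__ = [
    "SegmentationParams",
    "SegmentedObject",
    "SegmentationResult",
    "gaussian_smooth",
    "otsu_threshold",
    "label_components",
    "remove_small_objects",
    "segment",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation settings; the defaults are the assay's published ones."""

    smoothing_kernel_size: int = 8
    smoothing_sigma: float | None = None  # None -> kernel_size / 4 (= 2.0 voxels)
    min_object_voxels: int = 5
    connectivity: int = 26
    histogram_bins: int = 256
    per_slice_smoothing: bool = False  # 2D smoothing for anisotropy-sensitive users

    def __post_init__(self) -> None:
        if self.smoothing_kernel_size < 1:
            raise ValidationError("smoothing kernel size must be >= 1")
        if self.min_object_voxels < 1:
            raise ValidationError("min_object_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValidationError("connectivity must be one of {6, 18, 26}")
        if self.histogram_bins < 2:
            raise ValidationError("histogram_bins must be >= 2")
        if self.smoothing_sigma is not None and self.smoothing_sigma <= 0:
            raise ValidationError("smoothing_sigma must be positive")

    @property
    def sigma(self) -> float:
        return (
            self.smoothing_sigma
            if self.smoothing_sigma is not None
            else self.smoothing_kernel_size / 4.0
        )


@dataclass(frozen=True)
class SegmentedObject:
    label: int
    voxel_count: int
    centroid: tuple  # (z, y, x), voxel coordinates
    total_fluorescence: float


@dataclass
class SegmentationResult:
    """Label volume (0 = background) plus per-object summaries."""

    label_volume: np.ndarray
    objects: list = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": o.label,
                "voxel_count": o.voxel_count,
                "centroid_z": o.centroid[0],
                "centroid_y": o.centroid[1],
                "centroid_x": o.centroid[2],
                "total_fluorescence": o.total_fluorescence,
            }
            for o in self.objects
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "label", "voxel_count", "centroid_z", "centroid_y", "centroid_x",
                "total_fluorescence",
            ],
        )


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def gaussian_smooth(stack: ImageStack, params: SegmentationParams) -> ImageStack:
    """3D Gaussian smoothing with a window truncated at ``kernel_size`` voxels.

    The filter radius per axis is kernel_size / 2, so the full window spans
    kernel_size (+1 center) voxels; borders are reflect-padded, conserving
    total intensity away from the borders.
    """
    k = params.smoothing_kernel_size
    smoothed_axes = stack.shape[1:] if params.per_slice_smoothing else stack.shape
    if k > min(smoothed_axes):
        raise ValidationError(
            f"smoothing kernel {k} exceeds the smallest smoothed axis {min(smoothed_axes)}"
        )
    sigma = params.sigma
    truncate = (k / 2.0) / sigma
    vox = stack.voxels.astype(np.float64)
    if params.per_slice_smoothing:
        out = ndimage.gaussian_filter(
            vox, sigma=(0.0, sigma, sigma), truncate=truncate, mode="reflect"
        )
    else:
        out = ndimage.gaussian_filter(vox, sigma=sigma, truncate=truncate, mode="reflect")
    return stack.with_voxels(np.clip(out, 0.0, None))


def otsu_threshold(stack: ImageStack | np.ndarray, params: SegmentationParams | None = None):
    """Otsu's threshold over an equal-width histogram spanning [min, max].

    Maximizes the between-class variance over all cuts between histogram
    bins and returns the upper edge of the last bin of the background class;
    voxels strictly greater than the threshold are foreground.
    """
    params = params or SegmentationParams()
    vox = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    values = vox.ravel().astype(np.float64)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateInputError("constant volume has no Otsu threshold")

    nbins = params.histogram_bins
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    counts = counts.astype(np.float64)
    centers = (edges[:-1] + edges[1:]) / 2.0

    w = counts.sum()
    omega0 = np.cumsum(counts) / w                      # background weight up to bin k
    mu_cum = np.cumsum(counts * centers) / w
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    # between-class variance for a cut after bin k
    sigma_b = np.full(nbins, -np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        sb = (mu_total * omega0 - mu_cum) ** 2 / (omega0 * omega1)
    sigma_b[valid] = sb[valid]
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


def _summarize(labels: np.ndarray, n: int, intensity: np.ndarray | None) -> list:
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64), labels, index)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=np.float64), labels, index)
    if intensity is not None:
        totals = ndimage.sum_labels(intensity.astype(np.float64), labels, index)
    else:
        totals = np.zeros(n)
    return [
        SegmentedObject(
            label=int(lbl),
            voxel_count=int(round(cnt)),
            centroid=tuple(float(c) for c in cen),
            total_fluorescence=float(tot),
        )
        for lbl, cnt, cen, tot in zip(index, counts, centroids, totals)
    ]


def _relabel_scan_order(labels: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Renumber labels by the lexicographic scan position of each component's first voxel."""
    if n == 0:
        return labels, 0
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    first = np.full(n + 1, flat.size, dtype=np.int64)
    # reversed so earlier positions overwrite later ones
    first[flat[nz][::-1]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[labels], n


def label_components(
    binary: np.ndarray,
    connectivity: int = 26,
    intensity: np.ndarray | None = None,
) -> SegmentationResult:
    """Connected components of a binary volume (pre size-filter).

    Labels are consecutive positive integers assigned in lexicographic scan
    order of each component's first voxel.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValidationError("connectivity must be one of {6, 18, 26}")
    binary = np.asarray(binary).astype(bool)
    labels, n = ndimage.label(binary, structure=_structure(connectivity))
    labels, n = _relabel_scan_order(labels, n)
    return SegmentationResult(labels, _summarize(labels, n, intensity))


def remove_small_objects(
    result: SegmentationResult,
    min_object_voxels: int,
    intensity: np.ndarray | None = None,
) -> SegmentationResult:
    """Delete objects below the voxel-count floor; relabel survivors consecutively."""
    keep = [o for o in result.objects if o.voxel_count >= min_object_voxels]
    labels = result.label_volume
    remap = np.zeros(len(result.objects) + 1, dtype=labels.dtype)
    objects = []
    for new_label, o in enumerate(keep, start=1):
        remap[o.label] = new_label
        objects.append(
            SegmentedObject(new_label, o.voxel_count, o.centroid, o.total_fluorescence)
        )
    return SegmentationResult(remap[labels], objects)


def segment(stack: ImageStack, params: SegmentationParams | None = None) -> SegmentationResult:
    """Full chain: smooth -> Otsu -> 26-connected components -> size filter.

    ``total_fluorescence`` per object is summed from the input (normalized,
    pre-smoothing) intensities over the object's voxels.
    """
    params = params or SegmentationParams()
    smoothed = gaussian_smooth(stack, params)
    threshold = otsu_threshold(smoothed, params)
    binary = smoothed.voxels > threshold
    raw = stack.voxels.astype(np.float64)
    result = label_components(binary, params.connectivity, intensity=raw)
    return remove_small_objects(result, params.min_object_voxels, intensity=raw)
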