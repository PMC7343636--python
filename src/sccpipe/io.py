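"""Core imaging types plus TIFF and manifest input/output.

The pipeline's atomic object is a 3D voxel volume (``ImageStack``) with
acquisition metadata.  Axis order is fixed as ``(z, y, x)`` with 0-based
voxel indices throughout the package.  Intensities are stored on disk as
16-bit unsigned grayscale multi-page TIFF and processed in floating point.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ManifestError, UnsupportedFormatError, ValidationError

__all__ = [
    "Channel",
    "Modality",
    "Timepoint",
    "Group",
    "AcquisitionMetadata",
    "ImageStack",
    "BimodalAcquisition",
    "TumorROI",
    "SampleRecord",
    "MANIFEST_COLUMNS",
    "read_stack",
    "write_stack",
    "load_manifest",
    "read_manifest_table",
]


class Channel(str, enum.Enum):
    """Excitation channel: 488 nm (ZsGreen keratinocytes) or 532 nm (tdTomato cSCC)."""

    GFP_488 = "GFP_488"
    RFP_532 = "RFP_532"


class Modality(str, enum.Enum):
    reflectance = "reflectance"
    fluorescence = "fluorescence"


class Timepoint(str, enum.Enum):
    pre = "pre"
    post = "post"


class Group(str, enum.Enum):
    control = "control"
    treated_1x = "treated_1x"
    treated_2x = "treated_2x"


#: z-spacing sanity bounds (um) around the instrument's stated 1.5-5.3 um range.
Z_SPACING_BOUNDS_UM = (1.0, 6.0)


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition settings attached to every stack.

    ``laser_power`` and ``detector_gain`` are in instrument units relative to
    an arbitrary reference; only their ratios to the normalization reference
    matter downstream.
    """

    channel: Channel
    modality: Modality
    timepoint: Timepoint
    laser_power: float = 1.0
    detector_gain: float = 1.0
    lateral_pixel_um: float = 1.1
    z_spacing_um: float = 3.1
    batch_id: str = "batch0"

    def __post_init__(self) -> None:
        if self.laser_power <= 0 or self.detector_gain <= 0:
            raise ValidationError(
                f"laser_power and detector_gain must be strictly positive, got "
                f"{self.laser_power}, {self.detector_gain}"
            )
        lo, hi = Z_SPACING_BOUNDS_UM
        if not (lo <= self.z_spacing_um <= hi):
            raise ValidationError(
                f"z_spacing_um {self.z_spacing_um} outside sanity bounds [{lo}, {hi}]"
            )
        if self.lateral_pixel_um <= 0:
            raise ValidationError("lateral_pixel_um must be positive")

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        """Physical voxel size as (z, y, x) in micrometres."""
        return (self.z_spacing_um, self.lateral_pixel_um, self.lateral_pixel_um)


@dataclass
class ImageStack:
    """A 3D intensity volume (z, y, x) with its acquisition metadata."""

    voxels: np.ndarray
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("voxel intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValidationError("voxel intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def astype_float(self) -> "ImageStack":
        return ImageStack(self.voxels.astype(np.float64, copy=False), self.metadata)

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, self.metadata)

    def with_metadata(self, **kwargs) -> "ImageStack":
        return ImageStack(self.voxels, replace(self.metadata, **kwargs))


@dataclass
class BimodalAcquisition:
    """Simultaneously acquired reflectance + fluorescence stacks of one channel."""

    reflectance: ImageStack
    fluorescence: ImageStack

    def __post_init__(self) -> None:
        if self.reflectance.shape != self.fluorescence.shape:
            raise ValidationError(
                f"reflectance shape {self.reflectance.shape} != "
                f"fluorescence shape {self.fluorescence.shape}"
            )
        mr, mf = self.reflectance.metadata, self.fluorescence.metadata
        if (mr.lateral_pixel_um, mr.z_spacing_um) != (mf.lateral_pixel_um, mf.z_spacing_um):
            raise ValidationError("geometry differs between reflectance and fluorescence")
        if mr.channel != mf.channel or mr.timepoint != mf.timepoint:
            raise ValidationError("channel/timepoint differ between the paired stacks")


@dataclass(frozen=True)
class TumorROI:
    """Axis-aligned half-open voxel box delimiting one tumor spheroid."""

    roi_id: str
    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (self.z0 < self.z1 and self.y0 < self.y1 and self.x0 < self.x1):
            raise ValidationError(f"ROI {self.roi_id} has empty or inverted bounds")
        if min(self.z0, self.y0, self.x0) < 0:
            raise ValidationError(f"ROI {self.roi_id} has negative bounds")

    def contains(self, point) -> bool:
        z, y, x = point
        return (
            self.z0 <= z < self.z1 and self.y0 <= y < self.y1 and self.x0 <= x < self.x1
        )

    def overlaps(self, other: "TumorROI") -> bool:
        return (
            self.z0 < other.z1 and other.z0 < self.z1
            and self.y0 < other.y1 and other.y0 < self.y1
            and self.x0 < other.x1 and other.x0 < self.x1
        )

    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "z0": self.z0, "z1": self.z1,
            "y0": self.y0, "y1": self.y1,
            "x0": self.x0, "x1": self.x1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TumorROI":
        return cls(**{k: d[k] for k in ("roi_id", "z0", "z1", "y0", "y1", "x0", "x1")})


@dataclass
class SampleRecord:
    """One biological construct with its paired pre/post bimodal acquisitions."""

    sample_id: str
    group: Group
    acquisitions: dict  # (Timepoint, Channel) -> BimodalAcquisition
    tumor_rois: list = field(default_factory=list)
    qc_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        channels = {ch for (_, ch) in self.acquisitions}
        for ch in channels:
            for tp in (Timepoint.pre, Timepoint.post):
                if (tp, ch) not in self.acquisitions:
                    raise ValidationError(
                        f"sample {self.sample_id}: missing {tp.value} acquisition "
                        f"for channel {ch.value}"
                    )
        for i, a in enumerate(self.tumor_rois):
            for b in self.tumor_rois[i + 1:]:
                if a.overlaps(b):
                    raise ValidationError(
                        f"sample {self.sample_id}: ROIs {a.roi_id} and {b.roi_id} overlap"
                    )

    def get(self, timepoint: Timepoint, channel: Channel) -> BimodalAcquisition:
        return self.acquisitions[(timepoint, channel)]


# --------------------------------------------------------------------------
# TIFF I/O
# --------------------------------------------------------------------------

def read_stack(path, metadata: AcquisitionMetadata) -> ImageStack:
    """Read a multi-page grayscale TIFF into an ImageStack (pages stacked along z)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            if len(tf.series) != 1:
                raise UnsupportedFormatError(
                    f"{path}: pages have mismatched sizes ({len(tf.series)} series)"
                )
            series = tf.series[0]
            if "S" in series.axes or series.keyframe.samplesperpixel > 1:
                raise UnsupportedFormatError(
                    f"{path}: expected single-sample grayscale pages, got axes {series.axes!r}"
                )
            arr = series.asarray()
    except (ValueError, tifffile.TiffFileError) as exc:
        raise UnsupportedFormatError(f"{path}: cannot read as a uniform stack ({exc})") from exc
    arr = np.asarray(arr)
    if arr.dtype == object:
        raise UnsupportedFormatError(f"{path}: pages have mismatched sizes")
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    return ImageStack(arr, metadata)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as 16-bit grayscale multi-page TIFF (values clipped/rounded)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(stack.voxels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_stack_float(path, stack: ImageStack) -> None:
    """Write a stack as float32 TIFF (for normalized intermediates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels.astype(np.float32), photometric="minisblack")


# --------------------------------------------------------------------------
# Manifest
# --------------------------------------------------------------------------

#: One manifest row per (sample, timepoint, channel): a bimodal acquisition.
MANIFEST_COLUMNS = [
    "sample_id",
    "group",
    "timepoint",
    "channel",
    "reflectance_path",
    "fluorescence_path",
    "laser_power",
    "detector_gain",
    "lateral_pixel_um",
    "z_spacing_um",
    "batch_id",
    "rois_path",
]


def read_manifest_table(path) -> pd.DataFrame:
    """Read and structurally validate the manifest CSV without loading images."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    table = pd.read_csv(path, dtype={"sample_id": str, "batch_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns and c != "rois_path"]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    if "rois_path" not in table.columns:
        table["rois_path"] = ""
    if len(table) == 0:
        return table

    bad_groups = sorted(set(table["group"]) - {g.value for g in Group})
    if bad_groups:
        raise ManifestError(f"unknown group labels: {bad_groups}")
    dup = table.duplicated(subset=["sample_id", "timepoint", "channel"])
    if dup.any():
        offenders = sorted(table.loc[dup, "sample_id"].unique())
        raise ManifestError(f"duplicate (sample, timepoint, channel) rows for: {offenders}")
    for sid, rows in table.groupby("sample_id"):
        if rows["group"].nunique() != 1:
            raise ManifestError(f"sample {sid}: inconsistent group labels")
        for ch in rows["channel"].unique():
            tps = set(rows.loc[rows["channel"] == ch, "timepoint"])
            for needed in ("pre", "post"):
                if needed not in tps:
                    raise ManifestError(
                        f"sample {sid}: channel {ch} lacks its {needed} acquisition"
                    )
    return table


def _load_rois(rois_path, base: Path) -> list:
    if not rois_path or (isinstance(rois_path, float) and np.isnan(rois_path)):
        return []
    p = Path(rois_path)
    if not p.is_absolute():
        p = base / p
    with open(p) as fh:
        return [TumorROI.from_dict(d) for d in json.load(fh)]


def load_manifest(path) -> list:
    """Load a manifest CSV into fully populated SampleRecords.

    Relative stack paths are resolved against the manifest's directory.
    """
    path = Path(path)
    table = read_manifest_table(path)
    base = path.parent
    records = []
    for sid, rows in table.groupby("sample_id", sort=True):
        acquisitions = {}
        rois: list = []
        for row in rows.itertuples(index=False):
            tp = Timepoint(row.timepoint)
            ch = Channel(row.channel)
            stacks = {}
            for modality, col in (
                (Modality.reflectance, row.reflectance_path),
                (Modality.fluorescence, row.fluorescence_path),
            ):
                p = Path(col)
                if not p.is_absolute():
                    p = base / p
                meta = AcquisitionMetadata(
                    channel=ch,
                    modality=modality,
                    timepoint=tp,
                    laser_power=float(row.laser_power),
                    detector_gain=float(row.detector_gain),
                    lateral_pixel_um=float(row.lateral_pixel_um),
                    z_spacing_um=float(row.z_spacing_um),
                    batch_id=str(row.batch_id),
                )
                stacks[modality] = read_stack(p, meta)
            acquisitions[(tp, ch)] = BimodalAcquisition(
                reflectance=stacks[Modality.reflectance],
                fluorescence=stacks[Modality.fluorescence],
            )
            if getattr(row, "rois_path", "") and not rois:
                rois = _load_rois(row.rois_path, base)
        records.append(
            SampleRecord(
                sample_id=str(sid),
                group=Group(rows["group"].iloc[0]),
                acquisitions=acquisitions,
                tumor_rois=rois,
            )
        )
    return records
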