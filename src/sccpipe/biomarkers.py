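"""Imaging biomarkers and treatment effect.

Two biomarkers per analysis unit: the number of segmented objects (cells)
and their total fluorescence.  For GFP keratinocytes the unit is the whole
construct; for RFP cSCC it is the individual tumor ROI, objects being
assigned to the ROI containing their centroid.  The treatment effect is the
post-treatment value expressed as a percent of the pre-treatment value.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import UndefinedBaselineError, ValidationError
from .io import Channel, SampleRecord, Timepoint, TumorROI
from .segmentation import SegmentationResult

__all__ = [
    "WHOLE_SAMPLE",
    "UNASSIGNED",
    "Metric",
    "BiomarkerMeasurement",
    "TreatmentEffect",
    "BleedthroughQC",
    "measure",
    "treatment_effect",
    "treatment_effects",
    "qc_bleedthrough",
]

WHOLE_SAMPLE = "WHOLE_SAMPLE"
UNASSIGNED = "UNASSIGNED"


class Metric(str, enum.Enum):
    n_objects = "n_objects"
    total_fluorescence = "total_fluorescence"


@dataclass(frozen=True)
class BiomarkerMeasurement:
    sample_id: str
    timepoint: Timepoint
    channel: Channel
    roi_id: str
    n_objects: int
    total_fluorescence: float

    def __post_init__(self) -> None:
        if self.n_objects < 0 or self.total_fluorescence < 0:
            raise ValidationError("biomarker values must be non-negative")
        if self.n_objects == 0 and self.total_fluorescence != 0:
            raise ValidationError("total_fluorescence must be 0 when no objects exist")

    def value(self, metric: Metric) -> float:
        return float(getattr(self, Metric(metric).value))


@dataclass(frozen=True)
class TreatmentEffect:
    sample_id: str
    channel: Channel
    roi_id: str
    metric: Metric
    percent_of_pre: float


def measure(
    sample: SampleRecord,
    seg: SegmentationResult,
    channel: Channel,
    timepoint: Timepoint,
    rois: list | None = None,
) -> list:
    """Biomarkers per analysis unit.

    GFP: one whole-sample measurement.  RFP: one measurement per tumor ROI
    (objects assigned by centroid containment) plus an ``UNASSIGNED`` bucket
    for objects outside every ROI, so that per-unit totals conserve the
    whole-stack totals.  ``rois`` defaults to the sample's tumor ROIs for the
    RFP channel; passing ROIs explicitly for GFP raises a warning (the
    keratinocyte biomarkers are whole-construct) but is not an error.
    """
    if channel == Channel.GFP_488:
        if rois:
            warnings.warn(
                f"sample {sample.sample_id}: tumor ROIs are ignored for the GFP "
                "channel (keratinocyte biomarkers are whole-construct)",
                stacklevel=2,
            )
        total = float(sum(o.total_fluorescence for o in seg.objects))
        return [
            BiomarkerMeasurement(
                sample.sample_id, timepoint, channel, WHOLE_SAMPLE,
                seg.n_objects, total if seg.n_objects else 0.0,
            )
        ]

    if rois is None:
        rois = sample.tumor_rois
    buckets: dict[str, list] = {r.roi_id: [] for r in rois}
    buckets[UNASSIGNED] = []
    for o in seg.objects:
        assigned = UNASSIGNED
        for roi in rois:
            if roi.contains(o.centroid):
                assigned = roi.roi_id
                break
        buckets[assigned].append(o)
    out = []
    for roi_id, objs in buckets.items():
        total = float(sum(o.total_fluorescence for o in objs))
        out.append(
            BiomarkerMeasurement(
                sample.sample_id, timepoint, channel, roi_id,
                len(objs), total if objs else 0.0,
            )
        )
    return out


def treatment_effect(
    pre: BiomarkerMeasurement,
    post: BiomarkerMeasurement,
    metric: Metric = Metric.n_objects,
) -> TreatmentEffect:
    """percent_of_pre = 100 * post / pre for one matched unit and metric."""
    metric = Metric(metric)
    if (pre.sample_id, pre.channel, pre.roi_id) != (post.sample_id, post.channel, post.roi_id):
        raise ValidationError("pre/post measurements do not describe the same unit")
    if pre.timepoint != Timepoint.pre or post.timepoint != Timepoint.post:
        raise ValidationError("expected a (pre, post) measurement pair")
    pre_value = pre.value(metric)
    if pre_value == 0:
        raise UndefinedBaselineError(
            f"sample {pre.sample_id} unit {pre.roi_id}: pre-treatment "
            f"{metric.value} is zero; percent-of-pre is undefined"
        )
    return TreatmentEffect(
        pre.sample_id, pre.channel, pre.roi_id, metric,
        100.0 * post.value(metric) / pre_value,
    )


def treatment_effects(pre: BiomarkerMeasurement, post: BiomarkerMeasurement) -> list:
    """Both metrics' effects for one unit (zero baselines are skipped)."""
    out = []
    for metric in Metric:
        try:
            out.append(treatment_effect(pre, post, metric))
        except UndefinedBaselineError:
            continue
    return out


@dataclass(frozen=True)
class BleedthroughQC:
    flagged: bool
    coincident_fraction: float
    n_gfp_objects: int


def qc_bleedthrough(
    seg_gfp: SegmentationResult,
    seg_rfp: SegmentationResult,
    cell_radius_um: float = 4.0,
    voxel_size_um: tuple = (3.1, 1.1, 1.1),
    threshold: float = 0.5,
) -> BleedthroughQC:
    """Flag inter-channel bleed-through.

    A sample is flagged when the fraction of GFP objects whose centroid lies
    within one cell radius (physical distance) of an RFP object centroid
    exceeds ``threshold``.  Flagged samples mirror the study's exclusion of
    batches acquired with a wrong optical filter.
    """
    if seg_gfp.n_objects == 0 or seg_rfp.n_objects == 0:
        return BleedthroughQC(False, 0.0, seg_gfp.n_objects)
    scale = np.asarray(voxel_size_um, dtype=float)
    gfp = np.array([o.centroid for o in seg_gfp.objects]) * scale
    rfp = np.array([o.centroid for o in seg_rfp.objects]) * scale
    tree = cKDTree(rfp)
    d, _ = tree.query(gfp, k=1)
    frac = float(np.mean(d <= cell_radius_um))
    return BleedthroughQC(frac > threshold, frac, seg_gfp.n_objects)
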