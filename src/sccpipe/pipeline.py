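"""End-to-end orchestration: normalize -> register -> segment -> measure -> stats.

``run_pipeline`` executes the whole chain in memory from a sample manifest
and writes the result tables; the ``*_stage`` functions expose the same
steps with file handoffs (normalized stacks, label volumes, object tables)
so every stage is independently runnable and testable from the CLI.
All outputs carry the configuration snapshot hash, and a run is
deterministic given its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from .exceptions import SccPipeError, UndefinedBaselineError, ValidationError
from .io import (
    Channel,
    Group,
    SampleRecord,
    Timepoint,
    load_manifest,
)
from .preprocess import (
    NormalizationReference,
    apply_transform,
    estimate_rigid_transform,
    normalize_stack,
    zsum_projection,
)
from .segmentation import SegmentationParams, SegmentationResult, SegmentedObject, segment
from .stats import (
    dose_response_summary,
    two_sample_t,
    two_way_anova_unbalanced,
)

logger = logging.getLogger("sccpipe")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable snapshot of every setting a run depends on."""

    manifest: str = "manifest.csv"
    outdir: str = "results"
    normalization: NormalizationReference = field(default_factory=NormalizationReference)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc_bleedthrough_threshold: float = 0.5
    qc_cell_radius_um: float = 4.0
    registration_max_rotation_deg: float = 6.0
    hedges_exact: bool = True
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("normalization"), dict):
            d["normalization"] = NormalizationReference(**d["normalization"])
        if isinstance(d.get("segmentation"), dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def snapshot_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SampleResult:
    sample_id: str
    group: Group
    transforms: dict  # timepoint -> RigidTransform2D
    segmentations: dict  # (timepoint, channel) -> SegmentationResult
    measurements: list
    effects: list
    qc_flags: list


@dataclass
class PipelineResult:
    biomarkers: pd.DataFrame
    effects: pd.DataFrame
    qc: pd.DataFrame
    comparisons: pd.DataFrame
    anova: dict | None
    dose_response: pd.DataFrame
    config_hash: str
    excluded_samples: list
    failed_samples: list


def _cell_type(channel: Channel) -> str:
    return "cSCC" if channel == Channel.RFP_532 else "keratinocyte"


def process_sample(sample: SampleRecord, config: PipelineConfig) -> SampleResult:
    """Normalize, register, segment and measure one sample in memory."""
    t0 = time.perf_counter()
    norm = config.normalization
    seg_params = config.segmentation

    fluo = {}
    transforms = {}
    for tp in (Timepoint.pre, Timepoint.post):
        gfp = sample.get(tp, Channel.GFP_488)
        rfp = sample.get(tp, Channel.RFP_532)
        # normalize before any cross-batch comparison; order vs registration is
        # immaterial for a linear scale
        gfp_fl = normalize_stack(gfp.fluorescence, norm)
        rfp_fl = normalize_stack(rfp.fluorescence, norm)
        fixed = zsum_projection(gfp.reflectance)
        moving = zsum_projection(rfp.reflectance)
        t = estimate_rigid_transform(
            fixed, moving, max_rotation_deg=config.registration_max_rotation_deg
        )
        transforms[tp] = t
        if not t.is_identity():
            rfp_fl = apply_transform(rfp_fl, t)
        fluo[(tp, Channel.GFP_488)] = gfp_fl
        fluo[(tp, Channel.RFP_532)] = rfp_fl

    segs = {key: segment(stack, seg_params) for key, stack in fluo.items()}

    qc_flags = list(sample.qc_flags)
    voxel = sample.get(Timepoint.pre, Channel.GFP_488).fluorescence.metadata.voxel_size_um
    for tp in (Timepoint.pre, Timepoint.post):
        qc = bm.qc_bleedthrough(
            segs[(tp, Channel.GFP_488)],
            segs[(tp, Channel.RFP_532)],
            cell_radius_um=config.qc_cell_radius_um,
            voxel_size_um=voxel,
            threshold=config.qc_bleedthrough_threshold,
        )
        if qc.flagged:
            qc_flags.append(
                f"bleedthrough_{tp.value}:{qc.coincident_fraction:.2f}"
            )

    measurements = []
    by_key = {}
    for (tp, ch), seg in segs.items():
        ms = bm.measure(sample, seg, ch, tp)
        measurements.extend(ms)
        for m in ms:
            by_key[(ch, m.roi_id, tp)] = m

    effects = []
    for (ch, roi_id, tp) in list(by_key):
        if tp != Timepoint.pre or roi_id == bm.UNASSIGNED:
            continue
        pre_m = by_key[(ch, roi_id, Timepoint.pre)]
        post_m = by_key.get((ch, roi_id, Timepoint.post))
        if post_m is None:
            continue
        effects.extend(bm.treatment_effects(pre_m, post_m))

    logger.info(
        "sample %s processed in %.2fs (qc=%s)",
        sample.sample_id, time.perf_counter() - t0, qc_flags or "ok",
    )
    return SampleResult(
        sample.sample_id, sample.group, transforms, segs, measurements, effects, qc_flags
    )


def _group_statistics(effects: pd.DataFrame, config: PipelineConfig):
    """Control-vs-treated comparisons, ANOVA and dose-response from the effect table."""
    clean = effects[~effects["qc_excluded"]]
    comparisons = []
    for (channel, metric), sub in clean.groupby(["channel", "metric"], sort=True):
        ctrl = sub.loc[sub["group"] == Group.control.value, "percent_of_pre"]
        trt = sub.loc[sub["group"] != Group.control.value, "percent_of_pre"]
        if len(ctrl) < 2 or len(trt) < 2:
            continue
        try:
            cmp = two_sample_t(ctrl, trt, labels=("control", "treated"))
        except SccPipeError as exc:
            logger.info("comparison %s/%s skipped: %s", channel, metric, exc)
            continue
        comparisons.append(
            {
                "channel": channel,
                "metric": metric,
                "control_n": cmp.summary_a.n,
                "control_mean": cmp.summary_a.mean,
                "control_sd": cmp.summary_a.sd,
                "treated_n": cmp.summary_b.n,
                "treated_mean": cmp.summary_b.mean,
                "treated_sd": cmp.summary_b.sd,
                "t_statistic": cmp.t_statistic,
                "df": cmp.degrees_of_freedom,
                "p_value": cmp.p_value,
                "hedges_g": cmp.hedges_g,
            }
        )
    comparisons = pd.DataFrame(comparisons)

    anova = None
    counts = clean[clean["metric"] == bm.Metric.n_objects.value]
    if len(counts):
        table = pd.DataFrame(
            {
                "value": counts["percent_of_pre"],
                "cell_type": counts["channel"].map(
                    lambda c: _cell_type(Channel(c))
                ),
                "treatment": np.where(
                    counts["group"] == Group.control.value, "untreated", "treated"
                ),
            }
        )
        try:
            anova = two_way_anova_unbalanced(table).factors
        except ValidationError as exc:
            logger.info("ANOVA skipped: %s", exc)

    rfp_counts = counts[counts["channel"] == Channel.RFP_532.value]
    by_group = {
        g: rfp_counts.loc[rfp_counts["group"] == g, "percent_of_pre"].to_numpy()
        for g in rfp_counts["group"].unique()
    }
    dose = (
        dose_response_summary(by_group)
        if by_group
        else pd.DataFrame(columns=["group", "n", "mean_reduction_pct", "sd_reduction_pct"])
    )
    return comparisons, anova, dose


def run_pipeline(
    config: PipelineConfig,
    samples: list | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run the full assay chain for every sample in the manifest.

    Samples that fail to process are skipped and logged; samples with QC
    flags are kept in the biomarker/effect tables but excluded from the
    group statistics.  Raises if no sample processes successfully.
    """
    if samples is None:
        samples = load_manifest(config.manifest)
    results = []
    failed = []
    for sample in samples:
        try:
            results.append(process_sample(sample, config))
        except SccPipeError as exc:
            logger.warning("sample %s skipped: %s", sample.sample_id, exc)
            failed.append((sample.sample_id, str(exc)))
    if not results:
        raise SccPipeError("no sample could be processed")

    config_hash = config.snapshot_hash
    group_of = {r.sample_id: r.group.value for r in results}
    flags_of = {r.sample_id: ";".join(r.qc_flags) for r in results}
    excluded = sorted(r.sample_id for r in results if r.qc_flags)

    biomark_rows = []
    for r in results:
        for m in r.measurements:
            biomark_rows.append(
                {
                    "sample_id": m.sample_id,
                    "group": group_of[m.sample_id],
                    "timepoint": m.timepoint.value,
                    "channel": m.channel.value,
                    "roi_id": m.roi_id,
                    "n_objects": m.n_objects,
                    "total_fluorescence": m.total_fluorescence,
                    "qc_flags": flags_of[m.sample_id],
                    "config_hash": config_hash,
                }
            )
    biomarkers_df = pd.DataFrame(biomark_rows).sort_values(
        ["sample_id", "timepoint", "channel", "roi_id"], ignore_index=True
    )

    effect_rows = []
    for r in results:
        pre_vals = {
            (m.channel, m.roi_id): m
            for m in r.measurements
            if m.timepoint == Timepoint.pre
        }
        post_vals = {
            (m.channel, m.roi_id): m
            for m in r.measurements
            if m.timepoint == Timepoint.post
        }
        for e in r.effects:
            pre_m = pre_vals[(e.channel, e.roi_id)]
            post_m = post_vals[(e.channel, e.roi_id)]
            effect_rows.append(
                {
                    "sample_id": e.sample_id,
                    "group": group_of[e.sample_id],
                    "channel": e.channel.value,
                    "roi_id": e.roi_id,
                    "metric": e.metric.value,
                    "pre_value": pre_m.value(e.metric),
                    "post_value": post_m.value(e.metric),
                    "percent_of_pre": e.percent_of_pre,
                    "qc_flags": flags_of[e.sample_id],
                    "qc_excluded": bool(flags_of[e.sample_id]),
                    "config_hash": config_hash,
                }
            )
    effects_df = pd.DataFrame(effect_rows).sort_values(
        ["sample_id", "channel", "roi_id", "metric"], ignore_index=True
    )

    qc_df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "group": r.group.value,
                "qc_flags": flags_of[r.sample_id],
                "excluded": bool(r.qc_flags),
                "config_hash": config_hash,
            }
            for r in results
        ]
    )

    comparisons, anova, dose = _group_statistics(effects_df, config)
    if len(comparisons):
        comparisons["config_hash"] = config_hash
    if len(dose):
        dose["config_hash"] = config_hash

    result = PipelineResult(
        biomarkers=biomarkers_df,
        effects=effects_df,
        qc=qc_df,
        comparisons=comparisons,
        anova=anova,
        dose_response=dose,
        config_hash=config_hash,
        excluded_samples=excluded,
        failed_samples=failed,
    )
    if write_outputs:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_snapshot.yaml")
    result.biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    result.effects.to_csv(outdir / "effects.csv", index=False)
    result.qc.to_csv(outdir / "qc.csv", index=False)
    result.comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
    result.dose_response.to_csv(outdir / "dose_response.csv", index=False)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(
            {
                "config_hash": result.config_hash,
                "comparisons": result.comparisons.to_dict(orient="records"),
                "anova": result.anova,
                "dose_response": result.dose_response.to_dict(orient="records"),
                "excluded_samples": result.excluded_samples,
                "failed_samples": result.failed_samples,
            },
            fh,
            indent=2,
        )


# --------------------------------------------------------------------------
# File-based stages (CLI)
# --------------------------------------------------------------------------

def preprocess_stage(config: PipelineConfig) -> Path:
    """Normalize + register every sample; write float32 stacks and transforms."""
    from .io import Modality, read_manifest_table, write_stack_float

    outdir = Path(config.outdir) / "preprocessed"
    outdir.mkdir(parents=True, exist_ok=True)
    samples = load_manifest(config.manifest)
    table = read_manifest_table(config.manifest)
    transforms = {}
    new_rows = []
    for sample in samples:
        for tp in (Timepoint.pre, Timepoint.post):
            gfp = sample.get(tp, Channel.GFP_488)
            rfp = sample.get(tp, Channel.RFP_532)
            t = estimate_rigid_transform(
                zsum_projection(gfp.reflectance),
                zsum_projection(rfp.reflectance),
                max_rotation_deg=config.registration_max_rotation_deg,
            )
            transforms[f"{sample.sample_id}/{tp.value}"] = t.to_dict()
            for ch, acq in ((Channel.GFP_488, gfp), (Channel.RFP_532, rfp)):
                fl = normalize_stack(acq.fluorescence, config.normalization)
                refl = acq.reflectance.astype_float()
                if ch == Channel.RFP_532 and not t.is_identity():
                    fl = apply_transform(fl, t)
                    refl = apply_transform(refl, t)
                base = f"{sample.sample_id}_{tp.value}_{ch.value}"
                write_stack_float(outdir / f"{base}_fluorescence.tif", fl)
                write_stack_float(outdir / f"{base}_reflectance.tif", refl)
                row = table[
                    (table.sample_id == sample.sample_id)
                    & (table.timepoint == tp.value)
                    & (table.channel == ch.value)
                ].iloc[0].to_dict()
                row.update(
                    reflectance_path=f"{base}_reflectance.tif",
                    fluorescence_path=f"{base}_fluorescence.tif",
                    laser_power=config.normalization.reference_laser_power,
                    detector_gain=config.normalization.reference_detector_gain,
                )
                if row.get("rois_path"):
                    src = Path(config.manifest).parent / str(row["rois_path"])
                    dst = outdir / Path(str(row["rois_path"])).name
                    if src.exists() and not dst.exists():
                        dst.write_bytes(src.read_bytes())
                new_rows.append(row)
    with open(outdir / "transforms.json", "w") as fh:
        json.dump(transforms, fh, indent=2)
    out_manifest = outdir / "manifest.csv"
    pd.DataFrame(new_rows).to_csv(out_manifest, index=False)
    return out_manifest


def segment_stage(config: PipelineConfig, normalized: bool = True) -> Path:
    """Segment every fluorescence stack; write label TIFFs and object CSVs."""
    from .io import write_stack

    outdir = Path(config.outdir) / "segmented"
    outdir.mkdir(parents=True, exist_ok=True)
    samples = load_manifest(config.manifest)
    index_rows = []
    for sample in samples:
        for (tp, ch), acq in sorted(
            sample.acquisitions.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            stack = acq.fluorescence
            if not normalized:
                stack = normalize_stack(stack, config.normalization)
            seg = segment(stack, config.segmentation)
            base = f"{sample.sample_id}_{tp.value}_{ch.value}"
            from .io import ImageStack  # local import to avoid cycle noise

            write_stack(
                outdir / f"{base}_labels.tif",
                ImageStack(seg.label_volume.astype(np.float64), stack.metadata),
            )
            seg.to_dataframe().to_csv(outdir / f"{base}_objects.csv", index=False)
            index_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "group": sample.group.value,
                    "timepoint": tp.value,
                    "channel": ch.value,
                    "objects_csv": f"{base}_objects.csv",
                    "n_objects": seg.n_objects,
                }
            )
    index = outdir / "segmentation_index.csv"
    pd.DataFrame(index_rows).to_csv(index, index=False)
    return index


def quantify_stage(config: PipelineConfig, seg_index: Path) -> Path:
    """Rebuild biomarkers + effects from stored object tables and ROIs."""
    seg_dir = Path(seg_index).parent
    samples = {s.sample_id: s for s in load_manifest(config.manifest)}
    index = pd.read_csv(seg_index, dtype={"sample_id": str})
    segs = {}
    for row in index.itertuples(index=False):
        df = pd.read_csv(seg_dir / row.objects_csv)
        objects = [
            SegmentedObject(
                int(r.label), int(r.voxel_count),
                (float(r.centroid_z), float(r.centroid_y), float(r.centroid_x)),
                float(r.total_fluorescence),
            )
            for r in df.itertuples(index=False)
        ]
        segs[(row.sample_id, Timepoint(row.timepoint), Channel(row.channel))] = (
            SegmentationResult(np.zeros((1, 1, 1), dtype=int), objects)
        )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows_b, rows_e = [], []
    config_hash = config.snapshot_hash
    for sid, sample in sorted(samples.items()):
        voxel = sample.get(Timepoint.pre, Channel.GFP_488).fluorescence.metadata.voxel_size_um
        qc_flags = []
        for tp in (Timepoint.pre, Timepoint.post):
            qc = bm.qc_bleedthrough(
                segs[(sid, tp, Channel.GFP_488)],
                segs[(sid, tp, Channel.RFP_532)],
                cell_radius_um=config.qc_cell_radius_um,
                voxel_size_um=voxel,
                threshold=config.qc_bleedthrough_threshold,
            )
            if qc.flagged:
                qc_flags.append(f"bleedthrough_{tp.value}:{qc.coincident_fraction:.2f}")
        flags = ";".join(qc_flags)
        measurements = {}
        for tp in (Timepoint.pre, Timepoint.post):
            for ch in (Channel.GFP_488, Channel.RFP_532):
                for m in bm.measure(sample, segs[(sid, tp, ch)], ch, tp):
                    measurements[(ch, m.roi_id, tp)] = m
                    rows_b.append(
                        {
                            "sample_id": sid,
                            "group": sample.group.value,
                            "timepoint": tp.value,
                            "channel": ch.value,
                            "roi_id": m.roi_id,
                            "n_objects": m.n_objects,
                            "total_fluorescence": m.total_fluorescence,
                            "qc_flags": flags,
                            "config_hash": config_hash,
                        }
                    )
        for (ch, roi_id, tp), pre_m in sorted(
            measurements.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            if tp != Timepoint.pre or roi_id == bm.UNASSIGNED:
                continue
            post_m = measurements.get((ch, roi_id, Timepoint.post))
            if post_m is None:
                continue
            for e in bm.treatment_effects(pre_m, post_m):
                rows_e.append(
                    {
                        "sample_id": sid,
                        "group": sample.group.value,
                        "channel": ch.value,
                        "roi_id": roi_id,
                        "metric": e.metric.value,
                        "pre_value": pre_m.value(e.metric),
                        "post_value": post_m.value(e.metric),
                        "percent_of_pre": e.percent_of_pre,
                        "qc_flags": flags,
                        "qc_excluded": bool(flags),
                        "config_hash": config_hash,
                    }
                )
    pd.DataFrame(rows_b).to_csv(outdir / "biomarkers.csv", index=False)
    effects_path = outdir / "effects.csv"
    pd.DataFrame(rows_e).to_csv(effects_path, index=False)
    return effects_path


def stats_stage(config: PipelineConfig, effects_csv: Path) -> Path:
    """Group statistics from a stored effect table."""
    effects = pd.read_csv(effects_csv, dtype={"sample_id": str})
    if "qc_excluded" not in effects.columns:
        effects["qc_excluded"] = False
    effects["qc_excluded"] = effects["qc_excluded"].fillna(False).astype(bool)
    comparisons, anova, dose = _group_statistics(effects, config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
    dose.to_csv(outdir / "dose_response.csv", index=False)
    out = outdir / "stats.json"
    with open(out, "w") as fh:
        json.dump(
            {
                "config_hash": config.snapshot_hash,
                "comparisons": comparisons.to_dict(orient="records"),
                "anova": anova,
                "dose_response": dose.to_dict(orient="records"),
            },
            fh,
            indent=2,
        )
    return out
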