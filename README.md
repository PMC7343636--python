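# sccpipe

Imaging-biomarker pipeline for quantifying chemotherapeutic effect in 3D
bioprinted skin models of cutaneous squamous cell carcinoma (cSCC).

## The scientific problem

Preclinical drug testing on 3D bioprinted skin constructs needs a
**non-destructive, longitudinal readout** of how many tumor cells a treatment
kills — and how much collateral damage it does to healthy tissue. The assay
implemented here images each construct twice (before and after treatment)
with a bimodal confocal microscope:

* a **532 nm channel** excites tdTomato-labeled cSCC (A431) tumor cells,
  which grow as spheroids with a proliferating rim around a necrotic core;
* a **488 nm channel** excites ZsGreen in a ~1% spike-in of labeled
  keratinocytes, a sparse sentinel population for off-target toxicity;
* each fluorescence stack comes with a simultaneously acquired
  **reflectance (RCM) stack** of the same field, used as a label-free
  registration substrate, since laser lines are acquired sequentially and
  the sample can shift between them.

From each 3D stack the pipeline computes two imaging biomarkers —
**cell count** (one 26-connected component = one cell) and **total
fluorescence** of the segmented objects — and expresses the treatment effect
as the post-treatment value in **percent of the pre-treatment value**, per
tumor spheroid ROI (532 nm) or per whole construct (488 nm). Group-level
statistics (pooled t-test, Hedges' g, unbalanced two-way ANOVA with a
cell-type x treatment interaction, dose-response summary) quantify the
specificity of the drug effect.

The processing chain:

1. **Normalization** — intensities rescaled from each stack's recorded laser
   power and detector gain to a common reference.
2. **Registration** — an in-plane rigid transform (rotation + translation)
   estimated between the two channels' reflectance z-sum projections and
   applied slice-wise to the 532 nm fluorescence stack.
3. **Segmentation** — 3D Gaussian smoothing (kernel size 8 voxels),
   global Otsu binarization (256-bin histogram), 26-connectivity connected
   components, removal of objects of 4 voxels or fewer.
4. **Biomarkers** — object counts and total (pre-smoothing) fluorescence per
   analysis unit; percent-of-pre treatment effects; bleed-through QC.
5. **Statistics** — control-vs-treated comparisons with Hedges' g
   (exact small-sample correction), Type III two-way ANOVA, dose response.

Because the original raw images are not public, the package ships a
**synthetic phantom generator** that renders the whole scene (spheroid
shells of resolvable cells, keratinocyte spike-in, stratified reflectance
texture, per-channel gain/power factors, channel misregistration,
bleed-through, Poisson-Gaussian noise) with full ground truth, so every
stage is testable against known answers.

## Worked example

Generate one treated phantom construct (50% tumor kill, 11% keratinocyte
kill, full sensor-noise model), segment the tumor channel at both
timepoints, and compute per-spheroid treatment effects:

```python
from sccpipe import PhantomConfig, generate_phantom, segment, Channel, Timepoint
from sccpipe.biomarkers import measure, treatment_effects
from sccpipe.io import SampleRecord, Group

config = PhantomConfig(kill_fraction_tumor=0.5, kill_fraction_keratinocyte=0.11,
                       rng_seed=42)
pre, post, truth = generate_phantom(config)

sample = SampleRecord(
    "demo", Group.treated_1x,
    {(tp, ch): acqs[ch]
     for tp, acqs in ((Timepoint.pre, pre), (Timepoint.post, post))
     for ch in Channel},
    tumor_rois=truth.tumor_rois(),
)

for tp, acqs in ((Timepoint.pre, pre), (Timepoint.post, post)):
    seg = segment(acqs[Channel.RFP_532].fluorescence)
    print(f"{tp.value:4s}: {seg.n_objects} tumor cells segmented "
          f"(ground truth {len(truth.tumor_centers(tp))})")

pre_m = {m.roi_id: m for m in measure(
    sample, segment(pre[Channel.RFP_532].fluorescence), Channel.RFP_532, Timepoint.pre)}
post_m = {m.roi_id: m for m in measure(
    sample, segment(post[Channel.RFP_532].fluorescence), Channel.RFP_532, Timepoint.post)}
for roi_id in sorted(r.roi_id for r in sample.tumor_rois):
    for e in treatment_effects(pre_m[roi_id], post_m[roi_id]):
        if e.metric.value == "n_objects":
            print(f"{roi_id}: {pre_m[roi_id].n_objects} -> {post_m[roi_id].n_objects} "
                  f"cells ({e.percent_of_pre:.0f}% of pre-treatment)")
```

Output:

```
pre : 60 tumor cells segmented (ground truth 60)
post: 30 tumor cells segmented (ground truth 30)
tumor00: 12 -> 8 cells (67% of pre-treatment)
tumor01: 12 -> 6 cells (50% of pre-treatment)
tumor02: 12 -> 7 cells (58% of pre-treatment)
tumor03: 12 -> 1 cells (8% of pre-treatment)
tumor04: 12 -> 8 cells (67% of pre-treatment)
```

The segmentation recovers the generating truth exactly; the per-spheroid
percentages scatter around the configured 50% kill because each cell
survives independently.

## Command-line interface

Every stage reads and writes open formats (TIFF / CSV / JSON / YAML):

```bash
# write a phantom study (images + ROIs + ground truth + manifest)
sccpipe simulate --outdir data --seed 0 --n-control 15 --n-1x 18 --n-2x 20

# whole chain in memory
sccpipe run-all --manifest data/manifest.csv --outdir results

# or stage by stage, with file handoffs
sccpipe preprocess --manifest data/manifest.csv --outdir work
sccpipe segment    --manifest work/preprocessed/manifest.csv --outdir work
sccpipe quantify   --manifest work/preprocessed/manifest.csv --outdir work \
                   --seg-index work/segmented/segmentation_index.csv
sccpipe stats      --manifest work/preprocessed/manifest.csv --outdir work \
                   --effects work/effects.csv
```

`run-all` writes `biomarkers.csv`, `effects.csv`, `qc.csv`,
`group_comparisons.csv`, `dose_response.csv`, `stats.json` and a
`config_snapshot.yaml`; every table carries the config snapshot hash.

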