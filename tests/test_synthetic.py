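"""Phantom generator: determinism, ground-truth bookkeeping, kill arithmetic,
placement constraints, rendering invariants and dataset writing."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import small_config
from sccpipe.exceptions import ManifestError, PlacementError, ValidationError
from sccpipe.io import Channel, Group, Timepoint, load_manifest
from sccpipe.preprocess import RigidTransform2D
from sccpipe.segmentation import segment
from sccpipe.synthetic import (
    GROUP_KILL_FRACTIONS,
    NoiseModel,
    PhantomConfig,
    generate_phantom,
    simulate_dataset,
    simulate_effect_table,
    write_manifest,
    write_phantom_sample,
)

ALL_STACKS = [
    (tp, ch, mod)
    for tp in Timepoint
    for ch in Channel
    for mod in ("reflectance", "fluorescence")
]


def _stacks(pre, post):
    for tp, acqs in ((Timepoint.pre, pre), (Timepoint.post, post)):
        for ch, acq in acqs.items():
            yield (tp, ch, "reflectance"), acq.reflectance.voxels
            yield (tp, ch, "fluorescence"), acq.fluorescence.voxels


class TestDeterminism:
    def test_same_seed_is_bit_identical(self):
        cfg = small_config(rng_seed=5, kill_fraction_tumor=0.3)
        a = generate_phantom(cfg)
        b = generate_phantom(cfg)
        for (ka, va), (kb, vb) in zip(_stacks(a[0], a[1]), _stacks(b[0], b[1])):
            assert ka == kb
            assert np.array_equal(va, vb), f"stack {ka} differs between runs"
        assert np.array_equal(
            a[2].tumor_centers(Timepoint.pre), b[2].tumor_centers(Timepoint.pre)
        )

    def test_different_seeds_differ(self):
        a = generate_phantom(small_config(rng_seed=5))
        b = generate_phantom(small_config(rng_seed=6))
        assert not np.array_equal(
            a[0][Channel.RFP_532].fluorescence.voxels,
            b[0][Channel.RFP_532].fluorescence.voxels,
        )


class TestGroundTruth:
    def test_population_sizes_match_config(self, clean_phantom):
        cfg, pre, post, truth = clean_phantom
        assert len(truth.tumor_centers(Timepoint.pre)) == cfg.n_spheroids * cfg.cells_per_spheroid
        assert len(truth.keratinocyte_centers_pre) == cfg.n_keratinocytes
        n_labeled = int(round(cfg.gfp_labeled_fraction * cfg.n_keratinocytes))
        assert truth.keratinocyte_labeled_pre.sum() == n_labeled

    def test_all_centers_inside_volume(self, clean_phantom):
        cfg, _, _, truth = clean_phantom
        for centers in (
            truth.tumor_centers(Timepoint.pre),
            truth.keratinocyte_centers_pre,
        ):
            assert np.all(centers >= 0)
            assert np.all(centers < np.array(cfg.volume_shape))

    def test_post_centers_are_subset_of_pre(self, clean_phantom):
        _, _, _, truth = clean_phantom
        pre = {tuple(c) for c in truth.tumor_centers(Timepoint.pre)}
        post = {tuple(c) for c in truth.tumor_centers(Timepoint.post)}
        assert post <= pre

    def test_tumor_cells_respect_separation_metric(self, clean_phantom):
        cfg, _, _, truth = clean_phantom
        centers = truth.tumor_centers(Timepoint.pre).astype(float) * np.array(
            cfg.voxel_size_um
        )
        for i in range(len(centers)):
            d = centers[i + 1:] - centers[i]
            if len(d) == 0:
                continue
            n = (d[:, 0] / cfg.min_axial_separation_um) ** 2 + (
                d[:, 1] ** 2 + d[:, 2] ** 2
            ) / cfg.min_lateral_separation_um**2
            assert np.all(n >= 1.0)

    def test_tumor_cells_lie_in_shell(self, clean_phantom):
        cfg, _, _, truth = clean_phantom
        vox_um = np.array(cfg.voxel_size_um)
        core = cfg.necrotic_core_fraction * cfg.spheroid_radius_um
        for cells, center in zip(truth.tumor_cell_centers_pre, truth.spheroid_centers_vox):
            r = np.linalg.norm((cells - center) * vox_um, axis=1)
            # rounding to integer voxels moves a point by at most half a voxel diagonal
            slack = float(np.linalg.norm(vox_um / 2.0))
            assert np.all(r >= core - slack)
            assert np.all(r <= cfg.spheroid_radius_um + slack)

    def test_each_center_is_a_local_max_of_the_clean_scene(self, clean_phantom):
        cfg, pre, _, truth = clean_phantom
        vox = pre[Channel.RFP_532].fluorescence.voxels
        for cz, cy, cx in truth.tumor_centers(Timepoint.pre):
            val = vox[cz, cy, cx]
            nb = vox[
                max(0, cz - 1): cz + 2, max(0, cy - 1): cy + 2, max(0, cx - 1): cx + 2
            ]
            assert val == nb.max()
            assert val >= 0.9 * cfg.cell_peak_intensity

    def test_disjoint_rois_cover_their_cells(self, clean_phantom):
        _, _, _, truth = clean_phantom
        rois = truth.tumor_rois()
        for i, a in enumerate(rois):
            for b in rois[i + 1:]:
                assert not a.overlaps(b)
        for cells, roi in zip(truth.tumor_cell_centers_pre, rois):
            for c in cells:
                assert roi.contains(c)


class TestKillArithmetic:
    @pytest.mark.parametrize("kill,expected_kept", [(0.0, 6), (0.25, 4), (0.5, 3), (1.0, 0)])
    def test_tumor_kill_keeps_rounded_fraction(self, kill, expected_kept):
        # 2 spheroids x 3 cells = 6 tumor cells; keep = round((1-k) * 6)
        cfg = small_config(kill_fraction_tumor=kill, noise=None, rng_seed=21)
        _, _, truth = generate_phantom(cfg)
        assert len(truth.tumor_centers(Timepoint.post)) == expected_kept

    def test_keratinocyte_strata_killed_separately(self):
        # 400 keratinocytes, 4 labeled; kill 0.25 keeps exactly 3 labeled and
        # 297 unlabeled (the strata are subsampled independently)
        cfg = small_config(kill_fraction_keratinocyte=0.25, noise=None, rng_seed=22)
        _, _, truth = generate_phantom(cfg)
        assert truth.keratinocyte_labeled_post.sum() == 3
        assert (~truth.keratinocyte_labeled_post).sum() == 297

    def test_kill_zero_with_no_noise_gives_identical_stacks(self):
        cfg = small_config(noise=None, rng_seed=23)
        pre, post, _ = generate_phantom(cfg)
        for ch in Channel:
            assert np.array_equal(
                pre[ch].fluorescence.voxels, post[ch].fluorescence.voxels
            )


class TestAcquisitionEffects:
    def test_scale_factors_multiply_intensities(self):
        base = small_config(noise=None, rng_seed=31)
        scaled = small_config(
            noise=None, rng_seed=31,
            laser_power_factors={(Channel.RFP_532, Timepoint.pre): 2.0},
            detector_gain_factors={(Channel.RFP_532, Timepoint.pre): 1.5},
        )
        a = generate_phantom(base)[0][Channel.RFP_532].fluorescence
        b = generate_phantom(scaled)[0][Channel.RFP_532].fluorescence
        assert np.allclose(b.voxels, 3.0 * a.voxels)
        assert b.metadata.laser_power == 2.0 and b.metadata.detector_gain == 1.5

    def test_misregistration_moves_only_the_532_channel(self):
        t = RigidTransform2D(0.0, 0.0, 5.0)
        base = small_config(noise=None, rng_seed=32)
        shifted = small_config(noise=None, rng_seed=32, misregistration=t)
        a0 = generate_phantom(base)[0]
        b0 = generate_phantom(shifted)[0]
        assert np.array_equal(
            a0[Channel.GFP_488].fluorescence.voxels,
            b0[Channel.GFP_488].fluorescence.voxels,
        )
        moved = b0[Channel.RFP_532].fluorescence.voxels
        ref = a0[Channel.RFP_532].fluorescence.voxels
        # a pure +5 x-translation: moved[z, y, x] == ref[z, y, x-5] in the interior
        assert np.allclose(moved[:, :, 8:], ref[:, :, 3:-5], atol=1e-6)

    def test_bleed_through_mixes_scenes(self):
        c = 0.4
        base = small_config(noise=None, rng_seed=33)
        mixed = small_config(noise=None, rng_seed=33, bleed_through_coefficient=c)
        a0 = generate_phantom(base)[0]
        b0 = generate_phantom(mixed)[0]
        gfp, rfp = (a0[ch].fluorescence.voxels for ch in (Channel.GFP_488, Channel.RFP_532))
        assert np.allclose(b0[Channel.GFP_488].fluorescence.voxels, gfp + c * rfp)
        assert np.allclose(b0[Channel.RFP_532].fluorescence.voxels, rfp + c * gfp)

    def test_noise_model_changes_voxels_but_not_truth(self):
        clean = generate_phantom(small_config(noise=None, rng_seed=34))
        noisy = generate_phantom(
            small_config(noise=NoiseModel(photon_scale=1.0, read_noise_sd=2.0), rng_seed=34)
        )
        assert not np.array_equal(
            clean[0][Channel.RFP_532].fluorescence.voxels,
            noisy[0][Channel.RFP_532].fluorescence.voxels,
        )
        assert np.array_equal(
            clean[2].tumor_centers(Timepoint.pre), noisy[2].tumor_centers(Timepoint.pre)
        )

    def test_reflectance_is_stratified(self, clean_phantom):
        cfg, pre, _, _ = clean_phantom
        refl = pre[Channel.GFP_488].reflectance.voxels
        superficial = refl[0].mean()
        dermis = refl[-1].mean()
        assert superficial > dermis  # bright top band over dimmer fibrous dermis
        assert refl.min() >= 0


class TestSegmentabilityContract:
    def test_pinned_segmentation_recovers_true_counts(self, noisy_phantom):
        cfg, pre, post, truth = noisy_phantom
        for tp, acqs in ((Timepoint.pre, pre), (Timepoint.post, post)):
            n_rfp = segment(acqs[Channel.RFP_532].fluorescence).n_objects
            assert n_rfp == len(truth.tumor_centers(tp))
            n_gfp = segment(acqs[Channel.GFP_488].fluorescence).n_objects
            assert n_gfp == len(truth.labeled_keratinocyte_centers(tp))


class TestPlacementErrors:
    def test_too_many_spheroids_raises(self):
        with pytest.raises(PlacementError, match="spheroids"):
            generate_phantom(small_config(n_spheroids=8, rng_seed=1))

    def test_spheroid_too_deep_raises(self):
        with pytest.raises(PlacementError, match="axial extent"):
            generate_phantom(small_config(spheroid_radius_um=40.0, rng_seed=1))

    def test_unresolvable_density_raises(self):
        with pytest.raises(PlacementError, match="resolvable"):
            generate_phantom(small_config(cells_per_spheroid=200, rng_seed=1))

    @pytest.mark.parametrize("kwargs", [
        {"kill_fraction_tumor": 1.5},
        {"gfp_labeled_fraction": -0.1},
        {"volume_shape": (8, 96, 96)},
        {"cell_radius_um": 0.0},
    ])
    def test_config_validation(self, kwargs):
        with pytest.raises(ValidationError):
            small_config(**kwargs)


class TestDatasetWriting:
    def test_write_phantom_sample_creates_all_files(self, tmp_path):
        cfg = small_config(rng_seed=41)
        rows, _ = write_phantom_sample(tmp_path, "S000", Group.control, cfg)
        assert len(rows) == 4  # (2 timepoints) x (2 channels)
        for row in rows:
            assert (tmp_path / row["reflectance_path"]).exists()
            assert (tmp_path / row["fluorescence_path"]).exists()
        assert (tmp_path / "S000_rois.json").exists()
        assert (tmp_path / "S000_truth.json").exists()

    def test_simulate_dataset_round_trips_through_load_manifest(self, tmp_path):
        manifest = simulate_dataset(
            tmp_path, n_control=2, n_treated_1x=1, n_treated_2x=1,
            base_config=small_config(), seed=7,
        )
        records = load_manifest(manifest)
        assert len(records) == 4
        groups = sorted(r.group.value for r in records)
        assert groups == ["control", "control", "treated_1x", "treated_2x"]
        for rec in records:
            assert len(rec.tumor_rois) == 2
            meta = rec.get(Timepoint.pre, Channel.RFP_532).fluorescence.metadata
            assert meta.laser_power > 0

    def test_group_kill_fractions_increase_with_dose(self):
        kt = [GROUP_KILL_FRACTIONS[g][0] for g in (Group.control, Group.treated_1x, Group.treated_2x)]
        assert kt == sorted(kt) and kt[0] < kt[1] < kt[2]


class TestEffectTable:
    def test_simulate_effect_table_shape_and_means(self):
        rng = np.random.default_rng(0)
        table = simulate_effect_table(rng, n_per_arm=200, kill_tumor_treated=0.5)
        assert len(table) == 4 * 200
        assert set(table["cell_type"]) == {"cSCC", "keratinocyte"}
        treated_tumor = table.query("cell_type == 'cSCC' and treatment == 'treated'")["value"]
        control_tumor = table.query("cell_type == 'cSCC' and treatment == 'untreated'")["value"]
        assert abs(treated_tumor.mean() - 50.0) < 2.0
        assert abs(control_tumor.mean() - 100.0) < 2.0
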