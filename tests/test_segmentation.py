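"""Segmentation chain: smoothing, Otsu (vs brute-force oracle), connected
components (vs flood-fill oracle), size filtering, and phantom recovery."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu

from conftest import make_stack, small_config
from oracles import flood_fill_components, otsu_bruteforce
from sccpipe.exceptions import DegenerateInputError, ValidationError
from sccpipe.io import Channel, Timepoint
from sccpipe.segmentation import (
    SegmentationParams,
    gaussian_smooth,
    label_components,
    otsu_threshold,
    remove_small_objects,
    segment,
)
from sccpipe.synthetic import generate_phantom


class TestGaussianSmooth:
    def test_constant_volume_is_invariant(self):
        stack = make_stack(np.full((12, 12, 12), 7.0))
        out = gaussian_smooth(stack, SegmentationParams())
        assert np.allclose(out.voxels, 7.0)

    def test_total_intensity_conserved_for_interior_impulse(self):
        vox = np.zeros((24, 24, 24))
        vox[12, 12, 12] = 1000.0
        out = gaussian_smooth(make_stack(vox), SegmentationParams())
        # reflect boundary + interior impulse: mass is conserved up to the
        # truncation of the Gaussian window at kernel_size/2 = 2 sigma
        assert np.isclose(out.voxels.sum(), 1000.0, rtol=0.02)
        peak = np.unravel_index(np.argmax(out.voxels), out.voxels.shape)
        assert peak == (12, 12, 12)

    def test_default_sigma_is_quarter_kernel(self):
        assert SegmentationParams().sigma == 2.0
        assert SegmentationParams(smoothing_kernel_size=12).sigma == 3.0
        assert SegmentationParams(smoothing_sigma=1.5).sigma == 1.5

    def test_kernel_larger_than_volume_rejected(self):
        with pytest.raises(ValidationError, match="kernel"):
            gaussian_smooth(make_stack(np.zeros((4, 32, 32))), SegmentationParams())

    def test_per_slice_mode_does_not_mix_z(self):
        vox = np.zeros((5, 16, 16))
        vox[2] = 10.0
        params = SegmentationParams(per_slice_smoothing=True)
        out = gaussian_smooth(make_stack(vox), params)
        assert np.allclose(out.voxels[0], 0.0) and np.allclose(out.voxels[2], 10.0)

    def test_smoothing_reduces_variance(self):
        rng = np.random.default_rng(0)
        vox = rng.uniform(0, 100, size=(16, 16, 16))
        out = gaussian_smooth(make_stack(vox), SegmentationParams())
        assert out.voxels.var() < vox.var()


class TestOtsu:
    def test_bimodal_separates_modes(self):
        rng = np.random.default_rng(1)
        vox = np.where(rng.uniform(size=(10, 20, 20)) < 0.3, 200.0, 10.0)
        vox += rng.normal(0, 2, size=vox.shape)
        vox = np.clip(vox, 0, None)
        thr = otsu_threshold(make_stack(vox))
        # the cut must fall between the modes (background ~10, foreground ~200)
        assert 16 < thr < 194
        fg = vox > thr
        assert np.isclose(fg.mean(), 0.3, atol=0.02)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(make_stack(np.full((4, 4, 4), 3.0)))

    def test_matches_bruteforce_on_integer_volumes(self):
        # integers in [0, 255] with both extremes present map each value to
        # its own bin, so the two implementations must agree exactly
        rng = np.random.default_rng(2)
        for _ in range(20):
            vox = rng.integers(0, 256, size=(6, 8, 8)).astype(float)
            vox.ravel()[0], vox.ravel()[1] = 0.0, 255.0
            assert otsu_threshold(vox) == otsu_bruteforce(vox)

    def test_close_to_skimage_on_continuous_data(self):
        rng = np.random.default_rng(3)
        vox = np.concatenate([rng.normal(20, 5, 4000), rng.normal(120, 15, 2000)])
        vox = np.clip(vox, 0, None).reshape(10, 20, 30)
        thr = otsu_threshold(make_stack(vox))
        ref = threshold_otsu(vox, nbins=256)
        bin_width = (vox.max() - vox.min()) / 256
        # conventions differ by at most one bin (we return the bin's upper edge)
        assert abs(thr - ref) <= bin_width + 1e-9

    def test_foreground_is_strictly_greater_than_threshold(self):
        vox = np.zeros((4, 8, 8))
        vox[0, 0, :4] = 100.0
        thr = otsu_threshold(make_stack(vox))
        assert ((vox > thr).sum()) == 4


class TestConnectedComponents:
    def test_corner_touching_merges_at_26_but_not_6(self):
        binary = np.zeros((4, 4, 4), dtype=bool)
        binary[0, 0, 0] = True
        binary[1, 1, 1] = True  # corner neighbor
        assert label_components(binary, connectivity=26).n_objects == 1
        assert label_components(binary, connectivity=18).n_objects == 2
        assert label_components(binary, connectivity=6).n_objects == 2

    def test_edge_touching_merges_at_18_but_not_6(self):
        binary = np.zeros((4, 4, 4), dtype=bool)
        binary[0, 0, 0] = True
        binary[0, 1, 1] = True  # edge neighbor
        assert label_components(binary, connectivity=18).n_objects == 1
        assert label_components(binary, connectivity=6).n_objects == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(4)
        for _ in range(10):
            binary = rng.uniform(size=(6, 6, 6)) < 0.35
            got = label_components(binary, connectivity=connectivity).label_volume
            want = flood_fill_components(binary, connectivity=connectivity)
            assert np.array_equal(got, want)  # including scan-order numbering

    def test_labels_are_scan_ordered_and_consecutive(self):
        binary = np.zeros((2, 4, 4), dtype=bool)
        binary[1, 3, 3] = True  # created last in scan order
        binary[0, 0, 0] = True
        res = label_components(binary, connectivity=6)
        assert res.label_volume[0, 0, 0] == 1
        assert res.label_volume[1, 3, 3] == 2

    def test_object_summaries(self):
        binary = np.zeros((3, 4, 4), dtype=bool)
        binary[0, 0, 0:3] = True
        intensity = np.zeros(binary.shape)
        intensity[0, 0, 0:3] = [1.0, 2.0, 3.0]
        res = label_components(binary, connectivity=26, intensity=intensity)
        (obj,) = res.objects
        assert obj.voxel_count == 3
        assert obj.centroid == (0.0, 0.0, 1.0)
        assert obj.total_fluorescence == 6.0

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValidationError):
            label_components(np.zeros((2, 2, 2), dtype=bool), connectivity=4)


class TestRemoveSmallObjects:
    def test_size_floor_keeps_five_and_larger(self):
        binary = np.zeros((1, 6, 30), dtype=bool)
        sizes = [3, 4, 5, 6]
        x = 0
        for s in sizes:
            binary[0, 0, x: x + s] = True
            x += s + 3
        res = label_components(binary, connectivity=26)
        kept = remove_small_objects(res, min_object_voxels=5)
        assert sorted(o.voxel_count for o in kept.objects) == [5, 6]
        assert sorted(o.label for o in kept.objects) == [1, 2]  # relabeled
        assert set(np.unique(kept.label_volume)) == {0, 1, 2}

    def test_floor_of_one_keeps_everything(self):
        rng = np.random.default_rng(5)
        binary = rng.uniform(size=(5, 5, 5)) < 0.3
        res = label_components(binary)
        assert remove_small_objects(res, 1).n_objects == res.n_objects

    def test_empty_result(self):
        res = label_components(np.zeros((2, 2, 2), dtype=bool))
        assert remove_small_objects(res, 5).n_objects == 0


class TestSegmentChain:
    def test_phantom_counts_recovered_exactly(self, noisy_phantom):
        cfg, pre, post, truth = noisy_phantom
        seg = segment(pre[Channel.RFP_532].fluorescence)
        assert seg.n_objects == len(truth.tumor_centers(Timepoint.pre))
        # each truth center falls inside exactly one labeled object
        hit_labels = {
            int(seg.label_volume[tuple(c)]) for c in truth.tumor_centers(Timepoint.pre)
        }
        assert 0 not in hit_labels and len(hit_labels) == seg.n_objects

    def test_total_fluorescence_uses_presmoothing_intensities(self, clean_phantom):
        cfg, pre, _, _ = clean_phantom
        stack = pre[Channel.RFP_532].fluorescence
        seg = segment(stack)
        for obj in seg.objects:
            mask = seg.label_volume == obj.label
            assert np.isclose(obj.total_fluorescence, stack.voxels[mask].sum())

    def test_monotone_in_size_floor(self, noisy_phantom):
        _, pre, _, _ = noisy_phantom
        stack = pre[Channel.RFP_532].fluorescence
        counts = [
            segment(stack, SegmentationParams(min_object_voxels=m)).n_objects
            for m in (1, 5, 50, 500)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_connectivity_26_never_more_objects_than_6(self, noisy_phantom):
        _, pre, _, _ = noisy_phantom
        stack = pre[Channel.RFP_532].fluorescence
        n26 = segment(stack, SegmentationParams(connectivity=26)).n_objects
        n6 = segment(stack, SegmentationParams(connectivity=6)).n_objects
        assert n26 <= n6

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_pure_noise_yields_few_objects(self, seed):
        # smoothing + Otsu + the 5-voxel floor suppress speckle: unstructured
        # noise must not generate a cell-like population
        rng = np.random.default_rng(seed)
        vox = np.clip(rng.normal(10, 2, size=(12, 48, 48)), 0, None)
        n = segment(make_stack(vox)).n_objects
        assert n <= 20

    def test_intensity_scaling_preserves_labels(self, clean_phantom):
        _, pre, _, _ = clean_phantom
        stack = pre[Channel.RFP_532].fluorescence
        scaled = stack.with_voxels(stack.voxels * 3.7)
        a = segment(stack)
        b = segment(scaled)
        assert np.array_equal(a.label_volume, b.label_volume)
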