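"""Z-scan normalization, whole-cell fluorescence and the polarity index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_stack
from isquant import (
    BeadParams,
    CellParams,
    generate_bead_conjugate,
    generate_coverslip_cell,
    polarity_index,
    segment_cell,
    whole_cell_fluorescence,
    zscan_profile,
)
from isquant.segmentation import CellSegmentation


def _full_seg(shape):
    return CellSegmentation(cell_mask=np.ones(shape, bool))


class TestZScan:
    def test_uniform_intensity_gives_equal_percentages(self):
        stack = make_stack(np.ones((20, 10, 10)))
        prof = zscan_profile(stack, _full_seg((20, 10, 10)), "er")
        np.testing.assert_allclose(prof.pct_per_slice, 5.0)
        assert prof.is_fraction_pct == pytest.approx(10.0)
        assert prof.n_synapse_slices == 2

    def test_all_signal_in_synapse_slab(self):
        arr = np.zeros((20, 10, 10))
        arr[:2] = 3.0
        prof = zscan_profile(make_stack(arr), _full_seg(arr.shape), "er")
        assert prof.is_fraction_pct == pytest.approx(100.0)

    def test_zero_total_fluorescence_raises(self):
        stack = make_stack(np.zeros((20, 10, 10)))
        with pytest.raises(ValueError, match="zero whole-cell"):
            zscan_profile(stack, _full_seg((20, 10, 10)), "er")

    def test_percentages_sum_to_100_on_random_cells(self):
        for seed in range(5):
            stack, _ = generate_coverslip_cell(seed=seed)
            seg = segment_cell(stack, "actin")
            prof = zscan_profile(stack, seg, "er")
            assert prof.pct_per_slice.sum() == pytest.approx(100.0, abs=1e-6)

    def test_noise_free_recovery_of_true_fraction(self):
        params = CellParams(
            bottom_fraction=0.6, poisson_noise=False, gaussian_sigma=0.0
        )
        stack, truth = generate_coverslip_cell(params, seed=3)
        seg = segment_cell(stack, "actin")
        prof = zscan_profile(stack, seg, "er")
        assert prof.is_fraction_pct == pytest.approx(
            100 * truth.true_bottom_fraction, abs=1.0
        )

    @given(gain=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, gain):
        rng = np.random.default_rng(0)
        arr = rng.random((20, 8, 8)) + 0.1
        base = zscan_profile(make_stack(arr), _full_seg(arr.shape), "er")
        scaled = zscan_profile(make_stack(arr * gain), _full_seg(arr.shape), "er")
        np.testing.assert_allclose(scaled.pct_per_slice, base.pct_per_slice, rtol=1e-9)
        assert scaled.is_fraction_pct == pytest.approx(base.is_fraction_pct, rel=1e-9)

    def test_whole_frame_mode_includes_off_cell_signal(self):
        arr = np.ones((20, 10, 10))
        masked = zscan_profile(make_stack(arr), _full_seg(arr.shape), "er")
        unmasked = zscan_profile(make_stack(arr), None, "er")
        np.testing.assert_allclose(masked.pct_per_slice, unmasked.pct_per_slice)


class TestWholeCellFluorescence:
    def test_unit_intensity_counts_voxels(self):
        arr = np.zeros((10, 10, 10))
        arr[:, :10, :10] = 1.0
        seg = CellSegmentation(cell_mask=arr > 0)
        assert whole_cell_fluorescence(make_stack(arr), seg, "er") == 1000.0

    def test_equals_sum_of_zscan_raw_exactly(self, default_cell, default_seg):
        stack, _ = default_cell
        prof = zscan_profile(stack, default_seg, "er")
        wcf = whole_cell_fluorescence(stack, default_seg, "er")
        assert wcf == prof.raw_per_slice.sum()

    def test_linearity(self, default_cell, default_seg):
        stack, _ = default_cell
        doubled = make_stack(
            [stack.voxels[i] * 2 for i in range(3)],
            voxel_size=stack.voxel_size,
            roles=stack.channel_roles,
        )
        assert whole_cell_fluorescence(doubled, default_seg, "er") == pytest.approx(
            2 * whole_cell_fluorescence(stack, default_seg, "er")
        )


class TestPolarityIndex:
    @staticmethod
    def _sphere(shape=(30, 30, 30), radius=12):
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        c = (np.array(shape) - 1) / 2
        return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius**2

    def test_symmetric_distribution_gives_zero(self):
        mask = self._sphere()
        arr = mask.astype(float)
        stack = make_stack(arr, voxel_size=(0.1, 0.1, 0.1))
        seg = CellSegmentation(cell_mask=mask)
        pi = polarity_index(stack, seg, "er", bead_position=(14, 28, 14))
        assert abs(pi) <= 0.02

    def test_mass_at_bead_facing_boundary_near_one(self):
        mask = self._sphere()
        arr = np.zeros(mask.shape)
        arr[14, 26, 14] = 100.0  # at the +y boundary, toward the bead
        stack = make_stack(arr, voxel_size=(0.1, 0.1, 0.1))
        seg = CellSegmentation(cell_mask=mask)
        pi = polarity_index(stack, seg, "er", bead_position=(14, 29, 14))
        assert pi >= 0.9

    def test_antisymmetry_under_reflection(self):
        mask = self._sphere()
        rng = np.random.default_rng(5)
        arr = np.where(mask, rng.random(mask.shape), 0.0)
        mirrored = arr[:, ::-1, :]  # reflect through the plane normal to the axis
        stack = make_stack(arr, voxel_size=(0.1, 0.1, 0.1))
        stack_m = make_stack(mirrored, voxel_size=(0.1, 0.1, 0.1))
        seg = CellSegmentation(cell_mask=mask)
        bead = (14.5, 29.0, 14.5)  # exactly on the reflection axis
        pi = polarity_index(stack, seg, "er", bead_position=bead)
        pi_m = polarity_index(stack_m, seg, "er", bead_position=bead)
        assert pi_m == pytest.approx(-pi, abs=1e-6)

    def test_scale_invariance(self):
        mask = self._sphere()
        rng = np.random.default_rng(6)
        arr = np.where(mask, rng.random(mask.shape), 0.0)
        seg = CellSegmentation(cell_mask=mask)
        bead = (14, 29, 14)
        a = polarity_index(make_stack(arr, (0.1, 0.1, 0.1)), seg, "er", bead)
        b = polarity_index(make_stack(arr * 7.5, (0.1, 0.1, 0.1)), seg, "er", bead)
        assert a == pytest.approx(b, rel=1e-9)

    def test_recovers_generator_truth(self):
        stack, truth = generate_bead_conjugate(polarization=0.6, seed=4)
        seg = segment_cell(stack, "actin")
        pi = polarity_index(stack, seg, "er", bead_position=truth.bead_position)
        assert pi == pytest.approx(truth.true_polarization, abs=0.05)

    def test_bead_at_centroid_raises(self):
        mask = self._sphere()
        stack = make_stack(mask.astype(float), (0.1, 0.1, 0.1))
        seg = CellSegmentation(cell_mask=mask)
        with pytest.raises(ValueError, match="axis undefined"):
            polarity_index(stack, seg, "er", bead_position=(14.5, 14.5, 14.5))

    def test_zero_fluorescence_raises(self):
        mask = self._sphere()
        stack = make_stack(np.zeros(mask.shape), (0.1, 0.1, 0.1))
        seg = CellSegmentation(cell_mask=mask)
        with pytest.raises(ValueError, match="zero fluorescence"):
            polarity_index(stack, seg, "er", bead_position=(14, 29, 14))
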