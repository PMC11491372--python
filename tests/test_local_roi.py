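"""Masked Pearson colocalization, MTOC-circle density and line scans."""

import numpy as np
import pytest

from conftest import make_stack
from isquant import (
    generate_coverslip_cell,
    line_scan,
    mtoc_density,
    pearson_synapse,
    segment_cell,
)
from isquant.io_formats import synapse_slice_count
from isquant.local_roi import MTOC_CIRCLE_DIAMETER_UM
from isquant.segmentation import CellSegmentation


def _two_channel(a, b, voxel=(0.14, 0.2, 0.2)):
    return make_stack([a, b], voxel_size=voxel, roles={"er": 0, "tubulin": 1})


def _full_seg(shape, mtoc=None):
    return CellSegmentation(cell_mask=np.ones(shape, bool), mtoc_position=mtoc)


def direct_pearson(a, b):
    """Textbook formula, the independent oracle."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac * bc).sum() / np.sqrt((ac * ac).sum() * (bc * bc).sum()))


class TestPearsonSynapse:
    def test_affine_copy_gives_exactly_one(self):
        rng = np.random.default_rng(0)
        a = rng.random((20, 12, 12))
        res = pearson_synapse(_two_channel(a, 3 * a + 7), _full_seg(a.shape), "er", "tubulin")
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_copy_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.random((20, 12, 12))
        b = -a + a.max()
        res = pearson_synapse(_two_channel(a, b), _full_seg(a.shape), "er", "tubulin")
        assert res.pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_raises(self):
        a = np.random.default_rng(2).random((20, 12, 12))
        b = np.full_like(a, 4.0)
        with pytest.raises(ValueError, match="variance"):
            pearson_synapse(_two_channel(a, b), _full_seg(a.shape), "er", "tubulin")

    def test_matches_direct_formula_on_synthetic_cells(self):
        """Implementation route (scipy) vs the direct-formula oracle on the
        extracted ROI voxel vectors."""
        for seed in range(5):
            stack, _ = generate_coverslip_cell(seed=seed)
            seg = segment_cell(stack, "actin")
            res = pearson_synapse(stack, seg, "er", "tubulin")
            n_syn = synapse_slice_count(stack.n_z)
            roi = np.zeros_like(seg.cell_mask)
            roi[:n_syn] = seg.cell_mask[:n_syn]
            oracle = direct_pearson(
                stack.channel("er")[roi], stack.channel("tubulin")[roi]
            )
            assert res.pearson_r == pytest.approx(oracle, abs=1e-10)
            assert res.n_voxels == int(roi.sum())

    def test_roi_restricted_to_synapse_slab(self):
        rng = np.random.default_rng(3)
        a = rng.random((20, 10, 10))
        b = rng.random((20, 10, 10))
        b[:2] = 2 * a[:2] + 1  # perfect coupling only inside the slab
        res = pearson_synapse(_two_channel(a, b), _full_seg(a.shape), "er", "tubulin")
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)


class TestMtocDensity:
    def test_uniform_intensity_returns_constant_exactly(self):
        arr = np.full((10, 30, 30), 42.0)
        stack = make_stack(arr)
        seg = _full_seg(arr.shape, mtoc=(5, 15, 15))
        for d in MTOC_CIRCLE_DIAMETER_UM.values():
            assert mtoc_density(stack, seg, "er", d).mean_fluorescence == 42.0

    @pytest.mark.parametrize("diameter", [4.0, 2.0])
    def test_matches_brute_force_disc_oracle(self, diameter, default_cell, default_seg):
        """Same voxel set and mean as an exhaustive loop applying the disc
        inequality (dy·Δy)² + (dx·Δx)² ≤ (d/2)²."""
        stack, truth = default_cell
        seg = CellSegmentation(
            cell_mask=default_seg.cell_mask, mtoc_position=truth.mtoc_position
        )
        res = mtoc_density(stack, seg, "er", diameter)
        zm, ym, xm = truth.mtoc_position
        dz, dy, dx = stack.voxel_size
        er = stack.channel("er")
        values = []
        for z in range(er.shape[0]):
            if abs(z - zm) > 1:
                continue
            for y in range(er.shape[1]):
                for x in range(er.shape[2]):
                    if ((y - ym) * dy) ** 2 + ((x - xm) * dx) ** 2 <= (diameter / 2) ** 2:
                        values.append(float(er[z, y, x]))
        assert res.n_voxels == len(values)
        assert res.mean_fluorescence == pytest.approx(np.mean(values), rel=1e-12)

    def test_edge_slice_drops_missing_neighbor(self, caplog):
        arr = np.random.default_rng(4).random((6, 20, 20))
        stack = make_stack(arr)
        seg = _full_seg(arr.shape, mtoc=(0, 10, 10))
        with caplog.at_level("WARNING", logger="isquant"):
            res = mtoc_density(stack, seg, "er", 2.0)
        assert res.slices_used == (0, 1)
        assert any("edge" in r.message for r in caplog.records)

    def test_huge_circle_converges_to_three_slice_mean(self):
        arr = np.random.default_rng(5).random((10, 16, 16))
        stack = make_stack(arr)
        seg = _full_seg(arr.shape, mtoc=(5, 8, 8))
        res = mtoc_density(stack, seg, "er", diameter_um=1e3)
        assert res.mean_fluorescence == pytest.approx(arr[4:7].mean(), rel=1e-12)

    def test_missing_mtoc_raises(self):
        arr = np.ones((6, 10, 10))
        with pytest.raises(ValueError, match="MTOC"):
            mtoc_density(make_stack(arr), _full_seg(arr.shape), "er", 4.0)

    def test_perinuclear_pool_raises_density(self):
        from isquant import CellParams, generate_coverslip_cell

        base = dict(seed=5)
        lo, _ = generate_coverslip_cell(CellParams(mtoc_pool_fraction=0.01), **base)
        hi, _ = generate_coverslip_cell(CellParams(mtoc_pool_fraction=0.25), **base)
        out = []
        for stack in (lo, hi):
            seg = segment_cell(stack, "actin")
            from isquant.segmentation import detect_mtoc

            seg.mtoc_position = detect_mtoc(stack, seg)
            out.append(mtoc_density(stack, seg, "er", 4.0).mean_fluorescence)
        assert out[1] > out[0]


class TestLineScan:
    def test_constant_slice_gives_flat_profile(self):
        arr = np.full((4, 20, 20), 9.0)
        prof = line_scan(make_stack(arr), "er", (3, 2), (3, 17), z=1)
        np.testing.assert_allclose(prof, 9.0)
        assert prof.size == 16  # floor(15) + 1

    def test_reversal_reverses_profile(self):
        arr = np.random.default_rng(6).random((4, 30, 30))
        stack = make_stack(arr)
        fwd = line_scan(stack, "er", (5.0, 3.0), (22.0, 25.0), z=2)
        rev = line_scan(stack, "er", (22.0, 25.0), (5.0, 3.0), z=2)
        np.testing.assert_allclose(rev, fwd[::-1], rtol=1e-9)

    def test_profile_peaks_at_punctum(self, default_cell):
        stack, truth = default_cell
        zm, ym, xm = truth.mtoc_position
        p0, p1 = (ym, xm - 20), (ym, xm + 20)
        prof = line_scan(stack, "tubulin", p0, p1, z=zm)
        assert abs(int(np.argmax(prof)) - 20) <= 1

    def test_zero_length_raises(self):
        arr = np.ones((4, 10, 10))
        with pytest.raises(ValueError, match="zero-length"):
            line_scan(make_stack(arr), "er", (3, 3), (3, 3), z=0)
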