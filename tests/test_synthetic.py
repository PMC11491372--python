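"""Generator contracts: determinism, measured truth, monotonicity."""

import numpy as np
import pytest

from isquant import (
    BeadParams,
    CellParams,
    SceneTruth,
    generate_bead_conjugate,
    generate_coupled_channels,
    generate_coverslip_cell,
)
from isquant.io_formats import synapse_slice_count
from isquant.synthetic import er_support_mask

NOISEFREE = dict(poisson_noise=False, gaussian_sigma=0.0)


class TestDeterminism:
    def test_coverslip_same_seed_bit_identical(self):
        a, _ = generate_coverslip_cell(seed=7)
        b, _ = generate_coverslip_cell(seed=7)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_different_seeds_differ(self):
        a, _ = generate_coverslip_cell(seed=7)
        b, _ = generate_coverslip_cell(seed=8)
        assert not np.array_equal(a.voxels, b.voxels)

    def test_bead_same_seed_bit_identical(self):
        a, _ = generate_bead_conjugate(polarization=0.5, seed=3)
        b, _ = generate_bead_conjugate(polarization=0.5, seed=3)
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestBottomFraction:
    @pytest.mark.parametrize("requested", [0.2, 0.6])
    def test_realized_matches_voxel_sum_oracle(self, requested):
        """Noise-free slab mass, summed voxel by voxel, equals the recorded
        truth and sits within 1% of the request."""
        params = CellParams(bottom_fraction=requested, **NOISEFREE)
        stack, truth = generate_coverslip_cell(params, seed=1)
        er = stack.channel("er").astype(np.float64)
        n_syn = synapse_slice_count(stack.n_z)
        oracle = er[:n_syn].sum() / er.sum()
        assert truth.true_bottom_fraction == pytest.approx(oracle, abs=1e-6)
        assert abs(oracle - requested) < 0.01

    def test_slab_mass_strictly_increases_with_request(self):
        masses = []
        for f in (0.15, 0.35, 0.6, 0.85):
            params = CellParams(bottom_fraction=f, **NOISEFREE)
            stack, _ = generate_coverslip_cell(params, seed=2)
            er = stack.channel("er").astype(np.float64)
            masses.append(er[: synapse_slice_count(stack.n_z)].sum() / er.sum())
        assert all(a < b for a, b in zip(masses, masses[1:]))

    def test_unachievable_fraction_fails_loudly(self):
        # heavy coupling to a mid-cell tubulin pattern leaves too little
        # independent mass to push nearly all signal into the slab
        params = CellParams(coupling=0.7, mtoc_pool_fraction=0.2, bottom_fraction=0.95)
        with pytest.raises(ValueError, match="unachievable"):
            generate_coverslip_cell(params, seed=0)

    def test_out_of_range_request_rejected(self):
        with pytest.raises(ValueError):
            generate_coverslip_cell(CellParams(bottom_fraction=0.0), seed=0)
        with pytest.raises(ValueError):
            generate_coverslip_cell(CellParams(bottom_fraction=1.2), seed=0)


class TestGeometry:
    def test_cell_too_big_for_stack(self):
        with pytest.raises(ValueError, match="fit"):
            generate_coverslip_cell(CellParams(cell_height_um=4.0), seed=0)
        with pytest.raises(ValueError, match="fit"):
            generate_coverslip_cell(CellParams(cell_radius_xy_um=9.0), seed=0)

    def test_network_volume_hits_target_exactly(self):
        params = CellParams(er_target_volume_um3=20.0, **NOISEFREE)
        _, truth = generate_coverslip_cell(params, seed=4)
        dz, dy, dx = params.voxel_size
        assert truth.true_object_volume_um3 == pytest.approx(20.0, abs=dz * dy * dx)

    def test_network_volume_beyond_capacity_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_coverslip_cell(CellParams(er_target_volume_um3=500.0), seed=0)

    def test_full_support_volume_is_support_voxel_count(self):
        params = CellParams(**NOISEFREE)
        _, truth = generate_coverslip_cell(params, seed=0)
        dz, dy, dx = params.voxel_size
        expected = er_support_mask(params).sum() * dz * dy * dx
        assert truth.true_object_volume_um3 == pytest.approx(expected)


class TestBeadConjugate:
    def test_symmetric_cell_truth_is_zero(self):
        _, truth = generate_bead_conjugate(
            BeadParams(**NOISEFREE), polarization=0.0, seed=3
        )
        assert abs(truth.true_polarization) < 1e-9

    def test_truth_antisymmetric_in_polarization(self):
        _, plus = generate_bead_conjugate(BeadParams(**NOISEFREE), 0.7, seed=5)
        _, minus = generate_bead_conjugate(BeadParams(**NOISEFREE), -0.7, seed=5)
        assert plus.true_polarization == pytest.approx(
            -minus.true_polarization, abs=1e-9
        )

    def test_truth_matches_centroid_oracle(self):
        """Recorded truth equals the projected normalized centroid offset
        recomputed here by direct voxel summation."""
        params = BeadParams(**NOISEFREE)
        stack, truth = generate_bead_conjugate(params, polarization=0.8, seed=6)
        er = stack.channel("er").astype(np.float64)
        dz, dy, dx = params.voxel_size
        nz, ny, nx = er.shape
        zz = np.arange(nz)[:, None, None] * dz
        yy = np.arange(ny)[None, :, None] * dy
        total = er.sum()
        fz = (er * zz).sum() / total
        fy = (er * yy).sum() / total
        cz = (nz - 1) / 2 * dz
        cy = (ny - 1) / 2 * dy
        oracle = (fy - cy) / params.cell_radius_um  # bead axis is +y
        assert truth.true_polarization == pytest.approx(oracle, abs=1e-3)
        assert abs(fz - cz) < 0.05  # no off-axis displacement
        assert truth.true_polarization > 0.3

    def test_mirrored_bead_axis_same_magnitude(self):
        _, a = generate_bead_conjugate(BeadParams(bead_axis=+1, **NOISEFREE), 0.6, seed=7)
        _, b = generate_bead_conjugate(BeadParams(bead_axis=-1, **NOISEFREE), 0.6, seed=7)
        assert a.true_polarization == pytest.approx(b.true_polarization, abs=1e-9)
        assert a.bead_position != b.bead_position

    def test_polarization_out_of_range(self):
        with pytest.raises(ValueError):
            generate_bead_conjugate(polarization=1.5, seed=0)


class TestCoupledChannels:
    def test_full_coupling_noise_free_truth_is_one(self):
        params = CellParams(**NOISEFREE)
        _, truth = generate_coupled_channels(params, coupling=1.0, seed=2)
        assert truth.true_coupling == pytest.approx(1.0, abs=1e-6)

    def test_zero_coupling_truth_near_zero(self):
        params = CellParams(**NOISEFREE)
        _, truth = generate_coupled_channels(params, coupling=0.0, seed=2)
        assert abs(truth.true_coupling) < 0.2

    def test_truth_monotone_in_coupling(self):
        rs = []
        for c in (0.1, 0.45, 0.8):
            params = CellParams(**NOISEFREE)
            _, truth = generate_coupled_channels(params, coupling=c, seed=3)
            rs.append(truth.true_coupling)
        assert rs[0] < rs[1] < rs[2]

    def test_coupling_out_of_range(self):
        with pytest.raises(ValueError):
            generate_coupled_channels(coupling=1.4, seed=0)


def test_scene_truth_json_round_trip(tmp_path):
    _, truth = generate_coverslip_cell(seed=9)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = SceneTruth.from_json(path)
    assert back == truth
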