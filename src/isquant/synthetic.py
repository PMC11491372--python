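"""Synthetic 3-D confocal stacks of B cells with known ground truth.

Every statistic the quantification modules compute has a corresponding
ground-truth quantity here, and the central contract is that **truth is
measured, not requested**: each :class:`SceneTruth` field is recomputed from
the noise-free stack by direct per-voxel summation, so recovery tests
exercise the analysis pipeline rather than the generator's calibration.
Requested and realized values must agree within a documented tolerance or
generation fails loudly.

Two geometries are simulated:

* :func:`generate_coverslip_cell` — a hemispheroidal cell resting on the
  coverslip (z index 0), with a cortical actin shell, a tubulin aster with a
  bright MTOC punctum, and an ER channel painted on an inner support whose
  axial mass profile is exponential in z, tuned so that a requested fraction
  of the signal lies in the synapse-plane slab (first 10% of slices).  The
  ER can additionally be partially coupled to the tubulin pattern (for
  colocalization tests) and carry a perinuclear pool around the MTOC.
* :func:`generate_bead_conjugate` — a spherical cell touching an
  antigen-coated bead, with the ER mass displaced along the cell-bead axis
  by a polarization parameter (for polarity-index tests).

Noise model: Poisson shot noise on the expected counts (peak signal a few
hundred counts) followed by additive Gaussian read noise, clipped at zero.
An optional Gaussian PSF blur (wider in z) can be applied before noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .io_formats import ImageStack, synapse_slice_count

__all__ = [
    "CellParams",
    "BeadParams",
    "SceneTruth",
    "generate_coverslip_cell",
    "generate_bead_conjugate",
    "generate_coupled_channels",
    "cell_body_mask",
    "er_support_mask",
]


@dataclass
class CellParams:
    """Geometry, intensity and noise parameters for a coverslip cell.

    Defaults emulate an A20-like B cell spread on glass imaged at the
    acquisition geometry used throughout: 0.14 µm z-step, 0.2 µm pixels,
    20 slices.
    """

    shape: tuple[int, int, int] = (20, 72, 72)  # (n_z, n_y, n_x)
    voxel_size: tuple[float, float, float] = (0.14, 0.20, 0.20)  # µm
    cell_radius_xy_um: float = 5.0
    cell_height_um: float = 2.2
    #: ER support, relative to the cell body (lateral scale / height fraction).
    er_scale_xy: float = 0.85
    er_height_frac: float = 0.85
    #: Target fraction of noise-free ER signal in the synapse slab.
    bottom_fraction: float = 0.25
    #: Fraction of ER mass colinear with the tubulin pattern (colocalization).
    coupling: float = 0.0
    #: Fraction of ER mass in a perinuclear pool around the MTOC.
    mtoc_pool_fraction: float = 0.05
    #: (z, xy) extent of the perinuclear pool; laterally broad so the pool
    #: reads as a density increase of the reticulum, not a bright puncture,
    #: and axially tight so it stays clear of the synapse slab.
    mtoc_pool_sigma_um: tuple[float, float] = (0.35, 1.2)
    #: Painted ER volume in µm³; None fills the whole support.  When set,
    #: the support becomes a reticular network: the brightest voxels of a
    #: smoothed random field inside the support, exactly matching this
    #: volume, which lets a wide, flat ER keep the same volume as a compact
    #: one (redistribution without net growth).
    er_target_volume_um3: Optional[float] = None
    er_network_sigma_px: float = 2.0
    #: Bias of network-voxel selection toward the MTOC (0 = uniform random
    #: network; larger values concentrate the reticulum perinuclearly while
    #: the painted volume stays exactly on target).
    er_network_mtoc_bias: float = 0.0
    #: Bias of network-voxel selection toward the coverslip: builds a
    #: synaptic ER sheet, so slab enrichment comes from occupancy rather
    #: than from dimming the apical reticulum.
    er_network_bottom_bias: float = 0.0
    er_network_bottom_scale_um: float = 0.4
    #: Total expected ER photon count over the cell (sets the intensity scale;
    #: with the default support this puts the per-voxel mean near 80 counts
    #: and peaks around 200).
    er_total_counts: float = 4.5e5
    #: MTOC height as a fraction of cell height (mid-cell by default).
    mtoc_height_frac: float = 0.5
    # tubulin channel
    tubulin_punctum_counts: float = 250.0
    tubulin_punctum_sigma_um: float = 0.3
    tubulin_ray_counts: float = 30.0
    tubulin_n_rays: int = 12
    tubulin_diffuse_counts: float = 45.0
    # actin channel
    actin_peak_counts: float = 150.0
    actin_thickness_um: float = 0.5
    # multiplicative ER texture (smoothed uniform field)
    texture_low: float = 0.6
    texture_high: float = 1.4
    texture_sigma_px: float = 1.5
    # noise / optics
    poisson_noise: bool = True
    gaussian_sigma: float = 2.0
    psf_sigma_um: Optional[tuple[float, float]] = None  # (z, xy); None = off
    synapse_fraction: float = 0.10


@dataclass
class BeadParams:
    """Geometry and intensity parameters for a bead-conjugate cell."""

    shape: tuple[int, int, int] = (64, 72, 72)
    voxel_size: tuple[float, float, float] = (0.14, 0.20, 0.20)
    cell_radius_um: float = 4.0
    er_scale: float = 0.9
    bead_radius_um: float = 1.5
    #: +1 places the bead on the +y side of the cell, −1 on the −y side.
    bead_axis: int = +1
    #: Fluorescence-blob displacement = polarization × gain × cell radius.
    displacement_gain: float = 0.8
    blob_sigma_um: float = 1.2
    #: Fraction of ER mass painted uniformly over the support (the rest is
    #: the displaced blob); keeps the whole cell segmentable.
    floor_fraction: float = 0.15
    er_total_counts: float = 4.5e5
    tubulin_punctum_counts: float = 250.0
    tubulin_punctum_sigma_um: float = 0.3
    tubulin_diffuse_counts: float = 15.0
    actin_peak_counts: float = 150.0
    actin_thickness_um: float = 0.5
    poisson_noise: bool = True
    gaussian_sigma: float = 2.0
    psf_sigma_um: Optional[tuple[float, float]] = None


@dataclass
class SceneTruth:
    """Ground truth realized by the generator, measured on the noise-free stack."""

    seed: int
    true_bottom_fraction: Optional[float] = None
    true_polarization: Optional[float] = None
    true_coupling: Optional[float] = None
    mtoc_position: Optional[tuple[int, int, int]] = None
    bead_position: Optional[tuple[int, int, int]] = None
    true_object_volume_um3: Optional[float] = None
    requested: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("mtoc_position", "bead_position"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry helpers


def _grids(shape, voxel_size):
    """Physical (z, y, x) coordinate grids; voxel centers at index × spacing."""
    nz, ny, nx = shape
    dz, dy, dx = voxel_size
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    return z, y, x


def _center_yx(shape, voxel_size):
    _, ny, nx = shape
    _, dy, dx = voxel_size
    return ((ny - 1) / 2.0 * dy, (nx - 1) / 2.0 * dx)


def cell_body_mask(params: CellParams) -> np.ndarray:
    """Boolean mask of the hemispheroidal cell body (resting on z = 0)."""
    z, y, x = _grids(params.shape, params.voxel_size)
    cy, cx = _center_yx(params.shape, params.voxel_size)
    u2 = (z / params.cell_height_um) ** 2 + (
        (y - cy) ** 2 + (x - cx) ** 2
    ) / params.cell_radius_xy_um**2
    return u2 <= 1.0


def er_support_mask(params: CellParams) -> np.ndarray:
    """Boolean mask of the painted ER support (inner scaled hemispheroid)."""
    z, y, x = _grids(params.shape, params.voxel_size)
    cy, cx = _center_yx(params.shape, params.voxel_size)
    h = params.er_height_frac * params.cell_height_um
    r = params.er_scale_xy * params.cell_radius_xy_um
    u2 = (z / h) ** 2 + ((y - cy) ** 2 + (x - cx) ** 2) / r**2
    return u2 <= 1.0


def _check_fits(params: CellParams) -> None:
    nz, ny, nx = params.shape
    dz, dy, dx = params.voxel_size
    if params.cell_height_um > (nz - 3) * dz:
        raise ValueError(
            f"cell height {params.cell_height_um} µm does not fit in "
            f"{nz} slices of {dz} µm with margin"
        )
    if 2 * params.cell_radius_xy_um > min((ny - 5) * dy, (nx - 5) * dx):
        raise ValueError("cell diameter does not fit laterally with margin")


def _smooth_texture(shape, rng, sigma_px, lo, hi):
    """Smoothed uniform random field rescaled to [lo, hi]."""
    raw = gaussian_filter(rng.random(shape), sigma=sigma_px)
    rmin, rmax = raw.min(), raw.max()
    if rmax == rmin:
        return np.full(shape, (lo + hi) / 2.0)
    return lo + (hi - lo) * (raw - rmin) / (rmax - rmin)


def _gaussian_blob(shape, voxel_size, center_um, sigma_um):
    z, y, x = _grids(shape, voxel_size)
    cz, cy, cx = center_um
    if np.isscalar(sigma_um):
        sz = sy = sx = float(sigma_um)
    else:
        sz, sy, sx = sigma_um
    return np.exp(
        -0.5 * (((z - cz) / sz) ** 2 + ((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2)
    )


def _tubulin_aster(params: CellParams, body: np.ndarray, mtoc_um, rng) -> np.ndarray:
    """Aster of rays from the MTOC plus a bright punctum and diffuse pool.

    The diffuse pool is spatially textured (smoothed random field), as
    microtubule density in a real cell is heterogeneous; this is what makes
    ER–tubulin coupling measurable in any sub-ROI.
    """
    nz, ny, nx = params.shape
    dz, dy, dx = params.voxel_size
    diffuse_texture = _smooth_texture(
        params.shape, rng, params.texture_sigma_px, params.texture_low, params.texture_high
    )
    tub = params.tubulin_diffuse_counts * diffuse_texture * body.astype(float)
    tub += params.tubulin_punctum_counts * _gaussian_blob(
        params.shape, params.voxel_size, mtoc_um, params.tubulin_punctum_sigma_um
    )
    # rays: sample directions, march to the cell border, deposit decaying
    # counts; they start clear of the punctum so the MTOC voxel does not
    # accumulate an unphysical hot-pixel spike
    rays = np.zeros(params.shape)
    step = 0.5 * min(dy, dx)
    max_t = 2.0 * params.cell_radius_xy_um
    ts = np.arange(0.5, max_t, step)
    decay = np.exp(-ts / params.cell_radius_xy_um)
    for _ in range(params.tubulin_n_rays):
        v = rng.normal(size=3)
        v[0] *= 0.4  # bias rays toward the imaging plane, as in a flat cell
        v /= np.linalg.norm(v)
        pz = mtoc_um[0] + ts * v[0]
        py = mtoc_um[1] + ts * v[1]
        px = mtoc_um[2] + ts * v[2]
        iz = np.round(pz / dz).astype(int)
        iy = np.round(py / dy).astype(int)
        ix = np.round(px / dx).astype(int)
        ok = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        iz, iy, ix = iz[ok], iy[ok], ix[ok]
        inside = body[iz, iy, ix]
        iz, iy, ix = iz[inside], iy[inside], ix[inside]
        np.add.at(rays, (iz, iy, ix), params.tubulin_ray_counts * decay[ok][inside])
    return tub + rays


def _actin_shell(params: CellParams) -> np.ndarray:
    """Cortical actin: a thin shell at the cell border (ring at the footprint)."""
    z, y, x = _grids(params.shape, params.voxel_size)
    cy, cx = _center_yx(params.shape, params.voxel_size)
    u = np.sqrt(
        (z / params.cell_height_um) ** 2
        + ((y - cy) ** 2 + (x - cx) ** 2) / params.cell_radius_xy_um**2
    )
    w = params.actin_thickness_um / params.cell_radius_xy_um
    shell = (u >= 1.0 - w) & (u <= 1.0)  # cortex just inside the membrane
    return params.actin_peak_counts * shell.astype(float)


# ---------------------------------------------------------------------------
# independent per-voxel measurement routines (the "truth is measured" side)


def _measure_bottom_fraction(er: np.ndarray, n_bottom: int) -> float:
    total = float(er.sum())
    return float(er[:n_bottom].sum()) / total


def _measure_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask].astype(float)
    bv = b[mask].astype(float)
    ac = av - av.mean()
    bc = bv - bv.mean()
    denom = math.sqrt(float((ac * ac).sum()) * float((bc * bc).sum()))
    return float((ac * bc).sum()) / denom


def _measure_centroid_um(weights: np.ndarray, voxel_size) -> np.ndarray:
    z, y, x = _grids(weights.shape, voxel_size)
    total = float(weights.sum())
    return np.array(
        [
            float((weights * z).sum()) / total,
            float((weights * y).sum()) / total,
            float((weights * x).sum()) / total,
        ]
    )


# ---------------------------------------------------------------------------
# axial-profile solver


def _solve_axial_rate(slice_sums, n_bottom, target_share, lam_max=40.0):
    """Find the exponential rate λ such that the bottom-slab share of
    ``slice_sums[k] * exp(-λk)`` equals ``target_share``.

    λ > 0 enriches the coverslip-proximal slab, λ < 0 the apical side.
    """
    ks = np.arange(len(slice_sums), dtype=float)
    s = np.asarray(slice_sums, dtype=float)

    def share(lam):
        expo = -lam * ks
        w = np.exp(expo - expo.max())  # shift to avoid overflow
        m = s * w
        return float(m[:n_bottom].sum() / m.sum())

    lo, hi = share(-lam_max), share(lam_max)
    if not (lo < target_share < hi):
        raise ValueError(
            f"requested bottom fraction unachievable for this geometry: "
            f"attainable share range is ({lo:.4f}, {hi:.4f}), "
            f"target {target_share:.4f}"
        )
    return brentq(lambda lam: share(lam) - target_share, -lam_max, lam_max, xtol=1e-12)


def _apply_noise(nf: np.ndarray, rng, poisson: bool, sigma: float) -> np.ndarray:
    out = rng.poisson(np.clip(nf, 0, None)).astype(np.float64) if poisson else nf.copy()
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return np.clip(out, 0, None).astype(np.float32)


def _maybe_blur(nf: np.ndarray, params) -> np.ndarray:
    if params.psf_sigma_um is None:
        return nf
    sz, sxy = params.psf_sigma_um
    dz, dy, dx = params.voxel_size
    return gaussian_filter(nf, sigma=(sz / dz, sxy / dy, sxy / dx))


# ---------------------------------------------------------------------------
# generators


def generate_coverslip_cell(
    params: CellParams | None = None, seed: int = 0
) -> tuple[ImageStack, SceneTruth]:
    """Simulate a B cell spread on an antigen-coated coverslip.

    Returns a 3-channel stack (``er``, ``tubulin``, ``actin``) plus the
    realized :class:`SceneTruth`.  The ER channel mixes three unit-mass
    components: an axially weighted textured field on the ER support
    (weight ``1 − coupling − mtoc_pool_fraction``), a copy of the tubulin
    pattern restricted to the support (weight ``coupling``), and a Gaussian
    perinuclear pool at the MTOC (weight ``mtoc_pool_fraction``).  The
    exponential axial rate is solved so the noise-free synapse-slab share
    equals ``bottom_fraction``; realized and requested values must agree
    within 0.01 or generation fails.
    """
    params = params if params is not None else CellParams()
    _check_fits(params)
    if not 0.0 <= params.coupling <= 1.0:
        raise ValueError(f"coupling must be in [0, 1], got {params.coupling}")
    weight_indep = 1.0 - params.coupling - params.mtoc_pool_fraction
    if weight_indep <= 0:
        raise ValueError("coupling + mtoc_pool_fraction must be < 1")
    if not 0.0 < params.bottom_fraction < 1.0:
        raise ValueError(
            f"bottom_fraction must be in (0, 1), got {params.bottom_fraction}"
        )
    rng = np.random.default_rng(seed)
    nz = params.shape[0]
    n_bottom = synapse_slice_count(nz, params.synapse_fraction)

    body = cell_body_mask(params)
    support = er_support_mask(params)
    cy, cx = _center_yx(params.shape, params.voxel_size)
    mtoc_um = (params.mtoc_height_frac * params.cell_height_um, cy, cx)
    dz, dy, dx = params.voxel_size
    mtoc_vox = (
        int(round(mtoc_um[0] / dz)),
        int(round(mtoc_um[1] / dy)),
        int(round(mtoc_um[2] / dx)),
    )
    if not support[mtoc_vox]:
        raise ValueError("MTOC position falls outside the ER support")

    texture = _smooth_texture(
        params.shape, rng, params.texture_sigma_px, params.texture_low, params.texture_high
    )
    if params.er_target_volume_um3 is not None:
        # reticular support: brightest voxels of a smoothed random field,
        # selected to match the target volume exactly
        n_target = int(round(params.er_target_volume_um3 / (dz * dy * dx)))
        n_region = int(support.sum())
        if not 0 < n_target <= n_region:
            raise ValueError(
                f"er_target_volume_um3={params.er_target_volume_um3} outside the "
                f"support region's capacity ({n_region * dz * dy * dx:.1f} µm³)"
            )
        net_field = gaussian_filter(rng.random(params.shape), params.er_network_sigma_px)
        lo, hi = net_field.min(), net_field.max()
        if hi > lo:
            net_field = (net_field - lo) / (hi - lo)
        if params.er_network_mtoc_bias > 0:
            sz, sxy = params.mtoc_pool_sigma_um
            net_field = net_field + params.er_network_mtoc_bias * _gaussian_blob(
                params.shape, params.voxel_size, mtoc_um, (sz, sxy, sxy)
            )
        if params.er_network_bottom_bias > 0:
            z_um = np.arange(params.shape[0])[:, None, None] * dz
            net_field = net_field + params.er_network_bottom_bias * np.exp(
                -z_um / params.er_network_bottom_scale_um
            )
        vals = np.where(support, net_field, -np.inf).ravel()
        network = np.zeros(vals.size, dtype=bool)
        network[np.argpartition(vals, -n_target)[-n_target:]] = True
        network = network.reshape(params.shape)
    else:
        network = support

    # ER components (unit mass each)
    indep = texture * network
    tubulin_nf = _tubulin_aster(params, body, mtoc_um, rng)
    tub_support = tubulin_nf * network
    sz, sxy = params.mtoc_pool_sigma_um
    pool = _gaussian_blob(params.shape, params.voxel_size, mtoc_um, (sz, sxy, sxy))
    pool = pool * network

    slice_sums = indep.reshape(nz, -1).sum(axis=1)
    coupled_share = (
        params.coupling * float(tub_support[:n_bottom].sum() / tub_support.sum())
        + params.mtoc_pool_fraction * float(pool[:n_bottom].sum() / pool.sum())
    )
    target_indep_share = (params.bottom_fraction - coupled_share) / weight_indep
    if not 0.0 < target_indep_share < 1.0:
        raise ValueError(
            "requested bottom fraction unachievable with the given coupling/pool weights"
        )
    lam = _solve_axial_rate(slice_sums, n_bottom, target_indep_share)
    expo = -lam * np.arange(nz, dtype=float)
    w = np.exp(expo - expo.max())
    indep_w = indep * w[:, None, None]

    er_nf = params.er_total_counts * (
        weight_indep * indep_w / indep_w.sum()
        + params.coupling * tub_support / tub_support.sum()
        + params.mtoc_pool_fraction * pool / pool.sum()
    )

    realized_fraction = _measure_bottom_fraction(er_nf, n_bottom)
    if abs(realized_fraction - params.bottom_fraction) > 0.01:
        raise RuntimeError(
            f"axial calibration failed: requested {params.bottom_fraction}, "
            f"realized {realized_fraction}"
        )

    actin_nf = _actin_shell(params)

    er_nf = _maybe_blur(er_nf, params)
    tubulin_nf = _maybe_blur(tubulin_nf, params)
    actin_nf = _maybe_blur(actin_nf, params)

    truth = SceneTruth(
        seed=seed,
        true_bottom_fraction=_measure_bottom_fraction(er_nf, n_bottom),
        true_coupling=_measure_pearson(er_nf, tubulin_nf, network),
        mtoc_position=mtoc_vox,
        true_object_volume_um3=float(network.sum()) * dz * dy * dx,
        requested={
            "bottom_fraction": params.bottom_fraction,
            "coupling": params.coupling,
            "mtoc_pool_fraction": params.mtoc_pool_fraction,
        },
    )

    channels = np.stack(
        [
            _apply_noise(er_nf, rng, params.poisson_noise, params.gaussian_sigma),
            _apply_noise(tubulin_nf, rng, params.poisson_noise, params.gaussian_sigma),
            _apply_noise(actin_nf, rng, params.poisson_noise, params.gaussian_sigma),
        ]
    )
    stack = ImageStack(
        voxels=channels,
        voxel_size=params.voxel_size,
        channel_roles={"er": 0, "tubulin": 1, "actin": 2},
    )
    return stack, truth


def generate_coupled_channels(
    params: CellParams | None = None, coupling: float = 0.5, seed: int = 0
) -> tuple[ImageStack, SceneTruth]:
    """Coverslip cell whose ER channel is a ``coupling``-weighted mixture of
    the tubulin pattern and an independent textured field (no MTOC pool).

    ``SceneTruth.true_coupling`` records the noise-free Pearson r between the
    two channels inside the ER support.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must be in [0, 1], got {coupling}")
    params = params if params is not None else CellParams()
    # coupling = 1 leaves no independent mass, so no axial profile to solve;
    # shave an epsilon off to keep the mixture well defined while preserving
    # r = 1 to float precision.
    eff = min(coupling, 1.0 - 1e-9)
    params = replace(params, coupling=eff, mtoc_pool_fraction=0.0)
    # high coupling pins the axial profile to the tubulin pattern's; if the
    # requested bottom fraction is out of reach, aim inside the attainable band
    return _generate_with_feasible_fraction(params, seed)


def _generate_with_feasible_fraction(params: CellParams, seed: int):
    """Retry generation with the bottom fraction projected into the
    attainable range implied by the coupled components."""
    try:
        return generate_coverslip_cell(params, seed)
    except ValueError as exc:
        if "unachievable" not in str(exc):
            raise
    # probe the coupled component's bottom share, then request a fraction
    # inside the attainable band
    nz = params.shape[0]
    n_bottom = synapse_slice_count(nz, params.synapse_fraction)
    body = cell_body_mask(params)
    support = er_support_mask(params)
    rng = np.random.default_rng(seed)
    _ = _smooth_texture(params.shape, rng, params.texture_sigma_px,
                        params.texture_low, params.texture_high)
    cy, cx = _center_yx(params.shape, params.voxel_size)
    mtoc_um = (params.mtoc_height_frac * params.cell_height_um, cy, cx)
    tub = _tubulin_aster(params, body, mtoc_um, rng) * support
    tub_share = float(tub[:n_bottom].sum() / tub.sum())
    weight_indep = 1.0 - params.coupling
    # center of the attainable band
    feasible = params.coupling * tub_share + weight_indep * 0.5
    params = replace(params, bottom_fraction=feasible)
    return generate_coverslip_cell(params, seed)


def generate_bead_conjugate(
    params: BeadParams | None = None, polarization: float = 0.0, seed: int = 0
) -> tuple[ImageStack, SceneTruth]:
    """Simulate a B cell–bead conjugate with a polarized ER distribution.

    The ER is a uniform floor over a spherical support plus a Gaussian blob
    whose center is displaced from the cell center along the cell-bead axis
    by ``polarization × displacement_gain × cell_radius``.
    ``SceneTruth.true_polarization`` records the noise-free
    fluorescence-centroid displacement projected on the axis, normalized by
    the cell radius (measured, not requested).
    """
    params = params if params is not None else BeadParams()
    if not -1.0 <= polarization <= 1.0:
        raise ValueError(f"polarization must be in [-1, 1], got {polarization}")
    if params.bead_axis not in (+1, -1):
        raise ValueError("bead_axis must be +1 or -1")
    nz, ny, nx = params.shape
    dz, dy, dx = params.voxel_size
    r = params.cell_radius_um
    if 2 * r > (nz - 4) * dz or 2 * r > min((ny - 4) * dy, (nx - 4) * dx):
        raise ValueError("cell does not fit in the stack with margin")

    rng = np.random.default_rng(seed)
    center = np.array(
        [((nz - 1) / 2.0) * dz, ((ny - 1) / 2.0) * dy, ((nx - 1) / 2.0) * dx]
    )
    axis = np.array([0.0, float(params.bead_axis), 0.0])
    bead_center = center + (r + params.bead_radius_um) * axis
    if np.linalg.norm(bead_center - center) < 0.5 * r:
        raise ValueError("bead overlaps the cell center")

    z, y, x = _grids(params.shape, params.voxel_size)
    rho2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    body = rho2 <= r**2
    support = rho2 <= (params.er_scale * r) ** 2

    blob_center = center + polarization * params.displacement_gain * r * axis
    blob = _gaussian_blob(params.shape, params.voxel_size, blob_center, params.blob_sigma_um)
    blob = blob * support
    floor = support.astype(float)
    er_nf = params.er_total_counts * (
        params.floor_fraction * floor / floor.sum()
        + (1.0 - params.floor_fraction) * blob / blob.sum()
    )

    tub_nf = params.tubulin_diffuse_counts * body.astype(float)
    tub_nf += params.tubulin_punctum_counts * _gaussian_blob(
        params.shape, params.voxel_size, tuple(center), params.tubulin_punctum_sigma_um
    )
    u = np.sqrt(rho2) / r
    w = params.actin_thickness_um / r
    actin_nf = params.actin_peak_counts * ((u >= 1.0 - w) & (u <= 1.0)).astype(float)

    er_nf = _maybe_blur(er_nf, params)
    tub_nf = _maybe_blur(tub_nf, params)
    actin_nf = _maybe_blur(actin_nf, params)

    f_centroid = _measure_centroid_um(er_nf, params.voxel_size)
    true_pol = float(np.dot(f_centroid - center, axis) / r)

    truth = SceneTruth(
        seed=seed,
        true_polarization=true_pol,
        mtoc_position=tuple(int(round(c / d)) for c, d in zip(center, (dz, dy, dx))),
        bead_position=tuple(int(round(c / d)) for c, d in zip(bead_center, (dz, dy, dx))),
        true_object_volume_um3=float(support.sum()) * dz * dy * dx,
        requested={"polarization": polarization},
    )

    channels = np.stack(
        [
            _apply_noise(er_nf, rng, params.poisson_noise, params.gaussian_sigma),
            _apply_noise(tub_nf, rng, params.poisson_noise, params.gaussian_sigma),
            _apply_noise(actin_nf, rng, params.poisson_noise, params.gaussian_sigma),
        ]
    )
    stack = ImageStack(
        voxels=channels,
        voxel_size=params.voxel_size,
        channel_roles={"er": 0, "tubulin": 1, "actin": 2},
    )
    return stack, truth
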