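"""Axial (Z-scan) statistics and the bead polarity index.

The Z-scan expresses each slice's summed fluorescence as a percentage of
the whole-cell fluorescence; the synapse-plane statistic
(``is_fraction_pct``) is the summed percentage over the first 10% of slices
counted from the coverslip.  For bead conjugates, where no coverslip plane
exists, the polarity index takes over: the fluorescence centroid's
displacement from the cell centroid, projected on the cell-bead axis and
normalized by the centroid-to-boundary distance along that axis, so that
−1 is fully anti-polarized and +1 fully polarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ImageStack, synapse_slice_count
from .segmentation import CellSegmentation

logger = logging.getLogger(__name__)


@dataclass
class ZProfile:
    """Per-slice raw and percentage fluorescence plus the synapse fraction.

    Slice index 0 is the coverslip-proximal slice; ``pct_per_slice`` sums to
    100 by construction.
    """

    raw_per_slice: np.ndarray
    pct_per_slice: np.ndarray
    n_synapse_slices: int
    is_fraction_pct: float

    def __post_init__(self) -> None:
        if abs(float(self.pct_per_slice.sum()) - 100.0) > 1e-6:
            raise ValueError("slice percentages must sum to 100")
        if not 0.0 <= self.is_fraction_pct <= 100.0 + 1e-9:
            raise ValueError("is_fraction_pct must be in [0, 100]")


def zscan_profile(
    stack: ImageStack,
    seg: CellSegmentation | None,
    channel_role: str,
    synapse_fraction: float = 0.10,
) -> ZProfile:
    """Per-slice fluorescence profile of one channel.

    Sums are restricted to the cell mask by default (robust to off-cell
    debris); pass ``seg=None`` to sum over the whole frame, mirroring
    macro-style whole-image measurements.
    """
    channel = stack.channel(channel_role).astype(np.float64)
    if seg is not None:
        channel = np.where(seg.cell_mask, channel, 0.0)
    raw = channel.reshape(stack.n_z, -1).sum(axis=1)
    total = float(raw.sum())
    if total <= 0:
        raise ValueError(
            f"zero whole-cell fluorescence on {channel_role!r}: percentages undefined"
        )
    pct = 100.0 * raw / total
    n_syn = synapse_slice_count(stack.n_z, synapse_fraction)
    return ZProfile(
        raw_per_slice=raw,
        pct_per_slice=pct,
        n_synapse_slices=n_syn,
        is_fraction_pct=float(pct[:n_syn].sum()),
    )


def whole_cell_fluorescence(
    stack: ImageStack, seg: CellSegmentation | None, channel_role: str
) -> float:
    """Summed channel intensity over the cell mask (whole frame if ``seg`` is None).

    Equals ``sum(ZProfile.raw_per_slice)`` exactly.
    """
    channel = stack.channel(channel_role).astype(np.float64)
    if seg is not None:
        channel = np.where(seg.cell_mask, channel, 0.0)
    # slice-wise then total, in the same order as zscan_profile, so the
    # identity with sum(raw_per_slice) is bitwise exact
    return float(channel.reshape(stack.n_z, -1).sum(axis=1).sum())


def _mask_centroid_um(mask: np.ndarray, voxel_size) -> np.ndarray:
    idx = np.argwhere(mask).astype(np.float64)
    return idx.mean(axis=0) * np.asarray(voxel_size)


def _intensity_centroid_um(channel: np.ndarray, mask: np.ndarray, voxel_size) -> np.ndarray:
    w = np.where(mask, channel.astype(np.float64), 0.0)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("zero fluorescence inside the mask: centroid undefined")
    idx = np.indices(mask.shape, dtype=np.float64)
    com = np.array([float((w * idx[a]).sum()) / total for a in range(3)])
    return com * np.asarray(voxel_size)


def _boundary_distance_um(
    mask: np.ndarray, origin_um: np.ndarray, direction: np.ndarray, voxel_size
) -> float:
    """Distance from ``origin_um`` to the mask boundary along ``direction``.

    Marches the ray at quarter-voxel steps and returns the distance of the
    last in-mask sample.
    """
    voxel_size = np.asarray(voxel_size, dtype=float)
    step = 0.25 * float(voxel_size.min())
    shape = np.asarray(mask.shape)
    t = 0.0
    last_inside = 0.0
    max_t = float(np.sum(shape * voxel_size))  # generous upper bound
    while t <= max_t:
        pos = origin_um + t * direction
        idx = np.round(pos / voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            break
        if mask[tuple(idx)]:
            last_inside = t
        t += step
    return last_inside


def polarity_index(
    stack: ImageStack,
    seg: CellSegmentation,
    channel_role: str,
    bead_position: tuple[float, float, float] | None = None,
) -> float:
    """Normalized projection of the fluorescence-centroid displacement onto
    the cell-bead axis.

    Let C be the geometric centroid of the cell mask, F the
    intensity-weighted centroid of the channel within the mask, û the unit
    vector from C toward the bead, and R the distance from C to the mask
    boundary along û.  The index is ``((F − C)·û) / R``, computed in
    physical units so anisotropic z is handled correctly, and clamped to
    [−1, 1] (with a warning) against discretization overshoot.
    """
    bead = bead_position if bead_position is not None else seg.bead_position
    if bead is None:
        raise ValueError("bead position required for the polarity index")
    voxel_size = np.asarray(stack.voxel_size, dtype=float)
    bead_um = np.asarray(bead, dtype=float) * voxel_size

    c = _mask_centroid_um(seg.cell_mask, voxel_size)
    axis = bead_um - c
    norm = float(np.linalg.norm(axis))
    if norm < float(voxel_size.max()):
        raise ValueError("bead coincides with the cell centroid: axis undefined")
    u = axis / norm

    f = _intensity_centroid_um(stack.channel(channel_role), seg.cell_mask, voxel_size)
    r = _boundary_distance_um(seg.cell_mask, c, u, voxel_size)
    if r <= 0:
        raise ValueError("degenerate mask: no extent along the bead axis")
    pi = float(np.dot(f - c, u) / r)
    if abs(pi) > 1.0:
        logger.warning("polarity index %.3f clamped to [-1, 1]", pi)
        pi = max(-1.0, min(1.0, pi))
    return pi
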