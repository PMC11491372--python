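"""Masked-ROI colocalization, MTOC-proximal density and line scans.

Colocalization is the plain (non-thresholded) Pearson correlation between
two channels over the voxels of the cell mask restricted to the
synapse-plane slab (first 10% of slices).  MTOC-proximal density is the
mean fluorescence inside a physical-diameter circle (4 µm for the A20 cell
line, 2 µm for primary B cells) drawn on the MTOC slice plus the slices
directly above and below — a short cylinder, as drawn in Fiji, not
intersected with the cell mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

from .io_formats import ImageStack, synapse_slice_count
from .segmentation import CellSegmentation

logger = logging.getLogger(__name__)

#: Cell-type presets for the MTOC circle diameter (µm).
MTOC_CIRCLE_DIAMETER_UM = {"A20": 4.0, "primary": 2.0}


@dataclass
class ColocResult:
    pearson_r: float
    n_voxels: int
    roi_description: str

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1.0 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")
        if self.n_voxels < 2:
            raise ValueError("Pearson r needs at least 2 ROI voxels")


@dataclass
class MtocDensityResult:
    mean_fluorescence: float
    diameter_um: float
    slices_used: tuple[int, ...]
    n_voxels: int

    def __post_init__(self) -> None:
        if self.mean_fluorescence < 0:
            raise ValueError("mean fluorescence must be >= 0")
        s = self.slices_used
        if any(b - a != 1 for a, b in zip(s, s[1:])):
            raise ValueError("slices_used must be consecutive")


def pearson_synapse(
    stack: ImageStack,
    seg: CellSegmentation,
    role_a: str,
    role_b: str,
    synapse_fraction: float = 0.10,
) -> ColocResult:
    """Pearson correlation of two channels in the synapse-slab ROI.

    ROI = cell mask ∩ first ``ceil(synapse_fraction · n_z)`` slices.  No
    Costes thresholding is applied.  Raises on zero variance in either
    channel (r undefined).
    """
    n_syn = synapse_slice_count(stack.n_z, synapse_fraction)
    roi = np.zeros_like(seg.cell_mask)
    roi[:n_syn] = seg.cell_mask[:n_syn]
    n_vox = int(roi.sum())
    if n_vox < 2:
        raise ValueError("synapse-slab ROI has fewer than 2 voxels")
    a = stack.channel(role_a)[roi].astype(np.float64)
    b = stack.channel(role_b)[roi].astype(np.float64)
    if a.var() == 0 or b.var() == 0:
        raise ValueError(
            f"zero variance in ROI ({role_a!r} or {role_b!r}): Pearson r undefined"
        )
    r = float(stats.pearsonr(a, b).statistic)
    return ColocResult(
        pearson_r=r,
        n_voxels=n_vox,
        roi_description=f"cell_mask ∩ first {n_syn} slices",
    )


def mtoc_density(
    stack: ImageStack,
    seg: CellSegmentation,
    channel_role: str,
    diameter_um: float,
) -> MtocDensityResult:
    """Mean fluorescence in a circle of physical diameter centered at the MTOC.

    Uses the MTOC slice plus its immediate neighbors (clamped at the stack
    edges with a warning, dropping the out-of-range slice).  A pixel belongs
    to the circle when its center satisfies
    ``(Δy·dy)² + (Δx·dx)² ≤ (d/2)²``; voxels from the used slices are pooled
    into one mean and the circle is **not** intersected with the cell mask.
    """
    if seg.mtoc_position is None:
        raise ValueError("MTOC position not set on the segmentation")
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    zm, ym, xm = seg.mtoc_position
    _, dy, dx = stack.voxel_size
    n_z, n_y, n_x = stack.frame_shape

    slices = [z for z in (zm - 1, zm, zm + 1) if 0 <= z < n_z]
    if len(slices) < 3:
        logger.warning(
            "MTOC at edge slice %d: using %d-slice cylinder", zm, len(slices)
        )
    yy, xx = np.meshgrid(np.arange(n_y), np.arange(n_x), indexing="ij")
    disc = ((yy - ym) * dy) ** 2 + ((xx - xm) * dx) ** 2 <= (diameter_um / 2.0) ** 2
    n_disc = int(disc.sum())
    if n_disc == 0:
        raise ValueError("circle contains no pixel centers (entirely outside image)")
    channel = stack.channel(channel_role)
    values = channel[slices][:, disc].astype(np.float64)
    return MtocDensityResult(
        mean_fluorescence=float(values.mean()),
        diameter_um=float(diameter_um),
        slices_used=tuple(slices),
        n_voxels=int(values.size),
    )


def line_scan(
    stack: ImageStack,
    channel_role: str,
    p0: tuple[float, float],
    p1: tuple[float, float],
    z: int,
) -> np.ndarray:
    """Bilinear intensity profile along a segment in one slice.

    Samples ``floor(‖p1 − p0‖) + 1`` points spaced evenly from p0 to p1
    (≈ unit-pixel spacing), so reversing the endpoints reverses the profile
    exactly.
    """
    channel = stack.channel(channel_role)
    if not 0 <= z < channel.shape[0]:
        raise ValueError(f"slice index {z} out of range")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("zero-length line")
    n = int(np.floor(length)) + 1
    ts = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    coords = np.stack([p0[0] + ts * (p1[0] - p0[0]), p0[1] + ts * (p1[1] - p0[1])])
    return map_coordinates(channel[z].astype(np.float64), coords, order=1)
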