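"""Cell mask, actin spreading footprint and MTOC detection.

All quantification operations consume a :class:`CellSegmentation`.  The cell
ROI is derived automatically (Gaussian smoothing, Otsu threshold,
morphological closing, hole filling, largest connected component), with an
escape hatch to read a user-supplied mask TIFF for exact reproduction of
hand-drawn ROIs.  The MTOC is the maximum of the smoothed tubulin channel
inside the cell mask; bead positions are taken from annotation, not
detected (latex beads are unlabeled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label

from .io_formats import ImageStack

logger = logging.getLogger(__name__)

#: Pre-threshold smoothing in (z, y, x) units of slices/pixels: enough to
#: suppress shot noise without moving boundaries at the metrics' scale.
DEFAULT_SMOOTH_SIGMA = (0.5, 1.0, 1.0)


class SegmentationError(ValueError):
    """Raised when a usable mask cannot be derived."""


@dataclass
class CellSegmentation:
    """Binary cell mask plus derived landmarks.

    ``cell_mask`` is a single connected 3-D component on the stack's
    (z, y, x) grid; ``footprint_mask`` is the actin-delimited 2-D spreading
    area at the synapse plane (a subset of the cell mask's XY projection).
    """

    cell_mask: np.ndarray
    footprint_mask: Optional[np.ndarray] = None
    mtoc_position: Optional[tuple[int, int, int]] = None
    bead_position: Optional[tuple[int, int, int]] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.cell_mask.ndim != 3:
            raise ValueError("cell_mask must be 3-D (z, y, x)")
        if not self.cell_mask.any():
            raise SegmentationError("empty cell mask")
        if self.mtoc_position is not None and not self.cell_mask[self.mtoc_position]:
            raise ValueError("mtoc_position lies outside the cell mask")


def _smooth(channel: np.ndarray, sigma) -> np.ndarray:
    return ndi.gaussian_filter(channel.astype(np.float64), sigma=sigma)


def segment_cell(
    stack: ImageStack,
    channel_role: str = "actin",
    smooth_sigma=DEFAULT_SMOOTH_SIGMA,
    fill_holes: bool = True,
) -> CellSegmentation:
    """Derive the cell mask from one channel.

    Pipeline: Gaussian smoothing → Otsu threshold → 3-D morphological
    closing → hole filling → keep the largest connected component.
    Raises :class:`SegmentationError` on a blank image or when more than
    half the voxels end up in the mask (threshold failure).
    """
    channel = stack.channel(channel_role)
    smoothed = _smooth(channel, smooth_sigma)
    if smoothed.max() == smoothed.min():
        raise SegmentationError("empty mask: image is flat")
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    if not mask.any():
        raise SegmentationError("empty mask after thresholding")
    # pad before closing: the erosion step would otherwise strip voxels on
    # border-touching slices (the coverslip face is slice 0 of the array)
    padded = np.pad(mask, 2, mode="edge")
    padded = ndi.binary_closing(padded, structure=np.ones((3, 3, 3), bool))
    mask = padded[2:-2, 2:-2, 2:-2]
    if fill_holes:
        # fill each slice first: a cortical shell is open toward the
        # coverslip face, so a pure 3-D fill would leave the interior empty
        for k in range(mask.shape[0]):
            mask[k] = ndi.binary_fill_holes(mask[k])
        mask = ndi.binary_fill_holes(mask)
    labels, n = label(mask, connectivity=3, return_num=True)
    if n == 0:
        raise SegmentationError("empty mask after morphology")
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        logger.warning(
            "%d connected components found on %r channel; keeping the largest "
            "(%d of %d voxels)", n, channel_role, sizes.max(), sizes.sum(),
        )
        mask = labels == keep
    if mask.sum() > 0.5 * mask.size:
        raise SegmentationError(
            "threshold failure: more than 50% of voxels in the mask"
        )
    return CellSegmentation(
        cell_mask=mask,
        provenance={
            "method": "otsu",
            "channel": channel_role,
            "smooth_sigma": tuple(smooth_sigma),
            "threshold": float(thr),
        },
    )


def actin_footprint(
    stack: ImageStack, seg: CellSegmentation, n_synapse_slices: int
) -> np.ndarray:
    """Actin-delimited spreading footprint at the synapse plane.

    Threshold the actin channel within the bottom ``n_synapse_slices``,
    project to XY, fill holes (cortical actin is a ring; the footprint is
    its filled interior), keep the largest component, and clip to the cell
    mask's XY projection.
    """
    if n_synapse_slices < 1:
        raise ValueError("n_synapse_slices must be >= 1")
    slab = stack.channel("actin")[:n_synapse_slices].astype(np.float64)
    slab = ndi.gaussian_filter(slab, sigma=(0, 1.0, 1.0))
    if slab.max() == slab.min():
        raise SegmentationError("empty footprint: actin slab is flat")
    thr = threshold_otsu(slab)
    proj = (slab > thr).any(axis=0)
    proj = ndi.binary_fill_holes(proj)
    labels, n = label(proj, connectivity=2, return_num=True)
    if n == 0:
        raise SegmentationError("empty footprint")
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        proj = labels == (int(np.argmax(sizes)) + 1)
    proj = proj & seg.cell_mask.any(axis=0)
    if not proj.any():
        raise SegmentationError("empty footprint after clipping to cell mask")
    return proj


def detect_mtoc(
    stack: ImageStack, seg: CellSegmentation, smooth_sigma=DEFAULT_SMOOTH_SIGMA
) -> tuple[int, int, int]:
    """MTOC position: maximum of the smoothed tubulin channel in the mask.

    Ties (and the degenerate flat-channel case, which logs a low-contrast
    warning) break deterministically to the lowest (z, then y, then x)
    index.
    """
    tub = _smooth(stack.channel("tubulin"), smooth_sigma)
    masked = np.where(seg.cell_mask, tub, -np.inf)
    in_mask = tub[seg.cell_mask]
    if in_mask.max() == in_mask.min():
        logger.warning("tubulin channel has no contrast inside the mask")
    # np.argmax returns the first maximum in C order = lowest (z, y, x)
    flat_idx = int(np.argmax(masked))
    return tuple(int(i) for i in np.unravel_index(flat_idx, masked.shape))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit (0/255) single-channel TIFF."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path, stack: ImageStack | None = None) -> CellSegmentation:
    """Read a user-supplied 0/255 mask TIFF as a :class:`CellSegmentation`."""
    arr = tifffile.imread(Path(path))
    mask = arr > 0
    if stack is not None and mask.shape != stack.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack {stack.frame_shape}"
        )
    return CellSegmentation(cell_mask=mask, provenance={"method": "file", "path": str(path)})
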