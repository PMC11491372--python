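"""Reading and writing image stacks and per-cell result tables.

The central container is :class:`ImageStack`: a single cropped cell as a
``(channel, z, y, x)`` intensity array with physical voxel sizes and a map
from channel *roles* (``er``, ``tubulin``, ``actin``, ``other``) to channel
indices.  The axial convention is fixed at load time: **z index 0 is always
the slice nearest the coverslip** (the immune-synapse side); files recorded
top-down are re-indexed on read via ``z_flip``.

Intensities are kept in their native dtype and never rescaled or
background-subtracted at read time; computations promote to float
internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Recognised channel roles.
CHANNEL_ROLES = ("er", "tubulin", "actin", "other")

#: Stable column order for QuantRecord CSV export.
METRIC_COLUMNS = (
    "is_fraction_pct",
    "polarity_index",
    "pearson_r",
    "mtoc_density",
    "er_area_um2",
    "actin_area_um2",
    "spreading_ratio",
    "er_volume_um3",
    "whole_cell_fluorescence",
)

_ID_COLUMNS = ("cell_id", "condition", "timepoint_min")

# Metric-name -> (lo, hi) range invariant; None = unbounded on that side.
_METRIC_RANGES = {
    "is_fraction_pct": (0.0, 100.0),
    "polarity_index": (-1.0, 1.0),
    "pearson_r": (-1.0, 1.0),
    "mtoc_density": (0.0, None),
    "er_area_um2": (0.0, None),
    "actin_area_um2": (0.0, None),
    "spreading_ratio": (0.0, None),
    "er_volume_um3": (0.0, None),
}


def synapse_slice_count(n_z: int, fraction: float = 0.10) -> int:
    """Number of slices in the synapse-plane slab: ``ceil(fraction * n_z)``.

    The slab is the first ``fraction`` (default 10%) of the Z-slices counted
    from the coverslip; the ceiling guarantees at least one slice.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"synapse fraction must be in (0, 1], got {fraction}")
    return max(1, math.ceil(fraction * n_z))


@dataclass
class ImageStack:
    """A single-cell multi-channel 3-D stack with voxel geometry.

    Parameters
    ----------
    voxels
        Non-negative intensities, shape ``(n_channels, n_z, n_y, n_x)``.
    voxel_size
        ``(dz, dy, dx)`` in micrometres; all positive.
    channel_roles
        Map from role name to channel index; indices distinct and in range.
    z_origin
        Provenance flag; after construction always ``"coverslip"`` (z index 0
        nearest the glass).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_roles: Mapping[str, int]
    z_origin: str = "coverslip"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 4:
            raise ValueError(
                f"expected a (channel, z, y, x) array, got ndim={self.voxels.ndim}"
            )
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("intensities must be non-negative")
        dz, dy, dx = self.voxel_size
        if not (dz > 0 and dy > 0 and dx > 0):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        self.voxel_size = (float(dz), float(dy), float(dx))
        roles = dict(self.channel_roles)
        idx = list(roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError(f"channel role indices must be distinct: {roles}")
        for role, i in roles.items():
            if not 0 <= i < self.voxels.shape[0]:
                raise ValueError(
                    f"channel index {i} for role {role!r} out of range "
                    f"(n_channels={self.voxels.shape[0]})"
                )
        self.channel_roles = roles
        if self.z_origin != "coverslip":
            raise ValueError("after loading, z index 0 must be the coverslip slice")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(n_z, n_y, n_x)``."""
        return self.voxels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the 3-D ``(z, y, x)`` array for a channel role."""
        if role not in self.channel_roles:
            raise KeyError(
                f"channel role {role!r} not present (have {sorted(self.channel_roles)})"
            )
        return self.voxels[self.channel_roles[role]]


def _voxel_size_from_metadata(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) in µm from ImageJ/OME metadata, if present."""
    dz = dy = dx = None
    meta = tf.imagej_metadata
    if meta and "spacing" in meta:
        dz = float(meta["spacing"])
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None:
        num, den = xres.value
        if num:
            dx = den / num
    if yres is not None:
        num, den = yres.value
        if num:
            dy = den / num
    if tf.ome_metadata:
        # tifffile exposes OME physical sizes through the series metadata;
        # fall back to parsing the XML attributes directly.
        import re

        for axis, name in (("Z", "PhysicalSizeZ"), ("Y", "PhysicalSizeY"), ("X", "PhysicalSizeX")):
            m = re.search(rf'{name}="([0-9.eE+-]+)"', tf.ome_metadata)
            if m:
                val = float(m.group(1))
                if axis == "Z":
                    dz = val
                elif axis == "Y":
                    dy = val
                else:
                    dx = val
    if dz is not None and dy is not None and dx is not None:
        return (dz, dy, dx)
    return None


def read_stack(
    path: str | Path,
    channel_roles: Mapping[str, int],
    z_flip: bool = False,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a 3-D or 4-D TIFF into an :class:`ImageStack`.

    ``z_flip=True`` reverses slice order so the file's last slice becomes
    index 0; use it for stacks acquired top-down.  Voxel sizes come from
    TIFF/OME metadata when present; an explicit ``voxel_size`` overrides the
    metadata (with a logged warning on disagreement, since acquisition
    metadata is often wrong in practice).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        meta_voxel = _voxel_size_from_metadata(tf)

    if arr.ndim == 3:
        arr = arr[np.newaxis]  # single channel
    elif arr.ndim == 4:
        ax = axes.replace("S", "C").replace("Q", "")
        if len(ax) == 4 and set(ax) == {"C", "Z", "Y", "X"}:
            order = [ax.index(a) for a in "CZYX"]
            arr = arr.transpose(order)
        else:
            # Unknown leading axes: take the smaller of the first two as channel.
            if arr.shape[0] > arr.shape[1]:
                arr = arr.transpose(1, 0, 2, 3)
            logger.warning(
                "%s: ambiguous 4-D axes %r; assuming channel axis has size %d",
                path.name, axes, arr.shape[0],
            )
    else:
        raise ValueError(f"{path}: expected 3 or 4 dimensions, got {arr.ndim}")

    if voxel_size is not None:
        if meta_voxel is not None and not np.allclose(meta_voxel, voxel_size):
            logger.warning(
                "%s: voxel size %s overrides file metadata %s",
                path.name, voxel_size, meta_voxel,
            )
        vox = voxel_size
    elif meta_voxel is not None:
        vox = meta_voxel
    else:
        raise ValueError(
            f"{path}: no voxel-size metadata in file and none supplied"
        )

    if z_flip:
        arr = arr[:, ::-1].copy()
    return ImageStack(voxels=arr, voxel_size=vox, channel_roles=dict(channel_roles))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as an ImageJ-style TIFF with voxel sizes.

    Slice 0 is written first, so a round trip with ``z_flip=False`` is the
    identity.  Dtypes outside ImageJ's supported set are stored as float32.
    """
    arr = stack.voxels
    if arr.dtype not in (np.uint8, np.uint16, np.float32):
        arr = arr.astype(np.float32)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        Path(path),
        arr.transpose(1, 0, 2, 3),  # ImageJ hyperstack order ZCYX
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZCYX"},
    )


@dataclass
class QuantRecord:
    """One cell's worth of metrics, destined for one CSV row.

    Metrics that were not computed are *absent from the map*, never
    zero-filled; they export as empty CSV fields.
    """

    cell_id: str
    condition: str = ""
    timepoint_min: float = float("nan")
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.metrics.items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(
                    f"{self.cell_id}: metric {name!r} is null — omit absent metrics instead"
                )
            rng = _METRIC_RANGES.get(name)
            if rng is not None:
                lo, hi = rng
                if (lo is not None and value < lo) or (hi is not None and value > hi):
                    raise ValueError(
                        f"{self.cell_id}: metric {name}={value} outside [{lo}, {hi}]"
                    )


def records_to_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with stable column order."""
    extra = sorted(
        {k for r in records for k in r.metrics} - set(METRIC_COLUMNS)
    )
    columns = list(_ID_COLUMNS) + list(METRIC_COLUMNS) + extra
    rows = []
    for r in records:
        row: dict[str, object] = {
            "cell_id": r.cell_id,
            "condition": r.condition,
            "timepoint_min": r.timepoint_min,
        }
        for k in list(METRIC_COLUMNS) + extra:
            row[k] = r.metrics.get(k, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def write_records(records: Sequence[QuantRecord], path: str | Path) -> None:
    """Write records as CSV: one row per cell, missing metrics empty."""
    records_to_frame(list(records)).to_csv(path, index=False)


def read_records(path: str | Path) -> list[QuantRecord]:
    """Read a QuantRecord CSV back; empty fields become absent metrics."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        metrics = {
            k: float(row[k])
            for k in df.columns
            if k not in _ID_COLUMNS and pd.notna(row[k])
        }
        out.append(
            QuantRecord(
                cell_id=str(row["cell_id"]),
                condition="" if pd.isna(row.get("condition")) else str(row["condition"]),
                timepoint_min=float(row["timepoint_min"])
                if pd.notna(row.get("timepoint_min"))
                else float("nan"),
                metrics=metrics,
            )
        )
    return out
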