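"""Reading multi-channel z-stacks, z-projection, and tabular/image output."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .core import GREEN, RED, ProjectedImagePair

logger = logging.getLogger(__name__)


@dataclass
class ChannelStack:
    """Intensity grid indexed (z, channel, row, col) with physical metadata."""

    data: np.ndarray
    channel_roles: dict = field(default_factory=lambda: {RED: 0, GREEN: 1})
    pixel_pitch_nm: float = 40.0
    z_step_nm: float = 110.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("stack data must be (z, channel, row, col)")
        roles = set(self.channel_roles)
        if roles != {RED, GREEN}:
            raise ValueError("exactly the roles {'red', 'green'} must be assigned")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]


def _normalise_axes(data: np.ndarray, axes: str | None) -> np.ndarray:
    """Reshape TIFF data to (Z, C, Y, X), erroring on ambiguity."""
    if data.ndim == 3:
        if axes in ("CYX", "SYX"):
            return data[np.newaxis]
        if axes == "ZYX":
            raise ValueError("stack has z-slices but no channel axis")
        if axes is None:
            # a leading dimension of 2 with no metadata is taken as channels
            if data.shape[0] == 2:
                return data[np.newaxis]
            raise ValueError("ambiguous 3D axis order; pass axes='CYX' or 'ZCYX'")
        raise ValueError(f"unsupported axis order {axes!r}")
    if data.ndim == 4:
        if axes in (None, "ZCYX"):
            return data
        if axes == "CZYX":
            return np.swapaxes(data, 0, 1)
        raise ValueError(f"unsupported axis order {axes!r}")
    raise ValueError(f"expected 3D or 4D TIFF data, got shape {data.shape}")


def load_stack(path: str | Path, channel_map: dict | None = None,
               pitch_nm: float | None = None, z_step_nm: float = 110.0,
               axes: str | None = None) -> ChannelStack:
    """Load a multi-channel (optionally multi-z) TIFF as a ChannelStack.

    ``channel_map`` maps storage channel index to role, e.g. ``{0: 'green',
    1: 'red'}`` (default: channel 0 = red, 1 = green).  ``pitch_nm``
    overrides any pitch recorded in the file (logged when both are present).
    Axis order is taken from the TIFF series metadata when available and can
    be forced with ``axes``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        file_axes = series.axes if axes is None else axes
        data = series.asarray()
    file_axes = "".join(a for a in file_axes if a in "ZCSYX") or None
    if file_axes is not None:
        file_axes = file_axes.replace("S", "C")
        if len(file_axes) != data.ndim:
            file_axes = None
    data = _normalise_axes(data, file_axes)
    if data.shape[1] < 2:
        raise ValueError(f"{path.name}: need at least 2 channels, "
                         f"found {data.shape[1]}")
    roles = {RED: 0, GREEN: 1}
    if channel_map:
        roles = {role: int(idx) for idx, role in channel_map.items()}
    pitch = 40.0 if pitch_nm is None else float(pitch_nm)
    if pitch_nm is not None:
        logger.info("pixel pitch overridden to %.1f nm for %s", pitch, path.name)
    return ChannelStack(data=data.astype(float), channel_roles=roles,
                        pixel_pitch_nm=pitch, z_step_nm=z_step_nm,
                        provenance={"source": str(path)})


def project_z(stack: ChannelStack, z_indices=None) -> ProjectedImagePair:
    """Average projection over the selected z-slices (default: all)."""
    if z_indices is None:
        z_indices = list(range(stack.n_z))
    z_indices = list(z_indices)
    if not z_indices:
        raise ValueError("z-slice selection is empty")
    for z in z_indices:
        if not 0 <= z < stack.n_z:
            raise IndexError(f"z index {z} out of range (0..{stack.n_z - 1})")
    sub = stack.data[z_indices]
    proj = sub.mean(axis=0)
    return ProjectedImagePair(
        proj[stack.channel_roles[RED]], proj[stack.channel_roles[GREEN]],
        stack.pixel_pitch_nm,
        dict(stack.provenance, z_slices=tuple(z_indices)),
    )


def save_image_pair(path: str | Path, images: ProjectedImagePair) -> None:
    """Write a two-channel (C, Y, X) float TIFF; round-trips bit-identically."""
    stack = np.stack([images.red, images.green]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"axes": "CYX"})


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def ground_truth_to_frame(truth) -> "pandas.DataFrame":
    """Ground-truth CSV contract: one row per simulated FA."""
    import pandas as pd

    return pd.DataFrame([{
        "fa_id": t.fa_id,
        "centre_row": t.centre[0], "centre_col": t.centre[1],
        "angle_deg": t.angle_deg,
        "head_channel": t.head_channel, "head_extra_px": t.head_extra_px,
        "head_nm": t.head_nm,
        "tail_channel": t.tail_channel, "tail_extra_px": t.tail_extra_px,
        "tail_nm": t.tail_nm,
        "head_end_row": t.head_end[0], "head_end_col": t.head_end[1],
        "tail_end_row": t.tail_end[0], "tail_end_col": t.tail_end[1],
        "edge_class": t.edge_class if t.edge_class else "",
    } for t in truth])
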