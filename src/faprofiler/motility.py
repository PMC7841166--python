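"""Classify FAs by the motility of the nearest membrane edge.

From two cell masks (time points t0 and t1 about 30 min apart) the cell
edge at t1 is traced and each edge point receives a signed displacement:
its distance to the t0 edge, positive where the point lies outside the t0
cell (protrusion) and negative inside (retraction).  Displacements are
smoothed along the edge and thresholded into moving/static.  An FA is then
classified by the majority motion class of the edge near its centroid, or
disregarded when it sits too far inside the cell.

All numeric criteria (200 nm motion threshold, 2 um near-edge distance,
15 px smoothing window) are pipeline defaults exposed in the configuration;
they operationalise a qualitative "close to a moving edge" notion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import (binary_erosion, distance_transform_edt,
                           map_coordinates, uniform_filter1d)
from skimage.measure import find_contours

MOVING = "moving"
STATIC = "static"
DISREGARDED = "disregarded"


@dataclass
class MotilityParams:
    motion_threshold_nm: float = 200.0
    near_edge_threshold_nm: float = 2000.0
    smoothing_window_px: int = 15

    def __post_init__(self) -> None:
        if self.motion_threshold_nm <= 0 or self.near_edge_threshold_nm <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class EdgeMotionMap:
    edge_points: np.ndarray       # (n, 2) float (row, col) along the t1 edge
    displacement_nm: np.ndarray   # signed, + = protrusion
    motion_class: np.ndarray      # per point: 'moving' | 'static'
    pixel_pitch_nm: float


def _largest_contour(mask: np.ndarray) -> np.ndarray:
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour (empty cell mask?)")
    return max(contours, key=len)


def edge_displacement(mask_t0: np.ndarray, mask_t1: np.ndarray,
                      params: MotilityParams | None = None,
                      pixel_pitch_nm: float = 40.0) -> EdgeMotionMap:
    """Signed, edge-smoothed displacement of the t1 cell edge relative to t0."""
    params = params or MotilityParams()
    mask_t0 = np.asarray(mask_t0, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    if mask_t0.shape != mask_t1.shape:
        raise ValueError("masks must have the same shape")
    if not mask_t0.any() or not mask_t1.any():
        raise ValueError("empty cell mask")
    contour = _largest_contour(mask_t1)
    boundary0 = mask_t0 & ~binary_erosion(mask_t0)
    dist_to_edge0 = distance_transform_edt(~boundary0)
    d = map_coordinates(dist_to_edge0, contour.T, order=1, mode="nearest")
    inside0 = map_coordinates(mask_t0.astype(float), contour.T, order=0,
                              mode="constant") > 0.5
    signed = np.where(inside0, -d, d) * pixel_pitch_nm
    smoothed = uniform_filter1d(signed, size=max(1, params.smoothing_window_px),
                                mode="wrap")
    classes = np.where(np.abs(smoothed) >= params.motion_threshold_nm,
                       MOVING, STATIC)
    return EdgeMotionMap(edge_points=contour, displacement_nm=smoothed,
                         motion_class=classes, pixel_pitch_nm=pixel_pitch_nm)


def classify_fa_edge(centroid, motion_map: EdgeMotionMap,
                     params: MotilityParams | None = None) -> str:
    """Motion class of the edge nearest an FA centroid.

    Returns 'disregarded' for FAs farther than the near-edge threshold from
    the edge, else the majority class of edge points within one smoothing
    window around the nearest edge point (tie: the nearest point's class).
    """
    params = params or MotilityParams()
    p = np.asarray(centroid, dtype=float)
    d2 = ((motion_map.edge_points - p) ** 2).sum(axis=1)
    nearest = int(np.argmin(d2))
    if np.sqrt(d2[nearest]) * motion_map.pixel_pitch_nm > params.near_edge_threshold_nm:
        return DISREGARDED
    n = len(motion_map.edge_points)
    half = max(1, params.smoothing_window_px) // 2
    idx = (np.arange(nearest - half, nearest + half + 1)) % n
    window = motion_map.motion_class[idx]
    n_moving = int((window == MOVING).sum())
    n_static = len(window) - n_moving
    if n_moving == n_static:
        return str(motion_map.motion_class[nearest])
    return MOVING if n_moving > n_static else STATIC
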