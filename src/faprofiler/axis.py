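"""Fitting, refining, terminating and orienting the FA longitudinal axis.

The long axis of each segmented FA is first estimated from intensity-weighted
second-order moments (the "fit ellipse" estimate), then refined by fitting a
1D Gaussian (baseline + amplitude) to the green-channel intensity profile
sampled perpendicular to the axis at 1 px spacing, and replacing the axis by
a total-least-squares line through the fitted ridge centres.  The line is
rasterized to an 8-connected pixel chain and terminated at each end where the
3x3 box mean of *both* channels falls below 30% of its maximum along the
chain.  Finally the chain is oriented head-first: the head (distal) end is
the one closer to a rectangle enclosing the whole cell.

Angle convention: degrees in [0, 180), measured from the image horizontal
(+col axis) with the +row axis pointing down, so the unit direction of an
axis at angle a is (d_row, d_col) = (-sin a, cos a).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter
from scipy.optimize import OptimizeWarning, curve_fit

from .core import AxisPath, ProjectedImagePair, rasterize_segment
from .segmentation import FARegion

ISOTROPY_ECCENTRICITY = 0.05


def angle_to_direction(angle_deg: float) -> np.ndarray:
    """Unit (row, col) direction of an axis at ``angle_deg``."""
    a = math.radians(angle_deg)
    return np.array([-math.sin(a), math.cos(a)])


def direction_to_angle(d_row: float, d_col: float) -> float:
    """Axis angle in [0, 180) for a (row, col) direction vector."""
    return math.degrees(math.atan2(-d_row, d_col)) % 180.0


@dataclass
class AxisLine:
    """A refined continuous line through an FA's longitudinal axis."""

    centre: tuple[float, float]  # (row, col)
    angle_deg: float
    ridge_points: np.ndarray | None = None  # (k, 2) fitted ridge centres
    qc: tuple[str, ...] = ()


@dataclass
class TerminatedAxis:
    path: AxisPath  # unoriented chain
    qc: tuple[str, ...] = ()


@dataclass
class CellFrame:
    """Rectangle enclosing the cell, used to orient FA axes head-first."""

    row_min: float
    col_min: float
    row_max: float
    col_max: float

    def perimeter_distance(self, point) -> float:
        """Euclidean distance from ``point`` (row, col) to the rectangle's perimeter."""
        r, c = float(point[0]), float(point[1])
        inside = self.row_min <= r <= self.row_max and self.col_min <= c <= self.col_max
        if inside:
            return min(r - self.row_min, self.row_max - r,
                       c - self.col_min, self.col_max - c)
        dr = max(self.row_min - r, 0.0, r - self.row_max)
        dc = max(self.col_min - c, 0.0, c - self.col_max)
        return math.hypot(dr, dc)


def cell_frame_from_mask(mask: np.ndarray) -> CellFrame:
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if rows.size == 0:
        raise ValueError("cell mask is empty")
    return CellFrame(float(rows.min()), float(cols.min()),
                     float(rows.max()), float(cols.max()))


def cell_frame_from_images(images: ProjectedImagePair, sigma: float = 20.0) -> CellFrame:
    """Bounding rectangle of the cell: Otsu on the heavily blurred channel sum."""
    from skimage.filters import threshold_otsu

    blurred = gaussian_filter(images.red + images.green, sigma)
    if np.ptp(blurred) == 0:
        return CellFrame(0.0, 0.0, images.shape[0] - 1.0, images.shape[1] - 1.0)
    mask = blurred > threshold_otsu(blurred, nbins=256)
    if not mask.any():
        return CellFrame(0.0, 0.0, images.shape[0] - 1.0, images.shape[1] - 1.0)
    return cell_frame_from_mask(mask)


def moment_axis(region: FARegion, image: np.ndarray
                ) -> tuple[tuple[float, float], float, tuple[str, ...]]:
    """Intensity-weighted centroid and major-axis angle of a region.

    Returns ``(centre, angle_deg, qc_flags)``.  Nearly isotropic regions
    (eccentricity < 0.05) are flagged and fall back to the bounding-box
    diagonal for the axis direction.
    """
    px = region.pixels
    w = np.asarray(image, dtype=float)[px[:, 0], px[:, 1]]
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        w = np.ones(len(px))
    w = w / w.sum()
    centre = (float(w @ px[:, 0]), float(w @ px[:, 1]))
    d = px - np.array(centre)
    cov = (w[:, None] * d).T @ d
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_min, lam_max = float(evals[0]), float(evals[1])
    qc: list[str] = []
    if lam_max <= 0:
        ecc = 0.0
    else:
        ecc = math.sqrt(max(0.0, 1.0 - lam_min / lam_max))
    if ecc < ISOTROPY_ECCENTRICITY:
        qc.append("isotropic")
        r0, c0, r1, c1 = region.bbox
        angle = direction_to_angle(r1 - r0, max(c1 - c0, 1))
    else:
        v = evecs[:, 1]
        angle = direction_to_angle(v[0], v[1])
    return centre, angle, tuple(qc)


def _region_extents(region: FARegion, centre, angle_deg: float
                    ) -> tuple[float, float, float]:
    """(t_min, t_max) along the axis and full minor extent across it."""
    u = angle_to_direction(angle_deg)
    nvec = np.array([u[1], -u[0]])
    d = region.pixels - np.asarray(centre)
    t = d @ u
    s = d @ nvec
    return float(t.min()), float(t.max()), float(s.max() - s.min() + 1.0)


def _gauss_baseline(x, b, a, c, sd):
    return b + a * np.exp(-((x - c) ** 2) / (2.0 * sd ** 2))


def refine_axis_by_ridge(region: FARegion, green: np.ndarray,
                         centre, angle_deg: float) -> AxisLine:
    """Refine an axis by perpendicular Gaussian ridge fits in the green channel.

    At 1 px spacing along the initial axis, a baseline-plus-Gaussian is
    least-squares fitted to the perpendicular green profile (length 3x the
    region minor extent, bilinear sampling).  Fits with positive amplitude
    and centre shift below half the minor extent are kept; a total-least-
    squares line through the kept centres replaces the initial axis.  With
    fewer than 3 usable centres the initial axis is kept (flagged).
    """
    green = np.asarray(green, dtype=float)
    u = angle_to_direction(angle_deg)
    nvec = np.array([u[1], -u[0]])
    t_min, t_max, minor = _region_extents(region, centre, angle_deg)
    half = max(int(round(1.5 * minor)), 2)
    s = np.arange(-half, half + 1, dtype=float)
    centre = np.asarray(centre, dtype=float)

    kept = []
    for t in np.arange(math.ceil(t_min), math.floor(t_max) + 1.0):
        p = centre + t * u
        coords = p[:, None] + nvec[:, None] * s[None, :]
        prof = map_coordinates(green, coords, order=1, mode="nearest")
        if prof.max() <= prof.min():
            continue
        p0 = (float(prof.min()), float(prof.max() - prof.min()),
              float(s[int(np.argmax(prof))]), max(minor / 4.0, 0.8))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_gauss_baseline, s, prof, p0=p0, maxfev=400)
        except RuntimeError:
            continue
        b, a, c, sd = popt
        if a > 0 and abs(c) < minor / 2.0:
            kept.append(p + c * nvec)

    if len(kept) < 3:
        return AxisLine(tuple(centre), angle_deg, None, ("ridge_fallback",))
    pts = np.array(kept)
    mean = pts.mean(axis=0)
    d = pts - mean
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    v = vt[0]
    return AxisLine((float(mean[0]), float(mean[1])),
                    direction_to_angle(v[0], v[1]), pts)


def terminate_axis(line: AxisLine, images: ProjectedImagePair,
                   region: FARegion, termination_frac: float = 0.30,
                   box: int = 3, max_extension: int = 50
                   ) -> TerminatedAxis | None:
    """Cut the rasterized axis where both channels' box means drop below 30%.

    The line is rasterized to an 8-connected chain extending ``max_extension``
    px beyond the region at both ends.  Per channel, the maximum along the
    chain of the ``box`` x ``box`` mean is found; walking outward from the
    chain centre, each end is cut at the last pixel before *both* channels
    fall below ``termination_frac`` of their maxima.  Paths shorter than 3 px
    are discarded (returns None).
    """
    u = angle_to_direction(line.angle_deg)
    t_min, t_max, _ = _region_extents(region, line.centre, line.angle_deg)
    c = np.asarray(line.centre, dtype=float)
    chain = rasterize_segment(c + (t_min - max_extension) * u,
                              c + (t_max + max_extension) * u)
    nrow, ncol = images.shape
    ok = ((chain[:, 0] >= 0) & (chain[:, 0] < nrow)
          & (chain[:, 1] >= 0) & (chain[:, 1] < ncol))
    chain = chain[ok]
    if len(chain) < 3:
        return None
    qc: list[str] = []

    box_red = uniform_filter(images.red, box, mode="nearest")[chain[:, 0], chain[:, 1]]
    box_green = uniform_filter(images.green, box, mode="nearest")[chain[:, 0], chain[:, 1]]
    below = ((box_red < termination_frac * box_red.max())
             & (box_green < termination_frac * box_green.max()))

    centre_idx = int(np.argmin(((chain - c) ** 2).sum(axis=1)))
    hi = len(chain) - 1
    for j in range(centre_idx, len(chain)):
        if below[j]:
            hi = j - 1
            break
    else:
        qc.append("termination_maxed_high")
    lo = 0
    for j in range(centre_idx, -1, -1):
        if below[j]:
            lo = j + 1
            break
    else:
        qc.append("termination_maxed_low")
    if hi - lo + 1 < 3:
        return None
    return TerminatedAxis(AxisPath(chain[lo:hi + 1], images.pixel_pitch_nm), tuple(qc))


def orient_head_tail(path: AxisPath, cell_frame: CellFrame) -> AxisPath:
    """Order a path head-first: the head end lies closer to the cell frame.

    Exactly equidistant ends are broken deterministically toward the end
    with the smaller (row, col).
    """
    d0 = cell_frame.perimeter_distance(path.pixels[0])
    d1 = cell_frame.perimeter_distance(path.pixels[-1])
    if d1 < d0:
        return path.reversed()
    if d1 == d0 and tuple(path.pixels[-1]) < tuple(path.pixels[0]):
        return path.reversed()
    return path
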