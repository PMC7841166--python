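"""FA candidate detection: DoG band-pass, Otsu thresholding, region extraction.

Detection follows the classic recipe for elongated adhesion plaques: a
difference-of-Gaussians band-pass suppresses both pixel noise and the smooth
cytoplasmic background, an Otsu threshold (dark-background convention, 256
histogram bins) separates FA-scale structures, and 8-connected components
are filtered by area.  Manual outline corrections — in practice mostly the
separation of touching FAs — are replaced by a declarative, reproducible
edits file (delete / split operations).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core import rasterize_segment


@dataclass
class SegmentationParams:
    sigma_low: float = 1.0
    sigma_high: float = 5.0
    min_area: int = 50
    max_area: int = 5000
    source: str = "mean"  # {'green', 'red', 'mean'}

    def __post_init__(self) -> None:
        if not (self.sigma_high > self.sigma_low > 0):
            raise ValueError("require sigma_high > sigma_low > 0")
        if not (self.max_area > self.min_area > 0):
            raise ValueError("require max_area > min_area > 0")
        if self.source not in ("green", "red", "mean"):
            raise ValueError(f"unknown segmentation source {self.source!r}")


@dataclass
class FARegion:
    """One segmented focal adhesion: an 8-connected pixel set."""

    id: int
    pixels: np.ndarray  # (n, 2) int (row, col)
    centroid: tuple[float, float]
    area: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max) inclusive

    @classmethod
    def from_pixels(cls, id: int, pixels: np.ndarray) -> "FARegion":
        pixels = np.asarray(pixels, dtype=int)
        return cls(
            id=id,
            pixels=pixels,
            centroid=(float(pixels[:, 0].mean()), float(pixels[:, 1].mean())),
            area=len(pixels),
            bbox=(int(pixels[:, 0].min()), int(pixels[:, 1].min()),
                  int(pixels[:, 0].max()), int(pixels[:, 1].max())),
        )


def dog_filter(image: np.ndarray, sigma_low: float, sigma_high: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass: blur(sigma_low) - blur(sigma_high)."""
    if not sigma_high > sigma_low:
        raise ValueError("require sigma_high > sigma_low")
    image = np.asarray(image, dtype=float)
    return gaussian_filter(image, sigma_low) - gaussian_filter(image, sigma_high)


def otsu_binarize(filtered: np.ndarray) -> np.ndarray:
    """Foreground mask of pixels strictly above the 256-bin Otsu threshold."""
    filtered = np.asarray(filtered, dtype=float)
    if np.ptp(filtered) == 0:
        raise ValueError("cannot Otsu-threshold a constant image")
    thresh = threshold_otsu(filtered, nbins=256)
    return filtered > thresh


def extract_fa_regions(mask: np.ndarray, params: SegmentationParams | None = None
                       ) -> list[FARegion]:
    """Area-filtered 8-connected components, ids ordered by bounding box."""
    params = params or SegmentationParams()
    labelled = label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = []
    for prop in regionprops(labelled):
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        regions.append(np.array(prop.coords, dtype=int))
    return _relabel(regions)


def _relabel(pixel_sets: list[np.ndarray]) -> list[FARegion]:
    """Deterministic ids by (top row, left col) of the bounding box."""
    keyed = sorted(
        pixel_sets,
        key=lambda px: (int(px[:, 0].min()), int(px[:, 1].min())),
    )
    return [FARegion.from_pixels(i + 1, px) for i, px in enumerate(keyed)]


def read_roi_edits(path: str | Path) -> list[dict]:
    """Parse a ROI edits CSV: rows of ``op,id,polyline``.

    ``op`` is ``delete`` or ``split``; ``polyline`` (split only) is a
    ``;``-separated list of ``row col`` vertices in pixel coordinates.
    """
    edits = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#") or row[0].strip() == "op":
                continue
            op = row[0].strip()
            edit = {"op": op, "id": int(row[1])}
            if op == "split":
                pts = []
                for token in row[2].split(";"):
                    r, c = token.split()
                    pts.append((float(r), float(c)))
                edit["polyline"] = pts
            edits.append(edit)
    return edits


def apply_roi_edits(regions: list[FARegion], edits) -> list[FARegion]:
    """Apply delete/split edits and relabel the result deterministically.

    ``edits`` is a path to an edits CSV or an already-parsed list of dicts.
    A split removes the rasterized polyline pixels from the region and
    re-extracts 8-connected components; an edit referencing an unknown id
    raises ``KeyError``.
    """
    if isinstance(edits, (str, Path)):
        edits = read_roi_edits(edits)
    by_id = {r.id: r for r in regions}
    for edit in edits:
        rid = edit["id"]
        if rid not in by_id:
            raise KeyError(f"ROI edit references unknown region id {rid}")
        if edit["op"] == "delete":
            del by_id[rid]
        elif edit["op"] == "split":
            region = by_id.pop(rid)
            cut = set()
            pts = edit["polyline"]
            for p0, p1 in zip(pts[:-1], pts[1:]):
                cut.update(map(tuple, rasterize_segment(p0, p1)))
            kept = np.array([px for px in region.pixels if tuple(px) not in cut],
                            dtype=int).reshape(-1, 2)
            if len(kept) == 0:
                continue
            # relabel the remainder into 8-connected components
            r0, c0 = kept[:, 0].min(), kept[:, 1].min()
            grid = np.zeros((kept[:, 0].max() - r0 + 1, kept[:, 1].max() - c0 + 1), bool)
            grid[kept[:, 0] - r0, kept[:, 1] - c0] = True
            lab = label(grid, connectivity=2)
            next_id = max(by_id, default=0) + 1
            for v in range(1, lab.max() + 1):
                coords = np.argwhere(lab == v) + (r0, c0)
                by_id[next_id] = FARegion.from_pixels(next_id, coords)
                next_id += 1
        else:
            raise ValueError(f"unknown ROI edit op {edit['op']!r}")
    return _relabel([r.pixels for r in by_id.values()])
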