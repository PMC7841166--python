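"""Per-FA head/tail protrusion measurement from two-channel axis profiles.

This is the core observable of the pipeline.  Given an oriented axis path
(index 0 = head) and the two channels, the analysis proceeds:

1. sample raw red/green intensities along the path and median-filter each
   profile (window 5, truncated at the profile ends);
2. mark each pixel positive per channel when its filtered value reaches 40%
   of that channel's filtered-profile maximum (thresholds are per FA and per
   channel, so the measure is insensitive to expression level);
3. find the *main stretch*: the longest run of dual-positive pixels, allowing
   interior gaps of at most 4 pixels (160 nm at 40 nm pitch) where one or
   both channels dip below threshold — such dips are characteristic of the
   correlated speckle noise that SIM reconstruction leaves inside bright
   structures;
4. at each end of the main stretch, identify the protruding channel (the one
   still positive just outside the stretch, if any) and measure its
   gap-tolerant run length in nm along the path.

If the pixel bordering the main stretch is negative for both channels the
protrusion at that end is exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GREEN, NONE, RED, AxisPath, ProjectedImagePair
from .segmentation import FARegion

logger = logging.getLogger(__name__)


@dataclass
class MeasurementParams:
    """Tunables of the profile analysis, with the pipeline's defaults."""

    threshold_frac: float = 0.40      # positivity: fraction of filtered max
    max_gap: int = 4                  # px of tolerated negativity in a run
    median_window: int = 5            # px, profile median filter
    termination_frac: float = 0.30    # axis termination: fraction of box-mean max
    termination_box: int = 3          # px, box size for the termination mean
    max_axis_extension: int = 50      # px searched beyond the region per end


@dataclass
class ProfilePair:
    """Raw and median-filtered intensities along one axis path."""

    raw_red: np.ndarray
    raw_green: np.ndarray
    filtered_red: np.ndarray
    filtered_green: np.ndarray

    def __len__(self) -> int:
        return len(self.raw_red)


@dataclass
class ProtrusionMeasurement:
    """Head/tail protruding channel identity and length for one FA."""

    fa_id: int
    cell_id: int = 0
    head_channel: str = NONE
    head_nm: float = 0.0
    tail_channel: str = NONE
    tail_nm: float = 0.0
    main_stretch_nm: float = 0.0
    qc: tuple[str, ...] = ()
    centroid: tuple[float, float] | None = None
    path: AxisPath | None = None

    @property
    def discarded(self) -> bool:
        return "discarded" in self.qc


def truncated_median_filter(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Median filter with windows truncated (not reflected) at the ends.

    At index i the window is values[max(0, i-h) : i+h+1] with h = window//2,
    so end windows have sizes h+1 .. window-1.
    """
    values = np.asarray(values, dtype=float)
    h = window // 2
    n = len(values)
    out = np.empty_like(values)
    if n >= window:
        win = np.lib.stride_tricks.sliding_window_view(values, window)
        out[h:n - h] = np.median(win, axis=-1)
        edge = range(h)
    else:
        edge = range(n)
    for i in list(edge) + [n - 1 - i for i in edge if n - 1 - i >= 0]:
        out[i] = np.median(values[max(0, i - h): min(n, i + h + 1)])
    return out


def extract_profiles(path: AxisPath, images: ProjectedImagePair,
                     median_window: int = 5) -> ProfilePair:
    """Sample both channels at the path pixels and median-filter them."""
    rr, cc = path.pixels[:, 0], path.pixels[:, 1]
    raw_red = images.red[rr, cc]
    raw_green = images.green[rr, cc]
    return ProfilePair(
        raw_red=raw_red,
        raw_green=raw_green,
        filtered_red=truncated_median_filter(raw_red, median_window),
        filtered_green=truncated_median_filter(raw_green, median_window),
    )


def mark_positive(profiles: ProfilePair, threshold_frac: float = 0.40
                  ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Threshold each filtered profile at ``threshold_frac`` of its maximum.

    Positivity is non-strict (value >= threshold).  A channel whose filtered
    profile is identically zero yields all-negative marks and a QC flag.
    """
    flags: list[str] = []
    out = []
    for name, prof in ((RED, profiles.filtered_red), (GREEN, profiles.filtered_green)):
        m = prof.max() if len(prof) else 0.0
        if m <= 0:
            out.append(np.zeros(len(prof), dtype=bool))
            flags.append(f"zero_channel_{name}")
        else:
            out.append(prof >= threshold_frac * m)
    return out[0], out[1], tuple(flags)


def find_main_stretch(pos_red: np.ndarray, pos_green: np.ndarray,
                      max_gap: int = 4) -> tuple[int, int] | None:
    """Longest gap-tolerant dual-positive interval, as (i0, i1) inclusive.

    The interval starts and ends on dual-positive pixels and every interior
    run of non-dual-positive pixels is at most ``max_gap`` long.  Length is
    counted in pixels (i1 - i0 + 1); ties go to the interval nearer the head
    (lower i0).  Returns None when no dual-positive pixel exists.
    """
    both = np.asarray(pos_red, dtype=bool) & np.asarray(pos_green, dtype=bool)
    idx = np.flatnonzero(both)
    if idx.size == 0:
        return None
    # split dual-positive indices wherever the gap between neighbours exceeds
    # max_gap; within a group the maximal valid interval spans the whole group
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    best: tuple[int, int] | None = None
    best_len = -1
    for s, e in zip(starts, ends):
        i0, i1 = int(idx[s]), int(idx[e])
        length = i1 - i0 + 1
        if length > best_len:
            best, best_len = (i0, i1), length
    return best


def _gap_tolerant_run_end(pos: np.ndarray, start: int, step: int, max_gap: int) -> int:
    """Index of the outermost positive pixel of a gap-tolerant run.

    The run begins at ``start`` (which must be positive) and walks in
    direction ``step``; it ends when more than ``max_gap`` consecutive
    negatives are met or the sequence ends.
    """
    n = len(pos)
    last = start
    gap = 0
    j = start + step
    while 0 <= j < n:
        if pos[j]:
            last = j
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
        j += step
    return last


def measure_protrusion_at_end(pos_red: np.ndarray, pos_green: np.ndarray,
                              interval: tuple[int, int], end: str,
                              path: AxisPath, max_gap: int = 4
                              ) -> tuple[str, float, tuple[int, int]]:
    """Protruding channel and nm length at one end of the main stretch.

    Returns (channel, length_nm, interval) where the interval may have been
    extended over dual-positive pixels adjoining the original stretch (this
    happens when an interior gap capped the stretch search).  The length is
    the path distance from the last main-stretch pixel to the outermost
    pixel of the single-channel gap-tolerant run; if the bordering pixel is
    negative for both channels the protrusion is zero.
    """
    if end not in ("head", "tail"):
        raise ValueError("end must be 'head' or 'tail'")
    pos_red = np.asarray(pos_red, dtype=bool)
    pos_green = np.asarray(pos_green, dtype=bool)
    both = pos_red & pos_green
    n = len(pos_red)
    i0, i1 = interval
    step = -1 if end == "head" else +1
    while True:
        boundary = i0 if end == "head" else i1
        border = boundary + step
        if border < 0 or border >= n:
            return NONE, 0.0, (i0, i1)
        if both[border]:
            # absorb adjoining dual-positive pixels into the stretch, then
            # re-apply the rule at the new border
            while 0 <= border < n and both[border]:
                if end == "head":
                    i0 = border
                else:
                    i1 = border
                border += step
            continue
        if not pos_red[border] and not pos_green[border]:
            return NONE, 0.0, (i0, i1)
        channel = RED if pos_red[border] else GREEN
        pos = pos_red if channel == RED else pos_green
        outer = _gap_tolerant_run_end(pos, border, step, max_gap)
        return channel, path.length_nm(boundary, outer), (i0, i1)


def measure_profiles(profiles: ProfilePair, path: AxisPath,
                     params: MeasurementParams | None = None,
                     fa_id: int = 0, cell_id: int = 0,
                     qc: tuple[str, ...] = ()) -> ProtrusionMeasurement:
    """Positivity -> main stretch -> per-end protrusions for one profile pair."""
    params = params or MeasurementParams()
    qc = tuple(qc)
    pos_red, pos_green, flags = mark_positive(profiles, params.threshold_frac)
    qc += flags
    interval = find_main_stretch(pos_red, pos_green, params.max_gap)
    if interval is None:
        return ProtrusionMeasurement(fa_id=fa_id, cell_id=cell_id,
                                     qc=qc + ("discarded", "no_main_stretch"),
                                     path=path)
    head_ch, head_nm, interval = measure_protrusion_at_end(
        pos_red, pos_green, interval, "head", path, params.max_gap)
    tail_ch, tail_nm, interval = measure_protrusion_at_end(
        pos_red, pos_green, interval, "tail", path, params.max_gap)
    return ProtrusionMeasurement(
        fa_id=fa_id, cell_id=cell_id,
        head_channel=head_ch, head_nm=head_nm,
        tail_channel=tail_ch, tail_nm=tail_nm,
        main_stretch_nm=path.length_nm(interval[0], interval[1]),
        qc=qc, path=path,
    )


def measure_fa(images: ProjectedImagePair, region: FARegion, cell_frame,
               params: MeasurementParams | None = None,
               cell_id: int = 0) -> ProtrusionMeasurement:
    """Full per-FA measurement: axis fit through protrusion lengths.

    Chains moment axis -> perpendicular-Gaussian ridge refinement -> 30%
    box-mean termination -> head/tail orientation -> profile extraction ->
    positivity -> main stretch -> per-end protrusions.  Every fallback taken
    along the way is recorded as a QC flag; unrecoverable cases yield a
    record flagged ``discarded`` with no lengths.
    """
    from . import axis as _axis

    params = params or MeasurementParams()
    qc: list[str] = []

    centre, angle, flags = _axis.moment_axis(region, _segmentation_image(images))
    qc.extend(flags)
    line = _axis.refine_axis_by_ridge(region, images.green, centre, angle)
    qc.extend(line.qc)
    chain = _axis.terminate_axis(
        line, images, region,
        termination_frac=params.termination_frac,
        box=params.termination_box,
        max_extension=params.max_axis_extension,
    )
    if chain is None or len(chain.path) < 3:
        return ProtrusionMeasurement(fa_id=region.id, cell_id=cell_id,
                                     qc=tuple(qc) + ("discarded", "short_path"),
                                     centroid=region.centroid)
    qc.extend(chain.qc)
    path = _axis.orient_head_tail(chain.path, cell_frame)

    profiles = extract_profiles(path, images, params.median_window)
    m = measure_profiles(profiles, path, params, fa_id=region.id,
                         cell_id=cell_id, qc=tuple(qc))
    if m.discarded:
        logger.info("FA %d discarded: no dual-positive pixel", region.id)
    return replace(m, centroid=region.centroid)


def measure_image(images: ProjectedImagePair,
                  seg_params=None,
                  params: MeasurementParams | None = None,
                  cell_frame=None,
                  roi_edits=None,
                  cell_id: int = 0) -> list[ProtrusionMeasurement]:
    """Segment an image pair and measure every detected FA."""
    from . import axis as _axis
    from .segmentation import (SegmentationParams, apply_roi_edits, dog_filter,
                               extract_fa_regions, otsu_binarize)

    seg_params = seg_params or SegmentationParams()
    params = params or MeasurementParams()
    src = _segmentation_image(images, seg_params.source)
    mask = otsu_binarize(dog_filter(src, seg_params.sigma_low, seg_params.sigma_high))
    regions = extract_fa_regions(mask, seg_params)
    if roi_edits is not None:
        regions = apply_roi_edits(regions, roi_edits)
    if cell_frame is None:
        cell_frame = _axis.cell_frame_from_images(images)
    return [measure_fa(images, reg, cell_frame, params, cell_id) for reg in regions]


def _segmentation_image(images: ProjectedImagePair, source: str = "mean") -> np.ndarray:
    if source == "mean":
        return 0.5 * (images.red + images.green)
    return images.channel(source)


def measurements_to_frame(measurements) -> "pandas.DataFrame":
    """Tabulate measurements as the per-FA output contract (one row per FA)."""
    import pandas as pd

    rows = []
    for m in measurements:
        rows.append({
            "fa_id": m.fa_id, "cell_id": m.cell_id,
            "head_channel": m.head_channel, "head_nm": m.head_nm,
            "tail_channel": m.tail_channel, "tail_nm": m.tail_nm,
            "main_stretch_nm": m.main_stretch_nm,
            "centroid_row": m.centroid[0] if m.centroid else np.nan,
            "centroid_col": m.centroid[1] if m.centroid else np.nan,
            "qc": ";".join(m.qc),
        })
    return pd.DataFrame(rows, columns=[
        "fa_id", "cell_id", "head_channel", "head_nm", "tail_channel",
        "tail_nm", "main_stretch_nm", "centroid_row", "centroid_col", "qc"])
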