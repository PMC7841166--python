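"""Synthetic dual-colour FA scenes with exact ground truth.

The generator emulates the salient features of reconstructed dual-colour
SIM images of adherent cells:

* elongated FA-shaped intensity plateaus (default 25-50 px long and
  8-12 px wide at 40 nm pitch, i.e. 1-2 um by 320-480 nm), with a Gaussian
  cross-profile and a half-Gaussian (SD 1 px) longitudinal end falloff;
* per-channel longitudinal extensions at the distal ("head") and proximal
  ("tail") ends — the quantity the pipeline measures — rendered as
  same-width, same-intensity continuations of the plateau;
* additive read noise, signal-dependent shot-like noise, and "speckle
  holes": small clusters of depressed intensity inside bright patches, the
  phenomenological stand-in for the correlated noise SIM reconstruction
  leaves within structures;
* a polygonal cell outline whose bounding rectangle orients every FA
  (heads point outward), and displaced-polygon time-lapse mask pairs with
  per-segment protrusion/retraction programs for edge-motility tests.

Ground truth protrusion lengths are recorded in px and in nm, the latter by
walking the rasterized true axis with the straight/diagonal step rule, so
truth and measurement share the same length metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GREEN, NONE, RED, AxisPath, ProjectedImagePair
from .axis import angle_to_direction

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))
END_FALLOFF_SD_PX = 1.0


@dataclass
class FASpec:
    """Geometry and channel layout of one simulated focal adhesion.

    ``head_sign`` selects which end of the axis (at ``angle_deg``) is the
    head: +1 places it at centre + (core_length/2) * direction(angle).
    """

    centre: tuple[float, float]            # (row, col) px
    angle_deg: float                       # long-axis orientation, [0, 180)
    core_length: float                     # dual-positive stretch, px
    width: float                           # FWHM across the axis, px
    head_channel: str = NONE
    head_extra: float = 0.0                # protrusion at the distal end, px
    tail_channel: str = NONE
    tail_extra: float = 0.0                # protrusion at the proximal end, px
    peak_red: float = 1000.0
    peak_green: float = 1000.0
    head_sign: int = +1

    def __post_init__(self) -> None:
        if (self.head_extra == 0) != (self.head_channel == NONE):
            raise ValueError("head_extra must be 0 iff head_channel is 'none'")
        if (self.tail_extra == 0) != (self.tail_channel == NONE):
            raise ValueError("tail_extra must be 0 iff tail_channel is 'none'")
        if self.core_length < 1 or self.width < 1:
            raise ValueError("core_length and width must be >= 1 px")
        if self.head_sign not in (-1, 1):
            raise ValueError("head_sign must be +1 or -1")
        for ch in (self.head_channel, self.tail_channel):
            if ch not in (RED, GREEN, NONE):
                raise ValueError(f"unknown channel {ch!r}")

    def swapped(self) -> "FASpec":
        swap = {RED: GREEN, GREEN: RED, NONE: NONE}
        return replace(self, head_channel=swap[self.head_channel],
                       tail_channel=swap[self.tail_channel],
                       peak_red=self.peak_green, peak_green=self.peak_red)


@dataclass
class NoiseSpec:
    """Phenomenological noise model for reconstructed SIM-like images."""

    gaussian_sd: float = 15.0         # additive read noise SD (a.u.)
    shot_scaling: float = 0.5         # noise SD adds shot_scaling * sqrt(signal)
    speckle_hole_rate: float = 2.0    # expected holes per bright patch
    speckle_hole_size: float = 3.0    # hole diameter, px
    speckle_hole_depth: float = 0.6   # fractional intensity drop inside holes

    def __post_init__(self) -> None:
        if min(self.gaussian_sd, self.shot_scaling, self.speckle_hole_rate,
               self.speckle_hole_size) < 0:
            raise ValueError("noise rates/SDs must be >= 0")
        if not 0 <= self.speckle_hole_depth <= 1:
            raise ValueError("speckle_hole_depth must be in [0, 1]")


@dataclass
class SceneSpec:
    image_shape: tuple[int, int] = (1024, 1024)
    pixel_pitch_nm: float = 40.0
    fa_specs: list[FASpec] = field(default_factory=list)
    cell_polygon: np.ndarray | None = None   # (k, 2) vertices (row, col)
    background: tuple[float, float] = (100.0, 100.0)  # (red, green)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0


@dataclass
class GroundTruthRecord:
    fa_id: int
    centre: tuple[float, float]
    angle_deg: float
    head_channel: str
    head_extra_px: float
    head_nm: float
    tail_channel: str
    tail_extra_px: float
    tail_nm: float
    head_end: tuple[float, float]   # outermost head-end point (any channel)
    tail_end: tuple[float, float]
    edge_class: str | None = None


def _step_rule_nm_per_px(u: np.ndarray, pitch: float) -> float:
    """Step-rule path length per Euclidean pixel along direction ``u``.

    An 8-connected chain along ``u`` advances its dominant coordinate by 1
    per step and takes a diagonal step with frequency q = |minor|/|major|;
    M steps cover M*sqrt(1+q^2) Euclidean px and M*(1-q+q*sqrt(2)) straight-
    equivalent steps, giving the conversion factor below (exactly ``pitch``
    for axis-aligned and 45-degree axes, up to ~8% larger in between).
    """
    a, b = sorted(np.abs(u))
    q = a / b if b > 0 else 0.0
    return pitch * (1.0 - q + q * math.sqrt(2.0)) / math.sqrt(1.0 + q * q)


def _protrusion_nm(extra_px: float, u: np.ndarray, pitch: float) -> float:
    """True protrusion length: ``extra_px`` axis pixels under the step rule."""
    return extra_px * _step_rule_nm_per_px(u, pitch)


def render_scene(spec: SceneSpec) -> tuple[ProjectedImagePair, list[GroundTruthRecord]]:
    """Render the noiseless two-channel image and its ground truth.

    Each FA is an anisotropic plateau: Gaussian cross-profile (FWHM =
    ``width``), flat longitudinal core with half-Gaussian (SD 1 px) falloff
    beyond its ends; the two channels are identical except for the per-end
    single-channel extensions.  FAs whose support leaves the image raise a
    ``ValueError`` naming the FA id.
    """
    nrow, ncol = spec.image_shape
    red = np.full(spec.image_shape, float(spec.background[0]))
    green = np.full(spec.image_shape, float(spec.background[1]))
    truth: list[GroundTruthRecord] = []

    for i, fa in enumerate(spec.fa_specs, start=1):
        u = fa.head_sign * angle_to_direction(fa.angle_deg)
        nvec = np.array([u[1], -u[0]])
        half = fa.core_length / 2.0
        cross_sd = fa.width / _FWHM
        centre = np.asarray(fa.centre, dtype=float)

        extents = {}
        for ch, img, peak in ((RED, red, fa.peak_red), (GREEN, green, fa.peak_green)):
            t_hi = half + (fa.head_extra if fa.head_channel == ch else 0.0)
            t_lo = -half - (fa.tail_extra if fa.tail_channel == ch else 0.0)
            extents[ch] = (t_lo, t_hi)
            margin = 3.0 * END_FALLOFF_SD_PX
            reach = max(abs(t_lo), t_hi) + margin + 3.0 * cross_sd
            r0, r1 = int(math.floor(centre[0] - reach)), int(math.ceil(centre[0] + reach))
            c0, c1 = int(math.floor(centre[1] - reach)), int(math.ceil(centre[1] + reach))
            if r0 < 0 or c0 < 0 or r1 >= nrow or c1 >= ncol:
                raise ValueError(f"FA {i} extends outside the image")
            rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                                 indexing="ij")
            dr, dc = rr - centre[0], cc - centre[1]
            t = dr * u[0] + dc * u[1]
            s = dr * nvec[0] + dc * nvec[1]
            lon = np.ones_like(t)
            over = t - t_hi
            lon = np.where(over > 0, np.exp(-over ** 2 / (2 * END_FALLOFF_SD_PX ** 2)), lon)
            under = t_lo - t
            lon = np.where(under > 0, np.exp(-under ** 2 / (2 * END_FALLOFF_SD_PX ** 2)), lon)
            cross = np.exp(-s ** 2 / (2.0 * cross_sd ** 2))
            img[r0:r1 + 1, c0:c1 + 1] += peak * lon * cross

        pitch = spec.pixel_pitch_nm
        head_tip = centre + (half + fa.head_extra) * u
        tail_tip = centre - (half + fa.tail_extra) * u
        truth.append(GroundTruthRecord(
            fa_id=i, centre=tuple(centre), angle_deg=fa.angle_deg,
            head_channel=fa.head_channel, head_extra_px=fa.head_extra,
            head_nm=_protrusion_nm(fa.head_extra, u, pitch),
            tail_channel=fa.tail_channel, tail_extra_px=fa.tail_extra,
            tail_nm=_protrusion_nm(fa.tail_extra, u, pitch),
            head_end=tuple(head_tip), tail_end=tuple(tail_tip),
        ))

    images = ProjectedImagePair(red, green, spec.pixel_pitch_nm,
                                {"source": "synthetic", "seed": spec.seed})
    return images, truth


def add_noise(images: ProjectedImagePair, noise: NoiseSpec, seed: int
              ) -> ProjectedImagePair:
    """Apply speckle holes, shot-like and additive Gaussian noise (seeded).

    Holes are punched only inside above-background patches (per-channel Otsu
    foreground), before the pixelwise noise; output is clipped at zero and
    byte-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for img in (images.red, images.green):
        arr = img.astype(float).copy()
        if noise.speckle_hole_rate > 0 and noise.speckle_hole_depth > 0:
            arr = _punch_holes(arr, noise, rng)
        if noise.shot_scaling > 0:
            arr = arr + rng.normal(0.0, 1.0, arr.shape) * noise.shot_scaling * np.sqrt(
                np.clip(img, 0, None))
        if noise.gaussian_sd > 0:
            arr = arr + rng.normal(0.0, noise.gaussian_sd, arr.shape)
        out.append(np.clip(arr, 0.0, None))
    return ProjectedImagePair(out[0], out[1], images.pixel_pitch_nm,
                              dict(images.provenance, noise_seed=seed))


def _punch_holes(arr: np.ndarray, noise: NoiseSpec, rng: np.random.Generator
                 ) -> np.ndarray:
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    if np.ptp(arr) == 0:
        return arr
    fg = arr > threshold_otsu(arr, nbins=256)
    radius = noise.speckle_hole_size / 2.0
    rr, cc = np.ogrid[:arr.shape[0], :arr.shape[1]]
    for prop in regionprops(label(fg, connectivity=2)):
        if prop.area < 25:
            continue
        n_holes = rng.poisson(noise.speckle_hole_rate)
        if n_holes == 0:
            continue
        coords = prop.coords
        picks = coords[rng.integers(0, len(coords), size=n_holes)]
        for hr, hc in picks:
            r0 = max(0, int(hr - radius - 1)); r1 = min(arr.shape[0], int(hr + radius + 2))
            c0 = max(0, int(hc - radius - 1)); c1 = min(arr.shape[1], int(hc + radius + 2))
            win_r, win_c = np.ogrid[r0:r1, c0:c1]
            disk = (win_r - hr) ** 2 + (win_c - hc) ** 2 <= radius ** 2
            local = arr[r0:r1, c0:c1]
            local[disk & fg[r0:r1, c0:c1]] *= (1.0 - noise.speckle_hole_depth)
    return arr


# ---------------------------------------------------------------------------
# time-lapse cell masks


def _polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon

    rr, cc = draw_polygon(vertices[:, 0], vertices[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def displace_polygon(vertices: np.ndarray, displacements_px: np.ndarray) -> np.ndarray:
    """Offset each polygon edge outward by its programmed displacement.

    Edge i runs from vertex i to vertex i+1 (cyclic).  New vertices are the
    intersections of consecutive offset edge lines (miter joins); a
    self-intersecting result raises ``ValueError``.
    """
    from shapely.geometry import Polygon

    v = np.asarray(vertices, dtype=float)
    k = len(v)
    d = np.asarray(displacements_px, dtype=float)
    if len(d) != k:
        raise ValueError("need one displacement per polygon edge")
    centroid = v.mean(axis=0)
    pts, dirs = [], []
    for i in range(k):
        a, b = v[i], v[(i + 1) % k]
        e = b - a
        ln = np.linalg.norm(e)
        if ln == 0:
            raise ValueError("degenerate polygon edge")
        e = e / ln
        nrm = np.array([e[1], -e[0]])
        mid = 0.5 * (a + b)
        if np.dot(nrm, mid - centroid) < 0:  # point outward
            nrm = -nrm
        pts.append(a + d[i] * nrm)
        dirs.append(e)
    new_v = np.empty_like(v)
    for i in range(k):
        p_prev, e_prev = pts[i - 1], dirs[i - 1]
        p_cur, e_cur = pts[i], dirs[i]
        cross = e_prev[0] * e_cur[1] - e_prev[1] * e_cur[0]
        if abs(cross) < 1e-9:
            new_v[i] = 0.5 * (p_prev + p_cur)
        else:
            # solve p_prev + t*e_prev = p_cur + s*e_cur
            rhs = p_cur - p_prev
            t = (rhs[0] * e_cur[1] - rhs[1] * e_cur[0]) / cross
            new_v[i] = p_prev + t * e_prev
    poly = Polygon([(c, r) for r, c in new_v])
    if not poly.is_valid:
        raise ValueError("displaced polygon is self-intersecting")

    def shoelace(p):
        x, y = p[:, 1], p[:, 0]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    if shoelace(new_v) * shoelace(v) <= 0:  # collapsed/inverted outline
        raise ValueError("displaced polygon is self-intersecting")
    return new_v


def render_timelapse_masks(spec: SceneSpec, edge_program_nm,
                           ) -> tuple[np.ndarray, np.ndarray, list[GroundTruthRecord]]:
    """Binary cell masks at t0/t1 from a per-edge displacement program.

    ``edge_program_nm`` gives one signed displacement (nm; + = protrusion)
    per polygon edge.  Segments with displacement 0 are static, others
    moving; each FA in the scene inherits the class of its nearest t0 edge
    segment in the returned ground truth.
    """
    if spec.cell_polygon is None:
        raise ValueError("scene has no cell polygon")
    v0 = np.asarray(spec.cell_polygon, dtype=float)
    program = np.asarray(edge_program_nm, dtype=float)
    d_px = program / spec.pixel_pitch_nm
    v1 = displace_polygon(v0, d_px)
    mask0 = _polygon_mask(v0, spec.image_shape)
    mask1 = _polygon_mask(v1, spec.image_shape)

    def seg_class(disp_nm: float) -> str:
        if disp_nm == 0:
            return "static"
        return "protruding" if disp_nm > 0 else "retracting"

    _, truth = render_scene(replace(spec, noise=NoiseSpec(0, 0, 0, 0, 0))) \
        if spec.fa_specs else (None, [])
    k = len(v0)
    for rec in truth:
        best, best_d = None, np.inf
        p = np.asarray(rec.centre)
        for i in range(k):
            a, b = v0[i], v0[(i + 1) % k]
            dist = _point_segment_distance(p, a, b)
            if dist < best_d:
                best, best_d = i, dist
        rec.edge_class = seg_class(program[best])
    return mask0, mask1, truth


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


# ---------------------------------------------------------------------------
# randomized scene builder


def random_scene(seed: int,
                 n_fas: int = 40,
                 image_shape: tuple[int, int] = (1024, 1024),
                 pixel_pitch_nm: float = 40.0,
                 head_channel: str = NONE,
                 tail_channel: str = NONE,
                 head_extra_px: tuple[float, float] = (2.0, 8.0),
                 tail_extra_px: tuple[float, float] = (2.0, 8.0),
                 core_length_px: tuple[float, float] = (25.0, 50.0),
                 width_px: tuple[float, float] = (8.0, 12.0),
                 peak: tuple[float, float] = (800.0, 1200.0),
                 background: float = 100.0,
                 noise: NoiseSpec | None = None,
                 angle_jitter_deg: float = 15.0,
                 n_vertices: int = 12) -> SceneSpec:
    """Build a scene of peripherally placed, outward-pointing FAs.

    FAs sit in an annulus near the polygonal cell outline, roughly radially
    oriented (heads outward, as adhesions at protruding edges are), without
    mutual overlap and with an unambiguous head-to-frame distance margin so
    ground-truth orientation matches the rectangle rule.  ``head_channel`` /
    ``tail_channel`` name the protruding channel at each end ('none' for no
    protrusion); extras are drawn uniformly from the given px ranges.
    """
    rng = np.random.default_rng(seed)
    nrow, ncol = image_shape
    centre = np.array([nrow / 2.0, ncol / 2.0])
    radius = 0.42 * min(nrow, ncol)
    angles = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    radii = radius * rng.uniform(0.85, 1.0, n_vertices)
    polygon = np.column_stack([centre[0] + radii * np.sin(angles),
                               centre[1] + radii * np.cos(angles)])

    fas: list[FASpec] = []
    placed: list[tuple[np.ndarray, float]] = []
    attempts = 0
    while len(fas) < n_fas and attempts < 200 * n_fas:
        attempts += 1
        theta = rng.uniform(0, 2 * math.pi)
        frac = rng.uniform(0.55, 0.82)
        pos = centre + frac * radius * np.array([math.sin(theta), math.cos(theta)])
        L = rng.uniform(*core_length_px)
        W = rng.uniform(*width_px)
        h_extra = rng.uniform(*head_extra_px) if head_channel != NONE else 0.0
        t_extra = rng.uniform(*tail_extra_px) if tail_channel != NONE else 0.0
        reach = L / 2 + max(h_extra, t_extra) + 1.5 * W + 4
        if any(np.linalg.norm(pos - q) < reach + r for q, r in placed):
            continue
        # radial orientation with jitter; head points outward
        radial = math.degrees(math.atan2(-(pos - centre)[0], (pos - centre)[1]))
        ang = (radial + rng.uniform(-angle_jitter_deg, angle_jitter_deg)) % 180.0
        u = angle_to_direction(ang)
        head_sign = 1 if np.dot(u, pos - centre) >= 0 else -1
        if (min(pos[0], pos[1], nrow - 1 - pos[0], ncol - 1 - pos[1]) < reach):
            continue
        # keep the whole FA inside the cell polygon and the orientation margin
        tip_h = pos + head_sign * (L / 2 + h_extra + 3) * u
        tip_t = pos - head_sign * (L / 2 + t_extra + 3) * u
        if not (_inside_polygon(tip_h, polygon) and _inside_polygon(tip_t, polygon)):
            continue
        frame = (polygon[:, 0].min(), polygon[:, 1].min(),
                 polygon[:, 0].max(), polygon[:, 1].max())
        d_h = _frame_distance(tip_h, frame)
        d_t = _frame_distance(tip_t, frame)
        if d_t - d_h < 5.0:
            continue
        pk = rng.uniform(*peak)
        fas.append(FASpec(
            centre=(float(pos[0]), float(pos[1])), angle_deg=float(ang),
            core_length=float(L), width=float(W),
            head_channel=head_channel, head_extra=float(h_extra),
            tail_channel=tail_channel, tail_extra=float(t_extra),
            peak_red=float(pk), peak_green=float(pk), head_sign=head_sign))
        placed.append((pos, reach))
    return SceneSpec(image_shape=image_shape, pixel_pitch_nm=pixel_pitch_nm,
                     fa_specs=fas, cell_polygon=polygon,
                     background=(background, background),
                     noise=noise if noise is not None else NoiseSpec(),
                     seed=seed)


def simulate_reference_measurements(n_fas: int, seed: int,
                                    core_length_px: tuple[float, float] = (25.0, 50.0),
                                    peak: tuple[float, float] = (800.0, 1200.0),
                                    background: float = 100.0,
                                    noise: NoiseSpec | None = None,
                                    margin_px: int = 10,
                                    pixel_pitch_nm: float = 40.0) -> list:
    """Profile-level simulation of a same-protein dual-colour ("reference") set.

    Each simulated FA is a 1D axis profile pair: identical plateau signal
    (half-Gaussian end falloff) in both channels, plus independent per-channel
    noise — Gaussian, shot-like, and short speckle dips inside the plateau —
    measured with the standard profile analysis on a random straight/diagonal
    step pattern.  This is the cheap stand-in for imaging a full
    identical-channel scene: it exercises the measurement exactly, so the
    returned apparent protrusions form the null ("reference") distribution
    used for bias estimation and type-I-error calibration.
    """
    from .profiles import MeasurementParams, ProfilePair, measure_profiles, \
        truncated_median_filter

    rng = np.random.default_rng(seed)
    noise = noise if noise is not None else NoiseSpec()
    params = MeasurementParams()
    out = []
    for i in range(n_fas):
        L = rng.uniform(*core_length_px)
        n = int(round(L)) + 2 * margin_px
        t = np.arange(n, dtype=float) - margin_px
        lon = np.ones(n)
        lon[t < 0] = np.exp(-t[t < 0] ** 2 / (2 * END_FALLOFF_SD_PX ** 2))
        over = t - (L - 1)
        lon[over > 0] = np.exp(-over[over > 0] ** 2 / (2 * END_FALLOFF_SD_PX ** 2))
        signal = background + rng.uniform(*peak) * lon
        profs = []
        for _ in range(2):
            arr = signal.copy()
            if noise.speckle_hole_rate > 0 and noise.speckle_hole_depth > 0:
                for _ in range(rng.poisson(noise.speckle_hole_rate)):
                    c = rng.integers(0, n)
                    w = max(1, int(round(noise.speckle_hole_size)))
                    arr[max(0, c - w // 2): c + (w + 1) // 2] *= \
                        (1.0 - noise.speckle_hole_depth)
            arr = arr + rng.normal(0, 1, n) * noise.shot_scaling * np.sqrt(signal)
            arr = arr + rng.normal(0, noise.gaussian_sd, n)
            profs.append(np.clip(arr, 0, None))
        # random but consistent straight/diagonal step pattern along an axis
        ang = rng.uniform(0, 180)
        u = angle_to_direction(ang)
        pts = np.round(np.arange(n)[:, None] * u * (1.0 / max(abs(u).max(), 1e-9))
                       + [margin_px + 200, margin_px + 200]).astype(int)
        # deduplicate consecutive equal pixels from rounding
        keep = np.ones(len(pts), bool)
        keep[1:] = (np.abs(np.diff(pts, axis=0)).max(axis=1) > 0)
        pts = pts[keep][:n]
        if len(pts) < n:  # pad by extending the last step direction
            extra = pts[-1] + np.cumsum(
                np.repeat([pts[-1] - pts[-2]], n - len(pts), axis=0), axis=0)
            pts = np.vstack([pts, extra])
        path = AxisPath(pts, pixel_pitch_nm)
        pp = ProfilePair(profs[0], profs[1],
                         truncated_median_filter(profs[0], params.median_window),
                         truncated_median_filter(profs[1], params.median_window))
        out.append(measure_profiles(pp, path, params, fa_id=i + 1))
    return out


def _inside_polygon(p: np.ndarray, polygon: np.ndarray) -> bool:
    from matplotlib.path import Path as MplPath

    return bool(MplPath(polygon[:, ::-1]).contains_point((p[1], p[0])))


def _frame_distance(p: np.ndarray, frame: tuple[float, float, float, float]) -> float:
    r0, c0, r1, c1 = frame
    return min(p[0] - r0, r1 - p[0], p[1] - c0, c1 - p[1])
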