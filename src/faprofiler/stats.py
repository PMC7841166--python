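"""Signed protrusion statistics: histograms, bias correction, Mann-Whitney,
2D difference histograms and their diverging LUT rendering.

Sign convention: a green protrusion is positive, a red protrusion negative,
no protrusion is zero — independently for heads and tails — so every
population of FAs yields a signed head distribution and a signed tail
distribution.  A same-protein dual-colour ("reference") set defines the
apparent-protrusion null; its per-end median is the measurement bias that
is subtracted from experimental sets.  Distributions are binned at 80 nm
(one bin centred on zero) and compared against the reference with two-tailed
Mann-Whitney U tests; 2D (head, tail) histograms use 80 x 80 nm bins and
are reported as percentage-point differences from the reference, rendered
with a cyan-white-magenta diverging lookup table whose linear level map is
level = round(255 * (delta + 3.45) / 6.90), with levels 124-132 kept white.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm, rankdata

from .core import GREEN, NONE, RED

BIN_NM = 80.0
LUT_SPAN_PP = 3.45            # |delta| mapped to the LUT extremes
LUT_WHITE_BAND = (124, 132)   # inclusive level range kept white


@dataclass
class SignedProtrusionSet:
    """Per-FA signed head and tail protrusion values (nm) for a population."""

    head: np.ndarray
    tail: np.ndarray
    label: str = ""
    bias_corrected: bool = False
    bias: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float)
        self.tail = np.asarray(self.tail, dtype=float)
        if self.head.shape != self.tail.shape:
            raise ValueError("head and tail arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.head)

    def values(self, end: str) -> np.ndarray:
        if end == "head":
            return self.head
        if end == "tail":
            return self.tail
        raise ValueError("end must be 'head' or 'tail'")


@dataclass
class HistogramComparison:
    end: str
    bin_edges: np.ndarray
    counts_experimental: np.ndarray
    counts_reference: np.ndarray
    median_experimental_nm: float
    u_statistic: float
    p_value: float
    n_experimental: int
    n_reference: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def reported_median_nm(self) -> float | None:
        """Median protrusion length, reported only when the shift is significant."""
        return self.median_experimental_nm if self.significant else None


@dataclass
class Diff2DHistogram:
    head_edges: np.ndarray
    tail_edges: np.ndarray
    freq_experimental_pct: np.ndarray   # (head bins, tail bins), sums to 100
    freq_reference_pct: np.ndarray
    diff_pp: np.ndarray                 # percentage points, sums to 0


def _signed(channel: str, nm: float) -> float:
    if channel == GREEN:
        return +nm
    if channel == RED:
        return -nm
    return 0.0


def to_signed(measurements, label: str = "") -> SignedProtrusionSet:
    """Signed per-end values from QC-passing measurements.

    Accepts a sequence of ``ProtrusionMeasurement`` or a DataFrame following
    the per-FA output contract; discarded rows are dropped.
    """
    heads, tails = [], []
    try:
        rows = measurements.itertuples()
        for m in rows:
            if "discarded" in str(m.qc):
                continue
            heads.append(_signed(m.head_channel, m.head_nm))
            tails.append(_signed(m.tail_channel, m.tail_nm))
    except AttributeError:
        for m in measurements:
            if m.discarded:
                continue
            heads.append(_signed(m.head_channel, m.head_nm))
            tails.append(_signed(m.tail_channel, m.tail_nm))
    return SignedProtrusionSet(np.array(heads), np.array(tails), label=label)


def reference_bias(reference: SignedProtrusionSet) -> tuple[float, float]:
    """Per-end measurement bias: the median signed value of the reference set.

    In a same-protein dual-colour set both ends should centre on zero; any
    systematic offset (the study's apparent green-length bias) is returned
    here as (head_bias_nm, tail_bias_nm).
    """
    if reference.n == 0:
        raise ValueError("reference set is empty")
    if reference.n < 30:
        warnings.warn(f"reference set has only {reference.n} FAs; "
                      "bias estimate may be unstable", stacklevel=2)
    return float(np.median(reference.head)), float(np.median(reference.tail))


def apply_bias(s: SignedProtrusionSet, biases: tuple[float, float]
               ) -> SignedProtrusionSet:
    """Subtract per-end biases from every signed value (once only)."""
    hb, tb = float(biases[0]), float(biases[1])
    if not (math.isfinite(hb) and math.isfinite(tb)):
        raise ValueError("biases must be finite")
    if s.bias_corrected:
        raise ValueError("set is already bias-corrected")
    return SignedProtrusionSet(s.head - hb, s.tail - tb, label=s.label,
                               bias_corrected=True, bias=(hb, tb))


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by dynamic programming over the permutation null.

    Counts, over all C(n, nx) assignments of the pooled mid-ranks to the two
    groups, how many yield a U at least as far from nx*ny/2 as observed.
    Ties are handled exactly because the pooled mid-rank multiset is fixed.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * rankdata(pooled)).astype(int)  # doubled mid-ranks
    n = nx + ny
    max_sum = int(ranks2.sum())
    # dp[k, s] = number of k-subsets of the first items with doubled-rank sum s
    dp = np.zeros((nx + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1:, r:] += dp[:-1, :max_sum + 1 - r]
    counts = dp[nx]
    total = counts.sum()
    # doubled rank sum s corresponds to U = s/2 - nx(nx+1)/2
    s_vals = np.arange(max_sum + 1)
    u_vals = s_vals / 2.0 - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    extreme = np.abs(u_vals - mu) >= abs(u_obs - mu) - 1e-9
    return float(min(1.0, counts[extreme].sum() / total))


def mann_whitney_u(x, y, exact_limit: int = 400) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test, returning (U of x, two-sided p).

    U is computed with mid-rank tie handling.  When ``n_x * n_y`` is at most
    ``exact_limit`` the p-value is exact (full permutation distribution,
    ties included); otherwise a normal approximation with tie and continuity
    corrections is used.  Samples that are completely tied give p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if np.ptp(pooled) == 0:
        return u, 1.0
    if nx * ny <= exact_limit:
        return u, _exact_two_sided_p(x, y, u)
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    mu = nx * ny / 2.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)  # continuity correction
    return u, float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


# ---------------------------------------------------------------------------
# histograms


def signed_bin_edges(values: np.ndarray, bin_nm: float = BIN_NM) -> np.ndarray:
    """Symmetric 80-nm bin edges with one bin centred on zero."""
    values = np.asarray(values, dtype=float)
    m = float(np.abs(values).max()) if values.size else 0.0
    k = max(1, int(math.ceil((m - bin_nm / 2.0) / bin_nm + 1e-12)))
    return np.arange(-(k + 0.5) * bin_nm, (k + 0.5) * bin_nm + bin_nm / 2.0, bin_nm)


def _bin_counts(values: np.ndarray, edges: np.ndarray,
                bin_nm: float = BIN_NM) -> np.ndarray:
    """Histogram counts with mirror-symmetric edge handling.

    Values are assigned to the nearest bin centre; a value exactly on a bin
    boundary goes to the even bin index (round-half-even), which makes the
    binning of v and -v exact mirror images — important because measured
    lengths are often exact multiples of half a bin.
    """
    n_bins = len(edges) - 1
    k = n_bins // 2
    idx = np.rint(np.asarray(values, dtype=float) / bin_nm).astype(int) + k
    if idx.min() < 0 or idx.max() >= n_bins:
        raise ValueError("bin edges do not cover the data")
    return np.bincount(idx, minlength=n_bins)


def _bin_counts_2d(head: np.ndarray, tail: np.ndarray, edges: np.ndarray,
                   bin_nm: float = BIN_NM) -> np.ndarray:
    n_bins = len(edges) - 1
    k = n_bins // 2
    hi = np.rint(np.asarray(head, dtype=float) / bin_nm).astype(int) + k
    ti = np.rint(np.asarray(tail, dtype=float) / bin_nm).astype(int) + k
    return np.bincount(hi * n_bins + ti,
                       minlength=n_bins * n_bins).reshape(n_bins, n_bins)


def compare_histograms(experimental: SignedProtrusionSet,
                       reference: SignedProtrusionSet,
                       end: str, alpha: float = 0.05,
                       bin_nm: float = BIN_NM) -> HistogramComparison:
    """Binned signed distributions plus the U test against the reference."""
    if experimental.n == 0 or reference.n == 0:
        raise ValueError("both sets must be non-empty")
    if experimental.bias_corrected != reference.bias_corrected:
        raise ValueError("sets must be bias-corrected consistently")
    xv = experimental.values(end)
    yv = reference.values(end)
    edges = signed_bin_edges(np.concatenate([xv, yv]), bin_nm)
    u, p = mann_whitney_u(xv, yv)
    return HistogramComparison(
        end=end, bin_edges=edges,
        counts_experimental=_bin_counts(xv, edges, bin_nm),
        counts_reference=_bin_counts(yv, edges, bin_nm),
        median_experimental_nm=float(np.median(xv)),
        u_statistic=u, p_value=p,
        n_experimental=experimental.n, n_reference=reference.n,
        alpha=alpha,
    )


def diff_2d_histogram(experimental: SignedProtrusionSet,
                      reference: SignedProtrusionSet,
                      bin_nm: float = BIN_NM) -> Diff2DHistogram:
    """Per-bin relative-frequency difference (pp) on an 80 x 80 nm grid."""
    if experimental.bias_corrected != reference.bias_corrected:
        raise ValueError("sets must be bias-corrected consistently")
    all_vals = np.concatenate([experimental.head, experimental.tail,
                               reference.head, reference.tail])
    edges = signed_bin_edges(all_vals, bin_nm)
    fe = 100.0 * _bin_counts_2d(experimental.head, experimental.tail,
                                edges, bin_nm) / experimental.n
    fr = 100.0 * _bin_counts_2d(reference.head, reference.tail,
                                edges, bin_nm) / reference.n
    return Diff2DHistogram(head_edges=edges, tail_edges=edges,
                           freq_experimental_pct=fe, freq_reference_pct=fr,
                           diff_pp=fe - fr)


# ---------------------------------------------------------------------------
# diverging LUT


def lut_level(delta_pp) -> np.ndarray:
    """8-bit LUT level for a percentage-point difference.

    Linear map: level = round(255 * (delta + 3.45) / 6.90), clamped to
    [0, 255], so -3.45 pp -> 0 (full cyan), -0.13 -> 123 (last cyan),
    +0.14 -> 133 (first magenta) and +3.44 -> 255 (full magenta).
    """
    delta = np.asarray(delta_pp, dtype=float)
    level = np.rint(255.0 * (delta + LUT_SPAN_PP) / (2 * LUT_SPAN_PP))
    return np.clip(level, 0, 255).astype(int)


def render_lut(diff_pp: np.ndarray) -> np.ndarray:
    """RGB (float in [0,1]) rendering of a difference grid.

    Levels 0-123 run linearly cyan -> white, 124-132 are white (the near-zero
    dead band), 133-255 run white -> magenta.
    """
    level = lut_level(diff_pp)
    rgb = np.ones(level.shape + (3,))
    lo, hi = LUT_WHITE_BAND
    cyan_side = level < lo
    t = level[cyan_side] / float(lo - 1)          # 0 at full cyan, 1 at white
    rgb[cyan_side, 0] = t
    magenta_side = level > hi
    t = (level[magenta_side] - (hi + 1)) / float(255 - (hi + 1))
    rgb[magenta_side, 1] = 1.0 - t
    return rgb


# ---------------------------------------------------------------------------
# plotting


def plot_histogram_comparison(comp: HistogramComparison, ax=None):
    """1D signed histogram overlay: reference filled grey, experiment black."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centres = 0.5 * (comp.bin_edges[:-1] + comp.bin_edges[1:])
    width = comp.bin_edges[1] - comp.bin_edges[0]
    ref = 100.0 * comp.counts_reference / comp.n_reference
    exp = 100.0 * comp.counts_experimental / comp.n_experimental
    ax.bar(centres, ref, width=width, color="0.8", label="reference")
    ax.step(comp.bin_edges, np.append(exp, exp[-1]), where="post",
            color="k", label="experimental")
    ax.axvline(0, color="0.5", lw=0.5)
    ax.set_xlabel("signed protrusion (nm; red < 0 < green)")
    ax.set_ylabel("FAs (%)")
    ax.set_title(f"{comp.end}: median {comp.median_experimental_nm:.0f} nm, "
                 f"p = {comp.p_value:.3g}")
    ax.legend(frameon=False)
    return ax


def plot_diff_2d(diff: Diff2DHistogram, ax=None):
    """Cyan-white-magenta rendering of the 2D difference histogram."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rgb = render_lut(diff.diff_pp)
    extent = (diff.tail_edges[0], diff.tail_edges[-1],
              diff.head_edges[0], diff.head_edges[-1])
    ax.imshow(rgb, origin="lower", extent=extent, aspect="equal")
    ax.set_xlabel("signed tail (nm)")
    ax.set_ylabel("signed head (nm)")
    return ax
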