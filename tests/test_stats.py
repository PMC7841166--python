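import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faprofiler.profiles import ProtrusionMeasurement
from faprofiler.stats import (
    Diff2DHistogram,
    SignedProtrusionSet,
    apply_bias,
    compare_histograms,
    diff_2d_histogram,
    lut_level,
    mann_whitney_u,
    reference_bias,
    render_lut,
    signed_bin_edges,
    to_signed,
)
from faprofiler.synthetic import simulate_reference_measurements

from oracles import brute_mannwhitney


def null_set(n, seed, label=""):
    ms = simulate_reference_measurements(n, seed)
    return to_signed(ms, label=label)


class TestSignedConvention:
    def test_green_positive_red_negative_none_zero(self):
        ms = [
            ProtrusionMeasurement(1, head_channel="green", head_nm=120.0),
            ProtrusionMeasurement(2, head_channel="red", head_nm=96.6,
                                  tail_channel="red", tail_nm=40.0),
            ProtrusionMeasurement(3),
        ]
        s = to_signed(ms)
        assert list(s.head) == [120.0, -96.6, 0.0]
        assert list(s.tail) == [0.0, -40.0, 0.0]

    def test_discarded_rows_are_dropped(self):
        ms = [ProtrusionMeasurement(1, head_channel="green", head_nm=80.0),
              ProtrusionMeasurement(2, qc=("discarded",))]
        assert to_signed(ms).n == 1


class TestBias:
    def test_symmetric_null_bias_within_one_pixel(self):
        biases = reference_bias(null_set(800, seed=21))
        assert abs(biases[0]) <= 40.0 and abs(biases[1]) <= 40.0

    def test_injected_constant_shift_recovered(self):
        s = null_set(500, seed=22)
        shifted = SignedProtrusionSet(s.head + 57.0, s.tail + 57.0)
        biases = reference_bias(shifted)
        assert biases[0] == pytest.approx(57.0, abs=20.0)
        assert biases[1] == pytest.approx(57.0, abs=20.0)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            reference_bias(SignedProtrusionSet(np.array([]), np.array([])))

    def test_small_reference_warns(self):
        s = SignedProtrusionSet(np.arange(10.0), np.arange(10.0))
        with pytest.warns(UserWarning):
            reference_bias(s)

    def test_apply_bias_shifts_median_exactly(self):
        s = null_set(300, seed=23)
        out = apply_bias(s, (30.0, -10.0))
        assert np.median(out.head) == pytest.approx(np.median(s.head) - 30.0)
        assert np.median(out.tail) == pytest.approx(np.median(s.tail) + 10.0)

    def test_double_correction_rejected(self):
        s = apply_bias(null_set(50, seed=24), (0.0, 0.0))
        with pytest.raises(ValueError):
            apply_bias(s, (1.0, 1.0))

    def test_zero_bias_is_identity(self):
        s = null_set(100, seed=25)
        out = apply_bias(s, (0.0, 0.0))
        assert out.head == pytest.approx(s.head)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        u, p = mann_whitney_u(x, x)
        assert u == pytest.approx(50.0)  # n^2 / 2
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_all_tied_gives_p_one(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert p == 1.0

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=60)
    def test_exact_branch_matches_enumeration(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        # integer draws produce ties with high probability
        x = rng.integers(0, 5, nx).astype(float)
        y = rng.integers(0, 5, ny).astype(float)
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = brute_mannwhitney(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_asymptotic_branch_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(99)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 25)
        _, p_asym = mann_whitney_u(x, y, exact_limit=0)
        _, p_exact = mann_whitney_u(x, y, exact_limit=1000)
        assert p_asym == pytest.approx(p_exact, rel=0.15, abs=0.01)

    def test_scipy_agreement_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 18)
        y = rng.normal(0.8, 1, 15)
        u, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestHistograms:
    def test_bins_symmetric_with_zero_centred_bin(self):
        edges = signed_bin_edges(np.array([10.0, -250.0]))
        assert edges == pytest.approx(-edges[::-1])
        assert (-40.0 in edges) and (40.0 in edges)
        assert np.diff(edges) == pytest.approx(np.full(len(edges) - 1, 80.0))

    def test_counts_sum_to_n(self):
        exp, ref = null_set(200, 31, "exp"), null_set(300, 32, "ref")
        comp = compare_histograms(exp, ref, "head")
        assert comp.counts_experimental.sum() == exp.n
        assert comp.counts_reference.sum() == ref.n

    def test_null_vs_null_not_significant(self):
        comp = compare_histograms(null_set(400, 33), null_set(400, 34), "tail")
        assert comp.p_value > 0.05
        assert comp.reported_median_nm is None

    def test_injected_shift_detected_with_median_within_one_bin(self):
        ref = null_set(500, 35)
        exp = SignedProtrusionSet(ref.head.copy(), ref.tail + 120.0)
        comp = compare_histograms(exp, ref, "tail")
        assert comp.significant
        assert comp.reported_median_nm == pytest.approx(120.0, abs=80.0)

    def test_inconsistent_bias_state_rejected(self):
        a, b = null_set(60, 36), null_set(60, 37)
        with pytest.raises(ValueError):
            compare_histograms(apply_bias(a, (0, 0)), b, "head")


class TestDiff2D:
    def test_identical_sets_give_zero_grid(self):
        s = null_set(200, 41)
        d = diff_2d_histogram(s, s)
        assert d.diff_pp == pytest.approx(np.zeros_like(d.diff_pp))

    def test_frequencies_sum_to_100_and_diff_to_zero(self):
        d = diff_2d_histogram(null_set(150, 42), null_set(250, 43))
        assert d.freq_experimental_pct.sum() == pytest.approx(100.0)
        assert d.freq_reference_pct.sum() == pytest.approx(100.0)
        assert d.diff_pp.sum() == pytest.approx(0.0, abs=1e-9)

    def test_head_red_tail_green_population_fills_expected_quadrant(self):
        rng = np.random.default_rng(44)
        n = 400
        exp = SignedProtrusionSet(-rng.uniform(80, 300, n),   # red heads
                                  rng.uniform(80, 300, n))    # green tails
        ref = SignedProtrusionSet(np.zeros(n), np.zeros(n))
        d = diff_2d_histogram(exp, ref)
        hc = 0.5 * (d.head_edges[:-1] + d.head_edges[1:])
        tc = 0.5 * (d.tail_edges[:-1] + d.tail_edges[1:])
        quadrant = d.diff_pp[np.ix_(hc < 0, tc > 0)]
        assert quadrant.sum() == pytest.approx(100.0, abs=1.0)


class TestLut:
    @pytest.mark.parametrize("delta,level", [
        (-3.45, 0), (-0.13, 123), (0.14, 133), (3.44, 255), (0.0, 128)])
    def test_printed_anchor_points(self, delta, level):
        assert lut_level(delta) == level

    def test_clamping_beyond_range(self):
        assert lut_level(-10.0) == 0 and lut_level(10.0) == 255

    def test_dead_band_renders_white(self):
        grid = np.array([[-0.10, 0.0, 0.11]])
        rgb = render_lut(grid)
        assert rgb == pytest.approx(np.ones((1, 3, 3)))

    def test_extremes_render_cyan_and_magenta(self):
        rgb = render_lut(np.array([[-3.45, 3.45]]))
        assert rgb[0, 0] == pytest.approx([0.0, 1.0, 1.0])  # cyan
        assert rgb[0, 1] == pytest.approx([1.0, 0.0, 1.0])  # magenta

    def test_monotone_smooth_ramp_on_each_side(self):
        deltas = np.linspace(-3.45, 3.45, 201)
        rgb = render_lut(deltas[None, :])[0]
        assert (np.diff(rgb[:, 0]) >= 0).all()   # red rises cyan -> magenta
        assert (np.diff(rgb[:, 1]) <= 0).all()   # green falls white -> magenta


class TestColourSwapAntisymmetry:
    def test_swapping_channels_negates_values_mirrors_histograms(self):
        exp, ref = null_set(200, 51), null_set(300, 52)
        neg_exp = SignedProtrusionSet(-exp.head, -exp.tail)
        neg_ref = SignedProtrusionSet(-ref.head, -ref.tail)
        c1 = compare_histograms(exp, ref, "head")
        c2 = compare_histograms(neg_exp, neg_ref, "head")
        assert c2.median_experimental_nm == pytest.approx(-c1.median_experimental_nm)
        assert c2.p_value == pytest.approx(c1.p_value)
        assert (c2.counts_experimental[::-1] == c1.counts_experimental).all()
        d1 = diff_2d_histogram(exp, ref)
        d2 = diff_2d_histogram(neg_exp, neg_ref)
        assert d2.diff_pp[::-1, ::-1] == pytest.approx(d1.diff_pp)
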