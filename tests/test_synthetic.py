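import numpy as np
import pytest

from faprofiler.core import GREEN, NONE, RED
from faprofiler.profiles import find_main_stretch, mark_positive, extract_profiles
from faprofiler.synthetic import (
    FASpec,
    NoiseSpec,
    SceneSpec,
    add_noise,
    displace_polygon,
    random_scene,
    render_scene,
    render_timelapse_masks,
    simulate_reference_measurements,
)

NO_NOISE = NoiseSpec(0, 0, 0, 0, 0)


def single_fa_scene(**kwargs):
    defaults = dict(centre=(60.0, 80.0), angle_deg=0.0, core_length=30,
                    width=9, head_sign=1)
    defaults.update(kwargs)
    return SceneSpec(image_shape=(120, 160), fa_specs=[FASpec(**defaults)],
                     noise=NO_NOISE)


class TestFASpecInvariants:
    def test_extra_without_channel_rejected(self):
        with pytest.raises(ValueError):
            FASpec(centre=(0, 0), angle_deg=0, core_length=10, width=5,
                   head_channel=NONE, head_extra=3)

    def test_channel_without_extra_rejected(self):
        with pytest.raises(ValueError):
            FASpec(centre=(0, 0), angle_deg=0, core_length=10, width=5,
                   head_channel=GREEN, head_extra=0)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            FASpec(centre=(0, 0), angle_deg=0, core_length=0.5, width=5)


class TestRenderScene:
    def test_no_protrusions_channels_bit_identical(self):
        images, _ = render_scene(single_fa_scene())
        assert (images.red == images.green).all()

    def test_on_axis_extension_lengthens_green_support_by_exactly_extra(self):
        spec = single_fa_scene(tail_channel=GREEN, tail_extra=3)
        images, _ = render_scene(spec)
        row = 60
        eps = 1e-3
        red_cols = np.flatnonzero(images.red[row] - 100.0 > eps)
        green_cols = np.flatnonzero(images.green[row] - 100.0 > eps)
        assert green_cols.max() == red_cols.max()
        assert red_cols.min() - green_cols.min() == 3

    def test_ground_truth_nm_uses_step_rule(self):
        spec = single_fa_scene(head_channel=RED, head_extra=4)
        _, truth = render_scene(spec)
        assert truth[0].head_nm == pytest.approx(160.0)  # 4 straight steps
        diag = single_fa_scene(angle_deg=45.0, head_channel=RED, head_extra=4)
        _, truth = render_scene(diag)
        assert truth[0].head_nm == pytest.approx(160.0)  # step rule: 40 nm per axis px at 45 deg

    def test_fa_outside_image_raises_with_id(self):
        spec = single_fa_scene(centre=(5.0, 5.0))
        with pytest.raises(ValueError, match="FA 1"):
            render_scene(spec)

    def test_channel_swap_antisymmetry_of_ground_truth(self):
        spec = single_fa_scene(head_channel=RED, head_extra=5,
                               tail_channel=GREEN, tail_extra=3)
        _, truth = render_scene(spec)
        swapped = SceneSpec(image_shape=spec.image_shape,
                            fa_specs=[spec.fa_specs[0].swapped()],
                            noise=NO_NOISE)
        _, truth_sw = render_scene(swapped)
        signed = lambda ch, nm: nm if ch == GREEN else (-nm if ch == RED else 0)
        assert signed(truth_sw[0].head_channel, truth_sw[0].head_nm) == \
            -signed(truth[0].head_channel, truth[0].head_nm)
        assert signed(truth_sw[0].tail_channel, truth_sw[0].tail_nm) == \
            -signed(truth[0].tail_channel, truth[0].tail_nm)

    def test_rotating_specs_by_90_preserves_truth_nm(self):
        spec = single_fa_scene(angle_deg=30.0, head_channel=RED, head_extra=5)
        _, truth = render_scene(spec)
        rot = single_fa_scene(angle_deg=120.0, head_channel=RED, head_extra=5)
        _, truth_rot = render_scene(rot)
        assert truth_rot[0].head_nm == pytest.approx(truth[0].head_nm, abs=60)


class TestAddNoise:
    def test_all_zero_noise_is_identity(self):
        images, _ = render_scene(single_fa_scene())
        out = add_noise(images, NO_NOISE, seed=3)
        assert (out.red == images.red).all() and (out.green == images.green).all()

    def test_fixed_seed_reproducible(self):
        images, _ = render_scene(single_fa_scene())
        a = add_noise(images, NoiseSpec(), seed=5)
        b = add_noise(images, NoiseSpec(), seed=5)
        assert (a.red == b.red).all() and (a.green == b.green).all()
        c = add_noise(images, NoiseSpec(), seed=6)
        assert not (a.red == c.red).all()

    def test_output_clipped_at_zero(self):
        images, _ = render_scene(single_fa_scene())
        out = add_noise(images, NoiseSpec(gaussian_sd=300), seed=1)
        assert out.red.min() >= 0

    def test_speckle_holes_do_not_break_main_stretch(self):
        # holes <= 4 px inside the plateau are bridged by the gap rule
        from faprofiler.core import AxisPath

        spec = single_fa_scene(core_length=36)
        images, _ = render_scene(spec)
        noisy = add_noise(images, NoiseSpec(0, 0, speckle_hole_rate=2,
                                            speckle_hole_size=3,
                                            speckle_hole_depth=0.8), seed=9)
        path = AxisPath([(60, c) for c in range(55, 106)])
        clean = extract_profiles(path, images)
        noisy_prof = extract_profiles(path, noisy)
        iv_clean = find_main_stretch(*mark_positive(clean)[:2])
        iv_noisy = find_main_stretch(*mark_positive(noisy_prof)[:2])
        assert iv_noisy == iv_clean


class TestTimelapseMasks:
    def _spec(self):
        poly = np.array([[30.0, 30.0], [30.0, 160.0], [90.0, 160.0],
                         [90.0, 30.0]])
        return SceneSpec(image_shape=(120, 200), fa_specs=[],
                         cell_polygon=poly, noise=NO_NOISE)

    def test_zero_program_gives_identical_masks(self):
        spec = self._spec()
        m0, m1, _ = render_timelapse_masks(spec, [0, 0, 0, 0])
        assert (m0 == m1).all()

    def test_outward_displacement_grows_the_mask_on_that_side(self):
        spec = self._spec()
        m0, m1, _ = render_timelapse_masks(spec, [0, 0, 400.0, 0])
        # edge 2 runs row 90 between cols 160 and 30: bottom edge moves out
        assert m1.sum() > m0.sum()
        grown = m1 & ~m0
        assert grown.any() and np.median(np.argwhere(grown)[:, 0]) > 85

    def test_programmed_segment_classes_propagate_to_fas(self):
        poly = np.array([[30.0, 30.0], [30.0, 160.0], [90.0, 160.0],
                         [90.0, 30.0]])
        fas = [FASpec(centre=(45.0, 95.0), angle_deg=90.0, core_length=20,
                      width=8, head_sign=1),
               FASpec(centre=(75.0, 95.0), angle_deg=90.0, core_length=20,
                      width=8, head_sign=-1)]
        spec = SceneSpec(image_shape=(120, 200), fa_specs=fas,
                         cell_polygon=poly, noise=NO_NOISE)
        _, _, truth = render_timelapse_masks(spec, [0, 0, 400.0, -400.0])
        assert truth[0].edge_class == "static"      # nearest edge 0 (row 30)
        assert truth[1].edge_class == "protruding"  # nearest edge 2 (row 90)

    def test_self_intersecting_displacement_raises(self):
        poly = np.array([[50.0, 50.0], [50.0, 60.0], [60.0, 60.0], [60.0, 50.0]])
        spec = SceneSpec(image_shape=(120, 200), fa_specs=[],
                         cell_polygon=poly, noise=NO_NOISE)
        with pytest.raises(ValueError):
            render_timelapse_masks(spec, [-2000.0, 0, 0, 0])


class TestRandomScene:
    def test_deterministic_for_fixed_seed(self):
        a = random_scene(7, n_fas=10, image_shape=(512, 512))
        b = random_scene(7, n_fas=10, image_shape=(512, 512))
        ia, _ = render_scene(a)
        ib, _ = render_scene(b)
        assert (ia.red == ib.red).all() and (ia.green == ib.green).all()

    def test_heads_point_toward_cell_frame(self):
        spec = random_scene(8, n_fas=12, image_shape=(640, 640),
                            head_channel=RED, tail_channel=GREEN)
        _, truth = render_scene(spec)
        poly = spec.cell_polygon
        frame = (poly[:, 0].min(), poly[:, 1].min(),
                 poly[:, 0].max(), poly[:, 1].max())

        def frame_dist(p):
            return min(p[0] - frame[0], frame[2] - p[0],
                       p[1] - frame[1], frame[3] - p[1])

        for rec in truth:
            assert frame_dist(rec.head_end) < frame_dist(rec.tail_end)

    def test_requested_population_size_reached(self):
        spec = random_scene(3, n_fas=20, image_shape=(1024, 1024))
        assert len(spec.fa_specs) == 20


class TestReferenceSimulator:
    def test_deterministic_and_mostly_zero_protrusions(self):
        a = simulate_reference_measurements(50, seed=13)
        b = simulate_reference_measurements(50, seed=13)
        assert [(m.head_nm, m.tail_nm) for m in a] == \
            [(m.head_nm, m.tail_nm) for m in b]
        kept = [m for m in a if not m.discarded]
        assert len(kept) >= 45
        zeroish = sum(m.head_nm <= 2 * 57 and m.tail_nm <= 2 * 57 for m in kept)
        assert zeroish / len(kept) >= 0.9
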