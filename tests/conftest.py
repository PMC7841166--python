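from __future__ import annotations

import numpy as np
import pytest

from faprofiler.axis import CellFrame, cell_frame_from_images
from faprofiler.profiles import measure_image
from faprofiler.synthetic import NoiseSpec, add_noise, random_scene, render_scene


def scene_frame(spec) -> CellFrame:
    """The orientation rectangle: bounding box of the scene's cell polygon."""
    poly = spec.cell_polygon
    return CellFrame(float(poly[:, 0].min()), float(poly[:, 1].min()),
                     float(poly[:, 0].max()), float(poly[:, 1].max()))


def run_pipeline(spec, noisy: bool = False, seed: int = 0):
    """Render a scene, optionally add its noise, and measure every FA."""
    images, truth = render_scene(spec)
    if noisy:
        images = add_noise(images, spec.noise, seed)
    measurements = measure_image(images, cell_frame=scene_frame(spec))
    return images, truth, measurements


def match_to_truth(truth, measurements, max_dist_px: float = 10.0):
    """Greedy one-to-one pairing of ground-truth FAs with measured centroids."""
    usable = [m for m in measurements if not m.discarded and m.centroid]
    candidates = []
    for rec in truth:
        for m in usable:
            d = np.hypot(m.centroid[0] - rec.centre[0],
                         m.centroid[1] - rec.centre[1])
            if d <= max_dist_px:
                candidates.append((d, rec.fa_id, id(m), rec, m))
    pairs, used_truth, used_m = [], set(), set()
    for d, rid, mid, rec, m in sorted(candidates, key=lambda c: c[0]):
        if rid in used_truth or mid in used_m:
            continue
        used_truth.add(rid)
        used_m.add(mid)
        pairs.append((rec, m))
    return pairs


@pytest.fixture(scope="session")
def noiseless_scene():
    """Red-head / green-tail scene rendered without noise, plus measurements."""
    spec = random_scene(seed=11, n_fas=15, image_shape=(768, 768),
                        head_channel="red", tail_channel="green",
                        noise=NoiseSpec(0, 0, 0, 0, 0))
    images, truth, measurements = run_pipeline(spec)
    return spec, images, truth, measurements
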