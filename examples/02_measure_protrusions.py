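"""Measure head/tail protrusions on a rendered scene and compare to truth.

Runs the full measurement chain (DoG + Otsu segmentation, moment + ridge
axis fit, 30% box-mean termination, head orientation, 40% positivity,
gap-tolerant main stretch) and prints measured vs true lengths per FA.
"""

import numpy as np

from faprofiler import add_noise, measure_image, random_scene, render_scene
from faprofiler.axis import CellFrame

spec = random_scene(seed=5, n_fas=12, image_shape=(768, 768),
                    head_channel="red", tail_channel="green")
images, truth = render_scene(spec)
noisy = add_noise(images, spec.noise, seed=5)
poly = spec.cell_polygon
frame = CellFrame(poly[:, 0].min(), poly[:, 1].min(),
                  poly[:, 0].max(), poly[:, 1].max())
measurements = measure_image(noisy, cell_frame=frame)

print(f"{'fa':>3} {'head meas':>10} {'head true':>10} "
      f"{'tail meas':>10} {'tail true':>10}")
for m in measurements:
    if m.discarded:
        continue
    rec = min(truth, key=lambda t: np.hypot(t.centre[0] - m.centroid[0],
                                            t.centre[1] - m.centroid[1]))
    print(f"{m.fa_id:>3} {m.head_nm:>10.0f} {rec.head_nm:>10.0f} "
          f"{m.tail_nm:>10.0f} {rec.tail_nm:>10.0f}")
print("\nLengths are nm along the FA axis (40 nm straight steps, "
      "~57 nm diagonal steps); agreement within one 80 nm bin is the "
      "pipeline's working accuracy.")
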