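"""Three-point circumradius curvature on circles of known radius.

Curvature at a centerline point A is 1/R_A, with R_A = a / (2 sin A) the
circumradius of the triangle formed with points B and C taken 25 path
pixels either side of A. On a circle of radius R every triple lies on the
circle, so the measured curvature must be 1/R.
"""

import numpy as np

import retinavasc as rv

for radius in (50, 100, 200, 400):
    size = int(2 * radius + 60)
    ph = rv.generate(rv.PhantomSpec(kind="arc", size=size, radius=radius,
                                    width=9, theta_range=(20, 160)))
    _, graph = rv.build_graph(ph.vessel_mask)
    samples = rv.sample_curvatures(graph)
    mean_c = np.mean([s.curvature for s in samples])
    print(f"R = {radius:3d} px: curvature {mean_c:.5f} px^-1 "
          f"(true 1/R = {1/radius:.5f}; x1000 = {1000*mean_c:.2f}; "
          f"{len(samples)} samples)")
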