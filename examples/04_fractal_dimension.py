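"""Box-counting fractal dimension on sets of known dimension.

The dimension is the least-squares slope of log N(eps) against log(1/eps),
where N(eps) counts the eps-sized grid boxes touching the mask. A line has
dimension 1, a filled disk 2, and the Sierpinski carpet log 8 / log 3.
"""

import numpy as np

import retinavasc as rv
from retinavasc.phantoms import disc_mask

line = np.zeros((1024, 1024), bool)
line[512, :] = True
print(f"straight line      : {rv.fractal_dimension(line):.4f}  (expected 1)")

disk = disc_mask(640, (320, 320), 600)
print(f"filled disk        : {rv.fractal_dimension(disk):.4f}  (expected 2)")

carpet = rv.generate(rv.PhantomSpec(kind="sierpinski", size=729, iterations=5))
print(f"Sierpinski carpet  : {rv.fractal_dimension(carpet.vessel_mask):.4f}  "
      f"(expected log8/log3 = {np.log(8)/np.log(3):.4f})")
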