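"""Optic disc boundary by polar edge tracing + minimum enclosing circle.

A bright disk of known radius is traced from a deliberately off-centre
seed: the image is unwrapped to polar coordinates, the innermost strong
bright-to-dark radial transition marks the rim at each angle, and the
minimum enclosing circle of the rim points gives centre and papillary
diameter (PD). The 1.5 mm PD reference then calibrates pixels to mm.
"""

import numpy as np

from retinavasc.optic_disc import segment_disc
from retinavasc.phantoms import disc_mask

true_radius = 100
img = np.where(disc_mask(768, (384, 384), 2 * true_radius), 200.0, 50.0)

disc = segment_disc(img, seed=(404.0, 384.0))  # seed 20 px off-centre
print(f"true diameter      : {2 * true_radius} px")
print(f"measured diameter  : {disc.diameter_px:.2f} px")
print(f"measured centre    : ({disc.center[0]:.2f}, {disc.center[1]:.2f})  (true 384, 384)")
print(f"mm per pixel       : {disc.mm_per_px:.6f}  (= 1.5 / {disc.diameter_px:.2f})")
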