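"""Pixelwise segmentation scoring: Acc, sensitivity, specificity, IoU, DICE.

Scores a deliberately imperfect prediction against ground truth and shows
the single-confusion-matrix identity DICE = 2 IoU / (1 + IoU).
"""

import numpy as np

import retinavasc as rv
from retinavasc.phantoms import bar_mask

truth = bar_mask(300, (150, 150), 200, 9, 0)
pred = bar_mask(300, (150, 152), 200, 9, 0)  # shifted 2 px: partial overlap

scores = rv.evaluate_segmentation(pred, truth)
for name, value in scores.as_dict().items():
    print(f"{name:12s}: {value:.4f}")
print(f"2*IoU/(1+IoU): {2 * scores.iou / (1 + scores.iou):.4f}  (equals DICE)")
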