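"""Evaluate a predicted mask against ground truth, including boundary IoU.

Shows how MBIOU (mean IoU restricted to a band around class boundaries)
exposes boundary errors that the area-based MIOU barely notices.
"""

from omgeye import EyeGeometry, argmax_mask, corrupt_prediction, generate_eye, mbiou, segmentation_metrics
from omgeye.experiments import d_from_fraction

gt, _ = generate_eye(EyeGeometry())
d = d_from_fraction(gt.height, gt.width, 0.02)

for jitter in (0, 1, 3):
    pred = argmax_mask(corrupt_prediction(gt, jitter_px=jitter, softness=0.0, seed=1))
    report = segmentation_metrics(pred, gt)
    b = mbiou(pred, gt, d)
    print(
        f"jitter {jitter}px:  MIOU {report.means['miou']:.3f}  "
        f"MDice {report.means['mdice']:.3f}  MBIOU {b:.3f}"
    )
print()
print("MBIOU drops much faster than MIOU as boundary jitter grows: the band")
print(f"(d={d}px around class boundaries) contains exactly the pixels the")
print("jitter corrupts, while most of each region's area stays correct.")
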