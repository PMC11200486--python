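"""Hybrid-loss stability: why the boundary loss needs a global anchor.

Trains the same tiny pixel classifier on the same synthetic eyes under two
hybrid-loss modes — G+B (cross entropy + scheduled boundary term) and L+B
(Dice + scheduled boundary term) — and compares loss-curve oscillation and
held-out segmentation quality.  Local ratio losses amplify mini-batch noise
and lack per-pixel anchoring, so L+B oscillates more and generalizes worse.
"""

from omgeye import stability_demo

results = stability_demo(("G+B", "L+B", "G+L+B"), epochs=24, seed=0)
print(f"{'mode':8s} {'oscillation':>12s} {'holdout MIOU':>13s}")
for mode, res in results.items():
    print(f"{mode:8s} {res.oscillation:12.3f} {res.holdout_miou:13.3f}")
print()
print("The oscillation index is the mean epoch-to-epoch loss change divided")
print("by the curve's range (0 = perfectly smooth).  The L+B curve is the")
print("least stable and its held-out MIOU trails the modes with a global")
print("term — keep a global loss in the mix when adding a boundary term.")
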