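"""Ocular indicators from an eye mask: eyelid distance, clock point, sclera.

Generates a ptotic eye (small aperture: the upper lid droops over the
iris) and an eye with impaired leftward gaze (the iris barely moves while
the subject looks left), then prints the three indicators next to the
generator's analytic ground truth.
"""

from omgeye import EyeGeometry, compute_indicators, generate_eye

print("--- ptotic eye (aperture 24 px, iris radius 32 px) ---")
geom = EyeGeometry(aperture=24.0)
mask, truth = generate_eye(geom)
ind = compute_indicators(mask)
print(f"eyelid distance: {ind.eyelid_distance_px} px (truth {truth.eyelid_distance_px} px)")
print(f"clock point:     {ind.clock_point} -> grade {ind.clock_grade} "
      f"(truth {truth.clock_point}, grade {truth.clock_grade})")

print()
print("--- impaired leftward gaze (iris stays near fissure center) ---")
geom = EyeGeometry(gaze_offset=-4.0)
mask, truth = generate_eye(geom, gaze="left")
ind = compute_indicators(mask, gaze="left")
print(f"gaze-side sclera: {ind.sclera_gaze_px} px of {ind.eye_area_px} px eye area")
print(f"sclera proportion: {ind.sclera_proportion:.4f} (truth {truth.sclera_proportion:.4f})")
print()
print("A proportion above 0.03 means the eye could not rotate far enough to")
print("bury the gaze-side sclera — the screening rule's positive signal.")
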