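"""Measure whole-plant leaf area from an image with in-frame calibration.

Renders a toy top-view scene (two leaf blobs totalling 3.2 cm² plus the
1 cm² black reference square), then measures the area as the ratio of green
pixels to reference-square pixels.
"""

from phenokit import measure_area, render_leaf_scene

scene = render_leaf_scene([2.5, 0.7], px_per_cm=40, seed=0)
result = measure_area(scene.image)

print(f"ground-truth area : {scene.true_area_cm2:.4f} cm2")
print(f"measured area     : {result.area_cm2:.4f} cm2")
print(f"green pixels      : {int(result.green_mask.sum())}")
print(f"reference pixels  : {result.px_per_cm2}  (= 1 cm2)")

# The measured area is green_px / ref_px: with the reference square lying on
# the leaf plane the ratio is independent of camera distance and resolution.
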