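"""Segment a noise-free synthetic lung slice and score it against ground truth.

Generates a 512x512 phantom with a 3 cm disk tumor (0.7 mm/pixel), runs the
fully automatic pipeline (prior localization -> 7-seed ensemble growing ->
credibility screen), and prints the per-seed audit trail plus Dice/Jaccard.
"""

from priorgrow import PhantomSpec, dice, generate_phantom, jaccard_distance, segment_tumor

phantom = generate_phantom(PhantomSpec(tumor_diameter_cm=3.0, noise_sd=0.0, rng_seed=0))
result = segment_tumor(phantom.slice)

print(f"candidate contour: {result.contour.area_cm2:.2f} cm^2, "
      f"max size {result.contour.max_size_cm:.2f} cm")
print(f"seeds p1..p7: {result.seed_set.seeds}")
for i, region in enumerate(result.regions, start=1):
    print(f"  p{i}: tolerance {region.threshold:5.1f} gray levels, "
          f"area {region.area_px:5d} px, credible={region.credible}")

d = dice(phantom.truth_mask, result.combined_mask)
jd = jaccard_distance(phantom.truth_mask, result.combined_mask)
print(f"combined mask: {result.combined_area_px} px "
      f"(truth {int(phantom.truth_mask.sum())} px)")
print(f"dice={d:.4f} jaccard_distance={jd:.4f}")
print("A Dice of 1.0 means the grown ensemble recovered the tumor pixel-exactly;"
      " the Jaccard distance is the complementary disagreement fraction.")
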