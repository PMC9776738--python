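"""Batch evaluation over a varied phantom suite.

Twenty phantoms with tumor diameters drawn from 2.2-4.8 cm (inside the
TNM-derived 2-5 cm prior window), disk/ellipse/concave shapes, and additive
Gaussian noise up to 10 gray levels.  Prints per-case and summary Dice.
"""

import numpy as np

from priorgrow import dice, generate_suite, segment_tumor

suite = generate_suite(20, seed=2024)
scores = []
for i, ph in enumerate(suite):
    res = segment_tumor(ph.slice)
    d = dice(ph.truth_mask, res.combined_mask)
    scores.append(d)
    print(f"case {i:2d}: {ph.spec.tumor_shape:16s} "
          f"{ph.spec.tumor_diameter_cm:.2f} cm, noise sd {ph.spec.noise_sd:4.1f} "
          f"-> dice {d:.4f}, credible {sum(r.credible for r in res.regions)}/7")

print(f"\nmean dice {np.mean(scores):.4f} +- {np.std(scores):.4f} over {len(scores)} phantoms")
print("The mean Dice summarizes how closely the automatic segmentation matches"
      " the known tumor masks across sizes, shapes and noise levels.")
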