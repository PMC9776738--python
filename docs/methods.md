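# Methods

## Model and assumptions

`priorgrow` segments one lung tumor per 2-D CT slice under three
assumptions: (i) the tumor is a roughly blob-shaped region brighter than
the surrounding lung parenchyma; (ii) its physical size lies in the
TNM-derived window used for localization (max size in (2, 5] cm, enclosed
area in (1, 6.25π] cm²); (iii) the pixel spacing is known, because every
prior is stated in centimetres and converted via cm = px · spacing_mm / 10.
DICOM spacing is read from PixelSpacing (anisotropic spacings are averaged
with a warning); raster formats require an explicit spacing. Intensities
are used as stored — the growth tolerance is relative (a fraction of an
intensity range), so no HU calibration is needed.

The method is deterministic end to end: identical input bytes and
parameters give bit-identical masks and reports.

## Pipeline stages and numerical choices

**Contrast stretch (localization only).** A linear percentile stretch with
defaults (0.02, 0.98): values at/below the 2nd percentile map to 0,
at/above the 98th to the dtype maximum. The stretch feeds only the Otsu
binarization and contour screening; region growing always reads the
original intensities, so the stretch cannot bias the grown boundary. A
constant image is passed through unchanged with a warning.

**Otsu binarization.** `skimage.filters.threshold_otsu`; foreground is
`pixel > threshold`. The tests pin the returned threshold to an exhaustive
between-class-variance scan over all candidate gray levels. Constant
images raise a degenerate-histogram error.

**Contours and measurements.** Components are 8-connected; each component
is hole-filled and its outer boundary traced (marching squares), so
`area_px` is the enclosed pixel count. "Maximum size" is the maximum Feret
(caliper) diameter, computed over the *corners* of the boundary pixels'
unit squares via a convex hull: a 30×40 px rectangle therefore measures a
50 px diagonal, matching the physical outline of the pixel area rather
than the center-to-center distance. A single-pixel contour reports size 0.
The Feret reading of "maximum size" is consistent with the area cap: the
6.25π cm² bound is exactly the area of the circle whose diameter is the
5 cm size bound.

**Prior filter.** Both conditions are strict at the low end and inclusive
at the high end. The filter is pure (subsequence, idempotent). When
several contours survive, each is segmented independently and all are
reported, ordered by decreasing area; the largest is the primary. When
none survives, localization fails loudly with a hint to supply a manual
seed — the documented fallback for tumors outside the size window. Manual
mode grows a single seeded region with the whole-image tolerance; without
a target contour there is no sector geometry or restriction circle, so
credibility is only checked against a user-predicted size if one is given.

**Centroid and seed expansion.** The centroid uses filled-region pixel
moments (mean pixel coordinate), rounded to the nearest pixel for seeding;
if rounding lands outside a concave region, p1 snaps to the nearest region
pixel. Sector dividing lines default to 0°/60°/120° measured from the
image row axis (configurable via `sector_offset_deg`); membership uses
half-open angle intervals [θ, θ+60°), making the six sectors an exact
partition. Out-of-region sector centroids fall back to the midpoint of the
shortest centroid-to-boundary segment *within that sector* (both readings
of "the contour of the area" coincide for convex regions); a midpoint
still outside snaps to the nearest region pixel and is flagged. Duplicate
seeds are nudged to the nearest unused region pixel so the seven seeds are
distinct; regions under seven pixels degenerate to p1 repeated, flagged.

**Growing.** Similarity is measured against the seed's own intensity (the
fixed base value), not a running mean; a pixel joins iff
|I − base| ≤ tolerance and it is 8-connected (configurable to 4) to the
seed through joining pixels. This makes the grown region exactly the
seed's connected component of the pointwise predicate, which is how it is
computed (`scipy.ndimage.label`); the tests verify equality with an
explicit fixpoint flood fill.

**Threshold update.** The initial tolerance is `threshold_frac` (default
0.2) × (max − min) of the whole image. For seed p_k (k ≥ 2) the reference
area is the disk of radius L centered on the previous seed, with L = max
distance from that seed to its grown boundary pixels (pixel centers)
+ `margin_px` (default 6 px — the only spatial unit in play at this step).
"Gray threshold" is read as the intensity *range* of the reference area;
the chain runs p1→p2→…→p7 through each previous seed (`anchor_p1=True`
re-centers every circle on p1 — the other defensible reading).

**Growth restriction.** Predicted-size mode compares the region's Feret
diameter in cm against the prediction; circle mode compares the region's
pixel area against π·r², with r the largest distance from C to the target
contour's boundary, measured to the boundary pixels' square corners. The
corner measurement makes the geometric guarantee exact on the pixel grid:
a region can never out-measure its own circumscribed circle, so a grown
region equal to the candidate itself is always credible. An abnormal
region is discarded entirely (binary accept/reject); if all seven fail,
the run raises an explicit all-abnormal error with per-seed diagnostics
rather than returning anything.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold_frac` | 0.2 | growth tolerance as a fraction of the reference intensity range |
| `margin_px` | 6 px | additive slack on the threshold-update circle radius |
| `connectivity` | 8 | neighbor stencil of growth and component labeling |
| `predicted_max_size_cm` | none | switches credibility to predicted-size mode |
| size window | (2, 5] cm | localization condition a (TNM T1c–T2b cut-points) |
| area window | (1, 6.25π] cm² | localization condition b (vessel floor / 5 cm-circle cap) |
| stretch percentiles | (0.02, 0.98) | contrast clip points for localization |

## The phantom generator

Phantoms emulate exactly the features the pipeline interacts with: dark
exterior (0), soft-tissue body ellipse (120), two lung fields, a tumor
blob (200) of controlled physical diameter — disk, ellipse (diameter = its
major axis), or concave crescent (disk minus an off-center bite; its Feret
diameter remains the base-disk diameter) — thin (3 px) bright vessel-like
segments in the contralateral lung, and additive Gaussian noise, clipped
and quantized to 8 bits. The ground truth is the pre-noise tumor mask.
Vessel segments are deliberately sized so their maximum size can fall
inside the 2–5 cm window while their area stays below the 1 cm² floor —
the scenario that floor exists to reject — and drawn in disjoint row bands
so they cannot merge into a tumor-sized blob.

Lung fields default to intensity 35, near the exterior: parenchyma is
mostly air, and a dark lung is what lets the whole-image Otsu split put
the lungs with the background so that the tumor binarizes as an isolated
island. (With lungs at the midpoint of the body intensity, the trimodal
histogram makes Otsu's two-class split nearly degenerate and localization
brittle; brighter parenchyma, e.g. 60, still works on clean phantoms and
is covered by a test.) Tumor-to-lung contrast (165 gray levels) is well
above the default tolerance (~40–51), which is what makes clean-phantom
recovery essentially pixel-exact.

What the phantoms do *not* emulate — and hence what passing tests do not
show about clinical data: textured parenchyma and partial-volume tumor
boundaries, tumors abutting the pleural wall or mediastinum (where growth
can leak into tissue of similar intensity), juxtavascular lesions touching
vessels of tumor-like intensity, and expert-annotation variability.
Published per-case overlap on real CT slices with expert references
(Dice ≈ 0.9 class) is therefore not reproduced here; the phantom suite
instead verifies the mechanism: exact recovery when the model assumptions
hold, correct rejection when the priors are violated, and no
over-segmentation past the restriction circle.

## Problem sizes used in tests and the acceptance script

Oracle checks run on 32×32–48×48 random images (100 flood-fill cases, 50
Otsu histograms, 200 metric pairs); pipeline checks use full 512×512
phantoms — one clean disk case plus a 20-phantom suite (diameters sampled
uniformly in 2.2–4.8 cm, shapes cycling disk/ellipse/crescent, noise sd
uniform in [0, 10]). These sizes exercise every code path while keeping a
full run in the seconds-to-minutes range.

## Known limitations

Single-slice 2-D only (no volume propagation); one size-prior window (no
per-patient tuning beyond `predicted_max_size_cm`); multiple surviving
candidates are all reported but not ranked beyond area; the credibility
check is binary — a leaking region is dropped, never trimmed; localization
depends on the tumor binarizing as its own component, so juxtapleural
tumors fused to the chest wall in the binary image will not be found
automatically (use a manual seed).
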