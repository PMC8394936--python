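# Methods

## The analysis problem

A TEM micrograph of respiratory epithelium at fixed magnification shows up
to ~100 ciliary cross-sections: dark membrane rings enclosing the "9+2"
axoneme (nine peripheral microtubule doublets, one central pair).  The
package answers three questions per image: *where* are the cilia, *which*
of three classes does each belong to (normal / primary defect / secondary
defect), and *how well aligned* are the central-pair axes across the
ciliary border.  Primary defects here are the ones recognisable at this
magnification — central-complex defects, microtubular disorganization,
missing peripheral doublets; dynein-arm assessment needs higher
magnification and is out of scope.  Secondary defects are compound cilia,
swollen membranes, vesicle formation, extra microtubules and free
axonemes.

## Synthetic scenes as the study substrate

All quantitative claims in the test suite and the acceptance script are
made on images from the bundled generator, which fixes the pixel scale of
the whole toolchain: a normal cilium has an outer membrane diameter of
110 px, so one cilium fits the 150×150 px angle-measurement patch, and no
rendered membrane exceeds 150 px (compound 140 px, swollen 130 px).
Structures are dark on a bright background, as on TEM prints: background
grey 200, axoneme interior 178, membrane 110, microtubules 40 — the gap
between the tubule and membrane levels means a single threshold separates
the 11 tubule blobs of a normal cilium, which several tests exploit.
Geometry: doublet ring at 0.68 R with ±3° angular and ±1 px radial jitter,
central tubules at ±0.20 R along the axis (exactly, so the ground-truth
angle is recoverable to machine precision from the blob centres), doublet
radius 4.5 px, central radius 4 px.  The image is blurred with a Gaussian
(σ = 1.5 px) and additive Gaussian noise (SD 8; a Poisson term is
deliberately omitted) is applied; every scene is a pure function of its
parameters and seed, bit for bit.  Placement is rejection sampling with a
minimum centre separation of one outer diameter + 10 px = 120 px, so
non-compound cilia never overlap and point matching is unambiguous; class
counts come from one multinomial draw of the class mix.

What the generator does **not** emulate: texture of embedding medium and
cytoplasm, partial/oblique sections, stain gradients, neighbouring
non-ciliary organelles, and the continuum of real defect severity.
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline — its contracts, statistics and parameter
recovery under the stated noise model — not clinical performance on
patient micrographs.

## Preprocessing and tiling

Detector input is inverted (p → 255−p) and denoised with a 3×3 median
filter (parameter-free salt-noise suppression; the original system's
denoiser is unspecified, and any light denoiser serves the same role).
Images are padded on the right/bottom with the image median (a robust
background estimate) to a multiple of 814 px and cut into non-overlapping
814×814 patches, row-major, offsets recorded; stitching the patches and
cropping the padding reconstructs the input bit-exactly.  Training-time
operators are provided for completeness: mirrorings and quarter-turn
rotations with consistent point/axial-angle transforms (mirror: θ → 180−θ;
quarter turn: θ → θ+90, all mod 180), and class-balancing occlusion that
covers selected cilia with background-matched noise discs (disc shape
assumed; the original covering shape is unspecified).

## Detection

One candidate per (anchor box, class): square anchors of side 96/128/160 px
on a 16 px stride, with centres allowed to reach the patch border (the
scorer pads the hidden part of an over-the-edge box with the local median,
so a cilium cut by a patch boundary still receives a centred candidate and
is reported once after whole-image NMS).  The stride is half the initially
considered 32 px: calibration showed that with the centre-weighted
reference scorer a worst-case grid misalignment of ~23 px (stride 32)
drives the correlation of a true cilium to background level, while ~11 px
(stride 16) keeps it clearly above.

The **reference scorer** is classical template correlation.  Templates are
clean renders of the generator's own prototypes, inverted to detector
polarity and decimated to 48×48: for *normal*, a bank over 12 central-pair
angles × 8 doublet-ring phases (the axis and ring phase of a real section
are arbitrary); for *primary*, central-complex (9+0) and missing-doublet
(7+2) banks; for *secondary*, 8 compound-axis rotations, an extra-doublet
(12+2) bank and a swollen prototype.  Each anchor crop is compared by
Pearson correlation weighted by a centred Gaussian (σ = 0.5 of the box
side), which makes the response fall off quickly for off-centre boxes, and
the best in-class correlation is squashed through a logistic
1/(1+e^(−15(ncc−0.28))).  The midpoint sits above the maximum correlation
that median-filtered background noise attains over a full patch (~0.14),
so a blank image yields no point above the 0.15 filter, while the weakest
true renders (~0.21) stay above it.  This scorer exists to exercise the
pipeline contract at desk scale; subtype discrimination by correlation
alone is limited (disorganized or vesicle-bearing cilia are frequently
assigned the wrong class), which the evaluation module duly measures.  The
`TrainingConfig` record (Adam, learning rate 0.001, mini-batches of 16
image segments, 28 epochs, early stop after 5 epochs without validation
improvement) houses the hyperparameters for a trainable backend; training
a network at scale is not reproduced here.

NMS is greedy by descending score, suppressing boxes with IoU > 0.5
(class-agnostic, so each cilium keeps its best-scoring class), with
deterministic tie-breaking on position; it is idempotent and matched
against a brute-force O(n²) oracle in the tests.  Surviving boxes become
centroid points; scores < 0.15 are dropped, centroids closer than the
proximity radius keep only the higher score, and scores ≥ 0.75 are flagged
confident.  The proximity radius is 85 px: duplicate points from
off-centre boxes land 36–81 px from the true centre, while true
neighbours are ≥ 120 px apart, so 85 px separates the two cleanly (55 px,
half a cilium diameter, was considered first but leaves duplicates).

## Angle measurement

Per cilium: extract the 150×150 patch (clamped at borders), invert,
correlate with a bank of zero-mean elliptical Gaussian kernels (σ 3.5×2.5
px, ≈10 px across like a rendered microtubule, 12 orientations, per-pixel
maximum), threshold the correlation map at mean + 2 SD, open with a 3×3
structure and drop components under 25 px.  The admissible central pair is
the 1–2 surviving components nearest the mass centre of all components,
within 0.35 × patch size; if none qualifies the measurement fails with the
sentinel −1 (never an exception), displayed and exported as "−0" and
parsed back as failure.  The angle is the orientation of the longer side
of the minimum-area rotated rectangle around the chosen components
(rotating-calipers over the convex hull; principal axis as the degenerate
fallback), folded into [0°, 180°).  Angles are axial — a central pair has
no direction — so all arithmetic is mod 180.

Re-referencing: every observed angle is tried as the new zero; the offset
minimising max−min of (θ−δ) mod 180 wins, ties to the smallest offset.  On
the axial circle the range is constant between consecutive observations,
so the optimal cut always lies at an observed angle and this exhaustive
search is exact (verified against a 0.1° grid scan).  Summaries use the
plain arithmetic mean and per-cilium offsets of the re-referenced values,
matching the spreadsheet-style workflow this replaces; circular moments
are deliberately not used.  The mean is computed after re-referencing
(the natural order here, since the reference rotation is what makes the
angles comparable).

On 100 clean seeded normal cilia at uniform random orientations the
measurement recovers the ground-truth angle with MAE ≈ 0.6° and no
failures; the acceptance bar is MAE ≤ 5° and ≤ 5% failures.

## Evaluation

Predictions are matched to annotations greedily by increasing centroid
distance (each point used once, pairs beyond the radius unmatched; 55 px,
half a cilium diameter, is the matching radius).  Unmatched predictions
and annotations are background events.  One-vs-rest counts per class c:
matched pairs contribute TP_c / FP_c / FN_c / TN_c by label; an unmatched
prediction of c is FP_c, an unmatched annotation of c is FN_c, and each is
TN for the other classes — every event is counted for every class, so the
per-class event totals are equal by construction.  Metrics are
accuracy = (TP+TN)/N, precision = TP/(TP+FP), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), reported in percent rounded half-up to two
decimals; zero denominators yield NaN rather than an error.  Cohen's
κ = (p_o−p_e)/(1−p_e) is computed on the label-vs-label matrix with the
background treated as a fourth label, and optionally with the background
row/column removed; degenerate single-label data gives NaN.  PR and F1
curves re-match the thresholded predictions at each score threshold and
macro-average precision/recall over the classes present in the truth;
the argmax-F1 threshold is reported.  Angle errors are axial distances
min(|Δ|, 180−|Δ|): MAE, sample SD of absolute errors, the fraction within
5°, the mean absolute percent error (axial error / corrected angle,
excluding corrected angles of 0°, where the ratio is undefined — the
statistic is ill-conditioned near 0° and reported for completeness), and a
two-sided Wilcoxon signed-rank test on the pairs (exact for n ≤ 25, normal
approximation beyond).

## Configuration, I/O, determinism

All thresholds live in one validated YAML configuration with the 0.15 /
0.75 defaults.  Annotations travel in a comma-separated UTF-8 CSV with a
header and '.' decimals (`image_id, x, y, class, score, confident,
angle_deg, source`); floats are written in shortest-roundtrip form so
write-then-read is lossless, the class vocabulary is closed, malformed
rows report their index, and "−0" round-trips as measurement failure.
`export_results` writes one CSV per image plus a joint file whose class
counts are exact sums of the per-image counts and whose angle summary is
recomputed on the pooled valid angles.  Every random choice flows through
a seed, and the simulate → detect → angles pipeline is byte-identical
across runs with equal seeds.

## Acceptance-study sizes

`scripts/acceptance.py` uses 4 scenes of 814×814 px with 12 cilia each
(class mix 0.7/0.15/0.15) for the detection/classification study and 100
clean single cilia for angle recovery — large enough for stable
recall/precision and angle statistics, small enough to run in tens of
seconds on one CPU.  The classification κ of the reference scorer on mixed
scenes is modest (≈0.15–0.35 depending on the seed) and varies between
seeds at this study size; it reflects the limits of pure template
correlation for subtype discrimination, not of the evaluation machinery,
which is exercised separately against hand-computed and brute-force
oracles.

## Known limitations

* The reference scorer assumes the generator's fixed scale and contrast;
  images at another magnification are explicitly unsupported.
* Subtype-level classification (beyond the three classes) is not
  attempted.
* Overlapping-tile inference is not implemented; boundary handling relies
  on over-the-edge anchors within each patch.
* Re-referencing minimises the range, which is sensitive to a single
  outlier angle; with many measurement failures in one image the mean
  rotation rests on few values.
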