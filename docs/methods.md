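# Methods

## Problem and model

Backlit imaging of a batch of opaque, near-convex objects (the motivating
case is freshwater pearls on a light table at 20 px/mm) produces dark
silhouettes on a bright field. Objects that touch form one connected
foreground domain, so instance-level shape measurement requires splitting
tangent objects first. `pearlseg` does this with a concave-point model:
where two convex silhouettes touch, the merged boundary necessarily carries
two sharp inward notches ("pits") at the entrances of the contact neck, and
the straight segment joining them is a natural cut.

The pipeline stages and their models are:

**Binarization.** Global CDF histogram equalization, separable Gaussian
smoothing (σ = 1 px, reflective borders), then Otsu's
between-class-variance threshold with the dark side as foreground.
Morphological opening and closing with 3-px horizontal and vertical line
elements removes contour roughness; hole filling guarantees simply
connected regions, which the diameter measurement requires. On synthetic
anti-aliased scenes the recovered mask deviates from the true silhouette by
at most one diagonal pixel.

**Contact detection by area ratio.** With connected-domain areas
S₁…Sₙ and S_min their minimum, Kₙ = Sₙ / S_min separates singles
(K ≈ 1) from clusters. A region is a contact cluster when K > 1.50
(strict). This presumes at least one isolated object in the scene; when a
caller knows none exists, a nominal single-object area can be supplied
(`RunConfig.reference_area`). K values are reported rounded to two
decimals, the working precision of the area-ratio test. Regions under 50 px
are treated as speckle and dropped — real objects at this scale are
~13 000 px.

**Pit detection.** On the clockwise Moore-neighbor contour, the included
angle at point p_k is computed from the chords to the points `step`
positions before and after (law of cosines). Points with θ at or below the
candidate threshold (default 60°) form runs that are collapsed to their
minimum-angle point, one candidate per physical notch. The comparison is
inclusive because on a digital contour with a 2-px step the sharpest
attainable notch angle is frequently exactly 90°, which must remain
reachable by the relaxation cap below.

**Pit matching.** Candidates are clustered into two classes by 2-means
(deterministic: initialized at the two mutually farthest candidates);
candidate pairs are examined cross-class first, by increasing Euclidean
distance. A pair is accepted only if every integer point of the
perpendicular bisector of its connecting segment, restricted to the circle
whose diameter is that segment, has object gray (below the image's Otsu
threshold): a true neck is object-gray throughout, while a pair spanning a
background inlet is not. Two validation rules extend this test to dense
clusters:

* *Neck-depth gate.* The cut may not run deeper into the region than half
  the region's maximum inscribed radius (distance transform). A genuine
  neck hugs the background on both sides; a chord through an object's core
  — which arises when the nearest cross-class pair straddles two different
  necks of a chain — does not.
* *Same-class fallback.* If every cross-class pair fails, same-class pairs
  are examined under the same validation. This recovers necks whose two
  pits were grouped into one k-means class, the typical geometry for
  chains of three or more objects.

**Adaptive relaxation.** When no pair validates, the candidate set is
enlarged by raising the angle threshold in 5° increments up to 90°, and —
because the included angle of a rounded notch is scale-dependent — by then
escalating the angle step itself from 2 px up to 8 px and repeating the
threshold ladder. The full (step, threshold) ladder is walked so that every
neck of a multi-contact cluster is found in one pass; each accepted cut
leaves an exclusion zone scaled to 0.6× its pit separation, so a neck is
never cut twice at a later rung. A region whose ladder completes without
any accepted pair is reported unsplittable and left intact.

**Splitting.** Each accepted pit pair is cut with a 1-px digital segment.
The Bresenham line is thickened at diagonal steps (supercover) because
removing a plain 8-connected line does not disconnect 8-connected
foreground. Cut pixels are charged to neither object. After each round of
cuts the area-ratio test is re-run until no region exceeds the K threshold,
which resolves chains recursively.

**Shape grading.** For each contour pixel i, the diameter d_i is the chord
through the region centroid: the distance to the contour pixel whose
direction from the centroid is closest to antipodal, plus 1 px (a chord
between boundary-pixel centers spans n−1 px of an n-px-wide object), scaled
by mm/px. "Diameter" here is deliberately the chord through the centroid:
it is well defined per contour pixel, reduces to the true diameter for
circles, and matches the plain meaning of the word. The shape parameter is
X = (d_max − d_min)/d̄ × 100 with d̄ = mean(d_i) by default;
d̄ = (d_max + d_min)/2 is available as `d_mean_mode="extremes"` because
both conventions are in circulation — they agree for circles. Grades follow
the roundness bands X ≤ 3.0 (A1, perfect circle), ≤ 8.0 (A2, circle),
≤ 12.0 (A3, near circle), ≤ 20.0 (B, ellipse), else ungraded; bands are
inclusive with a 1e−9 epsilon for float round-off. The bands are evaluated
on X, not on millimetre ranges, since published range examples are anchored
to one nominal diameter.

A 5-point circular moving average is applied to the ordered d_i sequence
before the max/min are taken (`smooth_window`). Rationale: each raw chord
carries ±1 px quantization jitter, and an extreme over ~500 chords would
otherwise inflate X by 1–2 percentage points, enough to push a true
near-band-edge circle out of its band. The smoothing preserves one
diameter per contour pixel and leaves analytic disc/ellipse measurements
within 2% of truth.

**Evaluation.** Y = C/L with C the number of correctly segmented objects.
Predicted objects are matched to ground truth greedily by centroid
distance, gated at one mean true radius; a match is *correct* when its area
loss satisfies |Z| ≤ 10% and it overlaps its true instance by more than
50%; unmatched predictions are subtracted from C. The loss rate is
Z = (1 − K₁/K₂) × 100 with K₁ = S₁/S_a (the object's share of its
cluster's reference areas) and K₂ = S₂/S_b (its share of the contact-state
region area, taken from the pre-split mask); Z is signed and may be
negative when a split over-credits an object. For clusters of more than two
objects, Z is computed per object against its matched reference and
averaged in absolute value. Macro-F1 is the harmonic mean of macro-P and
macro-R (the arithmetic means of per-class precision/recall); classes with
an empty denominator score zero rather than being skipped. Note this
differs from the common "mean of per-class F1" convention.

## Synthetic scenes

The generator renders dark ellipses (intensity 25) on a bright field (230)
with 4× supersampled anti-aliasing, 8-bit quantization and additive
Gaussian intensity noise (σ = 5 gray levels), emulating a backlit LED
stage. Tangent clusters are built as chains: each member is placed along a
contact direction at the center distance where the two boundaries touch
exactly, solved by bisection on the neighbor's implicit ellipse equation
(tolerance ≪ 1 px, overlap excluded). Ground truth records the instance
label map (pixels assigned to the object with the largest coverage),
per-object areas, centroids, axes, intended grade and the analytic
tangency points.

Grades are encoded by eccentricity: a target X is drawn uniformly from the
interior of the grade's band (10% margin per side) and converted to an
axis ratio via X = 200(a−b)/(a+b); `axis_ratio=1.0` gives ideal circles.
Default geometry is a mean radius of 80 px (8 mm at 20 px/mm) with a 2-px
spread, matching the ~±5% area spread that singles exhibit in the worked
batch table; scenes used in the stress experiments contain one tangent
cluster plus two isolated objects, so S_min comes from a genuine single,
as the area-ratio test assumes.

What the generator does *not* emulate: surface texture and luster
(backlighting suppresses them by design), stacked objects, lens
distortion, and non-elliptical outlines. Passing tests therefore show the
geometry of the method works under realistic pixelation, soft edges and
intensity noise — not that the fixed 1.50/60° operating point is optimal
for any particular camera.

## Experiment sizes

The stress suite uses 200 scenes with cluster sizes drawn uniformly from
2–5 (≈1100 objects, ~90 s on one CPU); the contact-posture sweep uses 24
angles × 5 repetitions. These sizes give sub-percent resolution on the Y
and coincidence rates while keeping a full run to a few minutes.

## Numerical choices and degenerate inputs

* Otsu threshold: exhaustive integer scan, classes {v < t} and {v ≥ t},
  smallest maximizer on ties; single-level images yield an empty mask.
* arccos arguments are clipped to [−1, 1]; coincident angle points raise.
* Contour trace starts at the topmost-then-leftmost boundary pixel and
  runs clockwise — determinism for testing; single-pixel regions yield a
  one-point contour.
* 2-means is seeded and initialized at the two farthest candidates; with
  exactly two candidates the clustering is trivial, reducing matching to
  the plain bisector test.
* A pit pair with zero separation (both candidates on the same pixel, as
  happens for mathematically tangent crisp discs) is rejected; such
  regions are handled by the relaxation ladder or reported unsplittable.
* The centroid must lie inside the contour for diameters to be defined
  (winding-number check); pathological non-convex regions raise.
* No lower angle cutoff is enforced on pits: a true pit may be arbitrarily
  sharp.

## Known limitations

* The area-ratio test needs a trustworthy S_min; heavily size-heterogeneous
  batches (beyond ~±10% area) can push a two-object cluster of small
  objects below K = 1.50 relative to a large single. The threshold and a
  reference area are configurable, but no adaptive rule is implemented.
* Necks wider than ~2× the escalation cap (step 8 px) would evade the
  angle model; at the default scale this corresponds to interpenetrating,
  not tangent, objects.
* Grading assumes simply connected, star-shaped-about-the-centroid
  outlines; strongly concave objects are outside the model.
* Bands of the posture sweep near a grade boundary are intrinsically noisy:
  an object whose true X sits within the measurement jitter (~±0.5) of a
  band edge can flip grade regardless of segmentation quality.
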