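# pearlseg

Segmentation and roundness grading of **touching near-circular objects in
backlit images**, built around concave-point (pit) detection.

When pearls — or any batch of opaque, near-convex objects — are imaged in
bulk on a backlit stage, objects that touch merge into a single dark
connected domain, and any per-object shape measurement breaks down.
`pearlseg` implements a full pipeline for this problem:

1. **Preprocess**: histogram equalization, Gaussian smoothing, Otsu
   binarization (dark side = object), morphological cleanup with linear
   structuring elements, hole filling.
2. **Find contact clusters**: label the connected domains, compute each
   domain's area ratio *K*ₙ = *S*ₙ / *S*_min against the smallest domain
   (a genuine single object), and flag clusters by *K*ₙ > 1.50.
3. **Split clusters at concave points**: trace the cluster contour
   (Moore-neighbor), compute the three-point included angle
   θ = arccos[(S²ₖ₊₁ + S²ₖ₋₁ − S²ₖ) / 2Sₖ₊₁Sₖ₋₁] at every contour pixel,
   take sharp notches (θ ≤ 60° at a 2-px step) as candidate pits, match
   the two pits of each contact neck (2-means clustering, shortest
   cross-class pair, perpendicular-bisector gray test), and cut the
   validated pit pairs with a 1-px Euclidean segment. The contact test is
   re-run until every region is a single object.
4. **Grade shapes**: for every object, measure the chord-through-centroid
   diameter *d*ᵢ at each contour pixel and form the diameter-difference
   percentage **X = (d_max − d_min) / d̄ × 100**; grade by the
   GB/T 18781-2008 roundness bands — X ≤ 3.0 perfect circle (A1), ≤ 8.0
   circle (A2), ≤ 12.0 near circle (A3), ≤ 20.0 ellipse (B).
5. **Evaluate**: segmentation accuracy Y = C/L, per-object area loss rate
   Z = (1 − K₁/K₂) × 100, and macro-averaged P/R/F1 over the grade
   confusion matrix.

A synthetic-scene generator (`pearlseg.synth`) renders anti-aliased backlit
scenes of exactly tangent discs/ellipses with instance-level ground truth,
and drives the included stress and contact-posture experiments.

## Worked example

```python
from pearlseg import (RunConfig, SceneSpec, generate_scene, segment_scene,
                      grade_objects, evaluate_segmentation)

spec = SceneSpec(clusters=(3, 1, 1), grades=["A1", "A2", "B", "A1", "A3"], seed=21)
img, truth = generate_scene(spec)          # one 3-chain + two singles
res = segment_scene(img, RunConfig())
print(f"{res.n_objects} objects after {len(res.pit_pairs)} splits "
      f"(Otsu threshold {res.threshold})")
report = grade_objects(res.labels)
print(report[["label", "d_max_mm", "d_min_mm", "X_percent", "grade"]]
      .round(2).to_string(index=False))
ev = evaluate_segmentation(truth, res.labels, pre_split_mask=res.mask)
print(f"Y = {ev.Y:.2f}, mean |Z| = {ev.mean_abs_Z:.2f}%")
```

prints

```
5 objects after 2 splits (Otsu threshold 101)
 label  d_max_mm  d_min_mm  X_percent grade
     1      8.43      7.33      13.93     B
     2      8.26      8.13       1.59    A1
     3      8.06      7.34       9.42    A3
     4      8.63      8.06       6.80    A2
     5      8.21      8.03       2.16    A1
Y = 1.00, mean |Z| = 0.11%
```

The three tangent objects were separated by two pit-pair cuts; the five
measured grades recover the five grades the generator encoded (X is in
percent, diameters in mm at the default 20 px/mm scale), every object was
correctly segmented (Y = 1.00), and splitting sacrificed about 0.1% of
each object's area share (mean |Z|).

## Command line

```bash
pearlseg simulate scene.yaml -o sim/       # render a scene + ground truth
pearlseg segment sim/scene.png -o seg/     # label map, region + pit tables
pearlseg grade seg/labels.png -o shapes.csv
pearlseg evaluate --pred seg/labels.png --truth sim/truth.json \
                  --truth-labels sim/truth_labels.png -o metrics.json
pearlseg sweep --axis-ratio 1.0 --angles 0:360:15 --reps 5 -o sweep.csv
```

Defaults (2-px angle step, 60° candidate threshold, K threshold 1.50,
20 px/mm) can be overridden by flags or a YAML config.

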