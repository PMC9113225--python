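# Methods

## Problem and model

Counting fruit in orchard video by tracking-by-detection: a detector
emits per-frame bounding boxes; the tracker links them into tracks; the
count is the number of track identities. The failure mode this package
targets is identity fragmentation — one physical fruit receiving
several identities because occlusion or detector misses break its track
— which directly inflates the count.

Two physical facts license the central approximation. Fruits are
stationary in the world, and the camera translates at a uniform speed,
so between consecutive frames every fruit moves by (nearly) the same
image displacement. When a track goes unmatched, the mean displacement
of the tracks that *were* matched in that frame is an unbiased estimate
of the lost target's motion, independent of how long the target has
been unobserved — unlike a coasting Kalman prediction, whose error
grows with the gap. Occlusion is additionally gradual: a fruit slipping
behind a leaf shrinks in visible pixel area before vanishing, so the
propagated box's width and height are decayed by a factor α per
unobserved frame, and a track whose area falls below a fixed fraction
of its birth area is declared fully occluded and deleted.

## Tracker

State per track: the SORT parameterization `(cx, cy, s, r, vcx, vcy,
vs)` with constant aspect ratio and constant-velocity dynamics, SORT's
standard noise magnitudes (measurement `diag(1,1,10,10)`, initial
covariance `diag(10,10,10,10,1e4,1e4,1e4)`, process
`diag(1,1,1,1,.01,.01,1e-4)`). The filter is deliberately unmodified;
the contribution is in the lifecycle of unmatched tracks.

Per frame: predict all tracks; Hungarian assignment against detections
under cost `1 − IoU` (scipy `linear_sum_assignment`), assignments below
the IoU gate broken. Three categories result:

- *matched detection*: Kalman update; the (previous, current) center
  pair feeds the frame's mean-displacement estimate;
- *unmatched detection*: a new track id (ids start at 1, never reused);
- *unmatched track*: center shifted by the frame's mean displacement,
  size decayed; deleted when `w·h < scale_delete_ratio · birth_scale`.

The decayed size is computed in closed form, `w = w_ref · α^m` with
`w_ref` the size at the last matched frame and `m` the consecutive
estimated frames, so the decay law is exact rather than accumulated
through repeated floating multiplies. When a frame has no matched
track at all, the most recent nonzero displacement estimate is reused;
before any displacement has ever been observed, the track falls back to
its own Kalman prediction.

Counting: an identity is counted once it has `min_hits` matched frames
(default 2), suppressing single-frame false detections. With
`use_region`, detections are pre-filtered to box centers inside
`[region_lo·W, region_hi·W]` (closed interval, defaults 0.2/0.8 — the
central 3/5 of the frame width). The rationale comes from the occlusion
taxonomy below: occlusion states attached to the entry and exit fifths
of the frame then never reach the tracker. With
`use_displacement=False` the tracker is plain SORT: unmatched tracks
coast on the Kalman prediction and die after `max_age` (default 1)
unmatched frames.

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| `iou_threshold` | 0.3 | SORT convention for the association gate |
| `alpha` | 0.95 | slow decay: brief misses survive; with the deletion rule below, an unobserved track lives ~13 frames |
| `scale_delete_ratio` | 0.25 | scale-relative (resolution-independent) deletion; area α^{2m} < 0.25 ⇒ m ≳ 13 at α = 0.95 |
| `min_hits` | 2 | one matched frame is indistinguishable from a false detection |
| `region_lo/hi` | 0.2 / 0.8 | central 3/5 of the frame width |
| `max_age` | 1 | SORT baseline convention |

α and the deletion threshold are free parameters of the method (no
canonical values exist); both are exposed in the config and the YAML
schema.

## Metrics

Counting error of one sequence is `|y − ŷ|/ŷ` (automated vs manual
count); across m sequences the MAE is the mean of these and the SD is
the *population* standard deviation (divide by m) — the convention that
reproduces the published aggregate of the six-video benchmark this
package's worked examples are frozen from (MAE 0.081, SD ≈ 0.08 for the
region-strategy tracker; 0.45 for SORT; 1.212 for DeepSort). One
published per-video error (0.1265) is inconsistent with its printed
counts (211 vs 183 → 0.1530) and is documented but not asserted. The
SDs printed for the SORT/DeepSort rows of that benchmark are not
reproducible from the per-video errors under either the population or
the sample convention; only the region-strategy SD is asserted.

Track audit: each counted predicted track is assigned to the
ground-truth fruit sharing the most frames at IoU ≥ 0.5; per fruit the
earliest-born track is a correct count, later ones are double counts,
unassigned tracks are false counts. The identity-switch count used in
tests is, per fruit, the number of distinct assigned identities minus
one.

Detection metrics are single-class: greedy confidence-ordered
one-to-one matching at IoU ≥ 0.5 defines TP/FP; precision TP/(TP+FP),
recall TP/GroundTruth, F1 the harmonic mean, with undefined
denominators reported as absent (`None`) rather than zero. Average
precision is the exact integral of the empirical precision-recall step
curve, `Σ (R_k − R_{k−1}) P_k` — the continuous-integral reading of
AP = ∫ P(r) dr, without VOC-style envelope interpolation (the tests
cross-check against `sklearn.metrics.average_precision_score`, which
uses the same definition). Note the denominator is the full
ground-truth count, so undetected targets depress AP even though they
never appear as curve points.

## Network-design analytics

Receptive field: `R_k = 1 + Σ_{j≤k} (F_j − 1) Π_{i<j} S_i` with
`S_0 = 1`, counting convolution layers only — residual shortcut
additions are elementwise and leave the receptive field unchanged, so
they are transparent to the indexing. On the standard DarkNet53 conv
list (stem 3×3/1, five 3×3/2 downsamplers followed by 1/2/8/8/4
residual blocks of [1×1/1, 3×3/1]; 52 conv layers) this gives R₉ = 29
and R₂₆ = 165, which is the quantitative basis for placing small- and
medium-target detection branches at those depths: labelled orchard
fruit clusters at ~11×12–18×19 px fit inside a 29-px receptive field,
the 24×16–50×31 clusters inside 165 px. `branch_for_target` implements
the matching heuristic as "smallest k with R_k ≥ the target's larger
dimension"; the effective-receptive-field notion motivating it is
qualitative, so this concrete criterion is this package's choice.

Anchor clustering uses standard k-means (squared Euclidean on (w, h),
k-means++ init, fixed seed, `sklearn.cluster.KMeans`); a `metric="iou"`
variant (Lloyd iterations under 1 − IoU of corner-anchored boxes, the
convention common in anchor estimation) is offered since the metric is
a free choice. Mosaic augmentation composites four labelled images
into a 2×2 collage around a jittered center with nearest-neighbour
resizing; boxes are mapped by each quadrant's affine and clipped,
dropping boxes left empty.

Attention reference: channel attention is squeeze-excitation —
`z_c = mean(x_c)`, `s = σ(W₂ δ(W₁ z))`, `y_c = s_c x_c` — applied
independently to the shallow map and the 2× nearest-neighbour-upsampled
deep map (upsampling mode is unstated in the source design;
nearest-neighbour is parameter-free and standard in the YOLO lineage).
Reduction ratio defaults to 16 (SE-Net convention). The concatenated
map is spatially reweighted: channel-wise mean and max stacked, 7×7
convolution with zero "same" padding, sigmoid, broadcast multiply. The
two channel branches do not share parameters (the design is ambiguous;
independent sets are the general case). All weights are strictly in
(0, 1), so every stage is an attenuation — a property the tests assert.

## Simulator

What it emulates: a camera translating horizontally at uniform speed
past stationary fruits, so each fruit's image center moves exactly
`camera_speed` px/frame (right to left) from entry to exit; fruit
widths are drawn from a clipped normal spanning the ~11–50 px range of
labelled orchard fruit; each fruit carries one of seven occlusion
conditions A–G marking the initial/intermediate/leaving stages of its
transit as clear or occluded (A = never occluded, E = intermediate
only, ...). The three stages are implemented as the three equal thirds
of the transit in image x — the source taxonomy defines them only by
example frames — and an occluded stage suppresses the detection over
the central `occl_span` (default 0.6) fraction of that stage. An
optional `gradual_shrink` flag shrinks the box over the 3 frames
entering an occlusion, mimicking the gradual loss of visible pixel
area. Detector imperfection: per-box Bernoulli misses, Poisson false
positives per frame, Gaussian center/size jitter. Everything is
deterministic given the scene seed (noise uses an independent stream
derived from it).

Default study conditions: 1920×1080 frames; `camera_speed` 4 px/frame
(a slow rover pass: the frame is crossed in ~480 frames, and the
per-frame displacement stays well under the smallest fruit width so
association survives the zero-velocity Kalman initialization); default
occlusion mix 0.40/0.15/0.10/0.15/0.10/0.05/0.05 for A–G, reflecting
that entry/exit-edge conditions dominate real sequences while the
relative frequencies are otherwise unquantified. Test fixtures use
~30 fruits with a 400-px entry stagger (sequences of a few hundred
frames), sized so the whole suite runs in well under a minute of
tracker time.

What it does *not* model, hence what passing tests do not show:
appearance (no pixels are rendered — detector noise is statistical, not
photometric), camera shake and speed variation, fruit clustering and
mutual occlusion geometry, lighting. Closed-loop results on the
simulator validate the tracking logic under the method's own motion
assumptions; they do not predict counting error on real footage, where
detector quality dominates.

## Numerical choices and degenerate inputs

- Association ties are resolved by `linear_sum_assignment`'s
  deterministic ordering; match lists are reported sorted by detection
  index.
- Boxes are real-valued with strictly positive sizes; degenerate
  dimensions raise at construction. IoU of disjoint boxes is exactly 0.
- An empty detection file, empty frames, or an empty sequence are all
  valid (count 0); frames must be processed in strictly increasing
  order.
- MOT files are 1-based on disk, 0-based in memory; track files are
  written sorted by (frame, id) so identical runs are byte-identical.
- The counting region is a closed interval, so boundary centers count
  as inside.

## Known limitations

- No appearance model: two fruits swapping image positions within one
  frame gap can exchange identities; the displacement model assumes all
  targets share one motion, which breaks under camera rotation or
  depth parallax.
- The scale-decay deletion couples α and `scale_delete_ratio`; the
  defaults give a ~13-frame occlusion horizon at any resolution, but
  sustained occlusions longer than that necessarily fragment tracks
  (the region strategy exists precisely to keep such states out of the
  counting area).
- Detection-quality benchmarks on real orchard imagery require a
  trained detector and are out of scope; the detection metrics here are
  exercised on simulator output and published worked examples only.
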