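# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `rodtrack`, in the order the pipeline runs.

## Conventions

Boxes are half-open pixel rectangles `(xmin, ymin, xmax, ymax)` with area
`(xmax−xmin)·(ymax−ymin)`, top-left origin, x right, y down. On disk,
PASCAL VOC XML uses the inclusive 1-based convention, so `xmin+1, ymin+1,
xmax, ymax` are written and the conversion is inverted on read; the
roundtrip is exact and the files open in LabelImg. Grayscale conversion uses
BT.601 luma weights with BGR channel order (0.114, 0.587, 0.299).

## Detection post-processing

IOU is intersection area over union area. NMS is greedy: sort by descending
score (stable, so score ties keep insertion order and the result is
deterministic), keep the best, delete boxes whose IOU with it *exceeds* the
threshold. The threshold defaults to 0.45 and is configurable; suppression
is single-class. Rotated boxes and soft-NMS are out of scope.

## Segmentation chain (automatic labeling / default detector)

Stages, in order: Gaussian convolution → bilateral filter → grayscale →
CLAHE → fixed binarization → erosion/dilation → connected components →
size/ROI gate.

- Gaussian: kernel size 5, σ from the size rule
  `σ = 0.3·((ksize−1)·0.5 − 1) + 0.8` (= 1.1 at ksize 5). The 1-D profile is
  the standard `exp(−x²/(2σ²))`; the 2-D kernel is its outer product,
  normalized to unit sum. Borders replicate, so constants pass through
  unchanged and no frame-edge artifacts binarize as foreground.
- Bilateral: σ_color = σ_space = 75, neighborhood diameter 40 (rounded up to
  the odd 41 required by a centered window). Implemented with
  scikit-image's `denoise_bilateral` on the [0, 1] scale, so σ_color maps to
  75/255.
- CLAHE: contrast limit 1.0 in the OpenCV convention (clip at
  `clip·tile_area/nbins` counts per histogram bin), which maps to
  scikit-image's normalized `clip_limit = clip/nbins` with 256 bins. The
  "50×50" setting is read as a 50×50 *tile grid*; the tile size in pixels is
  derived from the frame size.
- Binarization at gray 100 keeps pixels *below* threshold (the animal is
  darker than the floor); an `invert_polarity` flag supports light-on-dark
  scenes.
- Morphology: 3 erosions then 4 dilations with a 5×5 rectangle. The extra
  dilation deliberately over-grows the blob slightly so the whole body is
  contained after the filters have eroded its edge.
- Contours: outermost connected components only (holes ignored); each
  component's bounding box becomes a detection with score 1.0. Components
  wider or taller than 200 px are rejected (an animal cannot be that large
  at this scene scale), as is anything outside the optional arena ROI.

## Nine-point position correction

Probe grid: the claimed point plus 8 neighbors at offsets {−30, 0, +30} px
in x and y. A probe "reads as body" when its gray value is strictly below
105 (strict comparison; the boundary case is not documented anywhere
authoritative, and strictness makes the body predicate identical to the
binarization predicate's spirit). If the claimed point reads as body it is
kept; otherwise the qualifying probe with minimum gray wins, ties broken by
distance to the claimed point, then scan order — the most literal reading of
"compare every gray value and select an optimal point". If nothing
qualifies the original point is returned, flagged `failed`. Probes are
sampled as single pixels (a patch radius is available but defaults to 0);
off-image probes clip to the border so the candidate count stays at nine.
Correction is idempotent by construction: a corrected point reads as body,
so a second pass keeps it.

## Kalman filter

Constant-velocity model, state (x, y, vx, vy), dt = 1 frame. The defaults
are Q = diag(1, 1, 10, 10) px², R = diag(10, 10) px², initial covariance
diag(10, 10, 100, 100) with zero initial velocity: position is measured
directly (moderate R), velocity is unobserved and changes as animals turn
(large Q on velocity, broad initial uncertainty). The update uses the
Joseph-form covariance, which stays symmetric PSD under any predict/update
interleaving (verified numerically to 1e−9). Box size and acceleration are
deliberately not part of the state.

## Identity assignment

Cost entry (i, j) is the plain Euclidean distance between track i's
reference point and detection j's center. The reference is the one-step
Kalman prediction by default, on every frame: right after initialization the
velocity estimate is ~0, so the prediction degenerates to the last position
and behavior is continuous; once velocity has converged the predicted point
lands on the correct detection even when two animals swap proximal
positions. The minimum-cost matching comes from
`scipy.optimize.linear_sum_assignment`; matches costlier than the gate
(150 px, configurable) are rejected afterwards, leaving both sides
unmatched — this also drops spurious extra detections, since the animal
count is fixed. The gate value is a generous multiple of the largest
plausible per-frame displacement at this scene scale.

## Tracking loop

Identities are created on the first frame with at least `n` detections (the
`n` best by score) and are arbitrary but stable. Per frame: NMS → associate
→ matched tracks take a Kalman update with the nine-point-corrected
measurement; unmatched tracks are filled with their corrected Kalman
prediction. Reported positions are the corrected measurement for `detected`
records and the corrected prediction for `filled` ones — the filter runs
underneath for prediction and association, but the record reflects what the
detector (or the correction) actually said. When a filled point is moved by
the correction it is also fed back into the filter as a pseudo-measurement,
which keeps long coasts anchored to the body. Tracks filled for more than
`max_coast` (30) consecutive frames are flagged `stale` in the CSV but never
deleted: the animal count is fixed, so deletion would only institutionalize
the failure. The track reference point is the box center.

## Highlight removal

Per channel, `f* = log(I+1)` (the +1 avoids log 0), forward-difference
gradients, attenuation `v = a^0.4 · |∇f*|^{−0.4} · ∇f*` applied on mask
pixels with the magnitude floored at 1e−6, then a direct sparse solve of the
5-point Poisson equation `Δf = div v` over the mask pixels with Dirichlet
values from the untouched surroundings, and `exp(f)−1` clipped to [0, 255]
inside the mask. The divergence is the backward difference (the discrete
adjoint of the forward gradient), so `div(∇f) = Δf` holds exactly on the
grid and the solved residual is at rounding level. The mask must not touch
the image border (no Dirichlet data there); an empty mask is a no-op.

The attenuation base `a` is 0.4 *times the mean gradient norm over the
masked region*, not an absolute 0.4. This is a deliberate design choice: the
transform attenuates only gradients above `a`, and the log-domain step of a
saturated highlight on a bright floor (e.g. 255 on 200 gray:
log(256/201) ≈ 0.24) falls *below* an absolute 0.4, which would amplify the
highlight edge instead of flattening it. Scaling by the regional mean —
small, since most of the region is flat floor — makes the highlight edge the
large gradient it needs to be, for any floor brightness. Channels are
processed independently, so the result is invariant to channel order and
safe to parallelize; the contract is equality with the sequential
composition.

## Synthetic scenes

Animals are rotated ellipses (full axes 60×30 px, body gray 60) on a
180-gray floor in a 1024×760 arena — shape fidelity beyond an ellipse adds
nothing to the gray-value and geometry contracts being tested. Motion is
constant-speed (default 5 px/frame) with optional per-frame heading jitter
(default 0.05 rad) and deterministic turn rate, reflective walls with a
margin that keeps the body inside, and rejection-sampled initial placement
at ≥120 px separation. Sensor noise is i.i.d. Gaussian (σ 5 gray levels)
plus optional salt-and-pepper; an optional saturated disk emulates a
specular highlight. Everything is seeded; the same spec reproduces
bit-identical frames.

Detection dropout (`TruthDetector`) suppresses each animal's detection
independently per frame and jitters surviving centers (default σ 2 px,
emulating detector localization error); it acts on the detection stream, not
the rendering, so fill accuracy is measurable against intact truth. What the
generator does **not** emulate: occlusion (animals can overlap only in
designed crossing scenes), body deformation, shadows, fur texture, lighting
drift, and motion blur. Passing tests therefore demonstrate the geometry and
estimation machinery, not robustness to those real-world effects.

The designed crossing scene sends two animals toward each other along one
line so that they pass within half a step near mid-sequence; right after the
pass, each animal's position is nearer the *other's* previous position,
which makes last-position assignment swap identities while the
constant-velocity prediction keeps them. The crossing frame is located
numerically from the truth table rather than assumed.

## Benchmark problem sizes

The tracking benchmarks (fill guarantee: 3 animals, 500 frames, 20%
dropout) run at the full 1024×760 arena — rendering and estimation are
cheap. The filter-chain benchmarks (label recall over 50 frames, clean and
at 1% salt-and-pepper) run on a 512×380 arena with the same animal size:
the 41×41 bilateral window dominates the cost and scales with pixel count,
and at 512×380 the chain's behavior per animal is unchanged (the window,
morphology, and gate are all sized in absolute pixels) while each frame
processes in ~2 s instead of ~7.5 s. Each recall frame is an independent
seeded scene (frame 0 of a fresh placement), so the ≥120 px separation holds
by construction in every measured frame.

## Known limitations

- The segmentation chain erodes the apparent body outline (bilateral mixing
  across the edge plus CLAHE re-stretching), so detected boxes run a few
  pixels small; the 4-vs-3 dilation/erosion imbalance compensates only
  partly. Recall at IOU 0.5 is robust; tight-IOU applications should
  re-tune the morphology.
- One fixed animal count: the tracker neither births nor kills tracks.
- Association uses geometry only (no appearance), so two animals that stay
  in contact for many frames can still swap.
- The highlight mask is user-supplied and static, matching the fixed-scene
  assumption; automatic highlight detection is out of scope.
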