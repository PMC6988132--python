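# Methods

This note documents the model, the parameter defaults, the numerical and
design choices that were genuinely open, what the synthetic scenes emulate,
and the known limitations.

## Appearance model

A bounding box is decomposed into a 7×7 grid of non-overlapping patches.
Grid cut points are `round(k·w/7)` (ties round up), so the patches tile the
box exactly for any integer size; boxes as small as 7×7 px are valid.  Each
patch yields an L1-normalised colour histogram — HSV with 8 H + 8 S + 4 V
bins (20-dim) by default, or RGB with 3×8 marginal bins (24-dim) — optionally
concatenated with a 16-bin signed-gradient orientation histogram over
[0°, 360°), votes weighted by gradient magnitude.  A perfectly flat patch
has an all-zero gradient block; this is the one exception to the
sum-to-one invariant and is deliberate (there is no orientation evidence to
normalise).  Magnitude weighting was chosen because unweighted voting is
dominated by flat-region noise.

Gradients are computed on standard luma (0.299 R + 0.587 G + 0.114 B) by
central differences with replicate borders.  Histograms are computed on the
variable-size patch rectangles directly — they are size-invariant after L1
normalisation — so candidates at different scales share one logical grid
with no image resampling.  Boxes may extend past the frame: pixel reads are
clamped (fully hidden patches give zero blocks) but overlap computations
always use the nominal geometry.

Two code paths produce descriptors: a direct per-rectangle route (the
reference) and per-channel integral images that score thousands of candidate
boxes per frame; a test pins them together at 1e-9 and both are checked
against independent per-pixel loops at 1e-10.

## Segmentation model and patch weights

Colours are quantised to a joint 8×8×8 RGB histogram (512 bins; joint
binning rather than marginals because the model must represent *specific*
foreground/background colours, and 512 bins keeps updates cheap).  The
foreground posterior is a per-pixel recursive-Bayes filter with transition
priors p(1|1) = 0.6 and p(1|0) = 0.4.  Histograms are initialised from the
first-frame box (foreground) and a surrounding ring (background): the ring
excludes a margin gap of 0.4× the box dimensions per side and extends a
further 0.5×; if the ring falls entirely outside the frame the background
region falls back to whole-frame-minus-box.  All histograms carry add-one
smoothing so likelihood ratios are finite.

Per frame, after localisation, the foreground histogram is refreshed from
the winning box with each pixel's count weighted by the weight of the patch
containing it (the *previous* frame's weights — the update order is colour
model → posterior → weights → classifier, matching that dependency), and
blended with factor δ = 0.1.  The background histogram updates symmetrically
from the ring with uniform unit weights.  Patch weights are the per-patch
mean posterior, normalised so the maximum update is exactly 1, then blended
with the same δ.  Weights start at 1 and remain in [0, 1] by convexity.

The previous posterior is stored in image coordinates over the winning box;
pixels never visited carry prior 0.5.  This same-image-location convention
is an interpretation — the per-pixel recursion does not define
re-registration under object motion — and is the simplest one consistent
with a filter over a slowly-moving target.  Degenerate guards: all-zero
patch weights skip the foreground update for that frame; an all-zero
posterior leaves the weights unchanged; a colour bin with both likelihoods
zero (impossible under smoothing) returns the prior.

## Two-level search and scale sets

Level 1 places fixed-scale candidates on a stride-2 grid over a square
window of half-extent r_w = (W+H)/2 (W, H from the pre-scaled first-frame
box).  Stride 2 keeps the ~10⁴-box dense search tractable while staying
sub-box-accurate, since level 2 refines at stride 1 within half-extent
r_s = 5 px around the level-1 winner.

The incremental scale set is S_r = {λ^m·s_{t−1}} with λ = 1.003 and
m ∈ [−5, 5] (n_r = 11, odd by construction).  The Lucas–Kanade set draws
n_pt = 5 points uniformly from each patch of the previous box, tracks them
with sparse pyramidal Lucas–Kanade (21×21 window, 3 pyramid levels, written
in numpy/scipy), and declares a point well-tracked iff forward and backward
passes succeed and the forward–backward error is under 1 px.  The scale
estimate s_p is the median of all pairwise distance ratios (lower middle
element for even counts; baseline distances under 1e-6 px excluded); when
fewer than half the points track well — occlusion, deformation, no texture —
the estimate is distrusted and s_p = 1.  S_p holds n_p = 11 multipliers
uniformly spanning [1, s_p], applied to s_{t−1}: the multiplier reading
(rather than absolute scales) is adopted because the degenerate s_p = 1 case
is described as re-adding the previous scale.  The fused set S_f = S_r ∪ S_p
is deduplicated on exact integer box geometry and always contains s_{t−1},
so the tracker can never be forced into a scale change.

Two details matter numerically.  Scaled candidates are centre-anchored
(the anchor is unspecified in principle; the centre is the symmetric
choice).  And because many nearby scales round to the same integer box,
scales are visited nearest-to-s_{t−1} first so a deduplicated box carries
the most conservative scale label — without this the recorded scale drifts
systematically toward whichever end of the set is visited first.

## Structured-output learning

The classifier is an online structured SVM with a linear kernel
(C = 100, support-vector budget B = 100, 10 reprocess rounds of one
PROCESS-OLD plus 10 OPTIMIZE steps per frame — the classic defaults for this
learner family).  Each frame contributes a pattern: the winner (anchor), a
polar grid of translated boxes (5 radii up to r_w, 16 angles), and two
shrunken boxes (0.90×, 0.95×) at the winner's centre, with structural loss
1 − IoU.  The shrunken negatives exist because the search space includes
scale: colour histograms are size-invariant, so a box strictly inside the
target is pure foreground and, without scale constraints, *always* at least
ties the correct box — under a slow zoom the scale estimate then ratchets
downward and freezes.  Grow-side negatives are deliberately absent: an
over-grown box already loses score through background contamination of its
border patches, and penalising larger boxes suppresses catch-up whenever
the tracker briefly lags a zoom (verified on the walk + zoom scene, where
symmetric negatives froze the scale at 1.07 against a true 1.8).

Dual feasibility (Σ_y β = 0 per pattern, 0 ≤ β_anchor ≤ C, β ≤ 0 elsewhere)
is asserted after every public call in the tests.  The SMO steps never
decrease the dual objective; budget maintenance — removing the negative
support vector whose coefficient transfer to its pattern's anchor least
perturbs the weight vector — necessarily can, so the monotonicity property
is checked with the budget disabled and the budget/feasibility invariants
with a tight budget.

η = 0.3 gates the learning phase: when the winner's normalised score margin
over the best *far* candidate (IoU < 0.5, measured on the level-1 set,
where far candidates exist) falls below η, the frame is ambiguous and the
colour model, weights and classifier are all left untouched.  The semantics
of this threshold were genuinely open; the gate is isolated behind
`TrackerConfig.eta_gate` and can be disabled.  Ties in candidate scores
(within 1e-12) break by smallest centre distance to the previous box, then
smallest scale change, so runs are deterministic given a seed.

## Tracking loop

Frames are pre-scaled (bilinear) so the minimum side of the initial box
reaches 32 px; every reported box is converted back to original coordinates
at the boundary, so external files never see scaled values.  Frame 1's
output is the initial box exactly, and the classifier is trained once on its
neighbourhood.  There is no re-detection: if the target leaves the frame the
search window clamps to the frame edge and the tracker keeps going — losing
a vanished target is an accepted limitation of the framework, not a bug.

## Evaluation metrics

One-pass evaluation: precision at 20 px (fraction of valid frames whose
predicted centre is within 20 px Euclidean, inclusive, of the ground-truth
centre; full curve over 0–50 px) and the success AUC (fraction of frames
with IoU strictly above u, averaged over 1001 thresholds in [0, 1]; equals
mean per-frame IoU up to grid resolution — a perfect run scores 1000/1001
because the u = 1 endpoint uses strict inequality).  Ground-truth rows that
are NaN or non-positive mark out-of-view frames and are excluded from all
statistics.

## Synthetic scenes

The generator renders a textured rectangular target over a textured
background with closed-form ground truth: per-frame centres (random walk,
≤ 5 px/frame in the walk preset), a scale profile (geometric drift, e.g.
1 %/frame, or a step jump such as 1.3× in one frame), optional partial
occlusion by a background-coloured rectangle, and global illumination gain.
Textures are seeded value noise (smooth random fields) because sparse point
tracking needs gradients; a flat mode exercises the low-texture fallback.
The target texture is one fixed master field resampled to the current box
size, so a scale change is a true optical zoom.  Identical seeds give
byte-identical frames.

The rendered target is inset by 6 % per side inside the ground-truth box.
Annotation boxes in real footage bound the object with some background
visible inside them — that margin is precisely what patch weighting exists
to suppress, and the framework's own working assumption is that the target
occupies most (not all) of the box.  A target that exactly fills its box
also makes every under-scaled candidate pure foreground, which turns scale
selection into a degenerate one-sided problem no appearance model can
resolve.  The default study sizes are a 200×150 frame with a 48×48 target
(pre-scale factor 1), 60 frames for the drift scenes and 24 for the jump
scene; these sizes keep a full experiment in tens of seconds while leaving
every mechanism (wide level-1 search, KLT bridging, weight adaptation)
active.

Colour separability is a knob: the background palette can be pulled toward
the foreground palette, and `colour_bayes_error` computes the Bayes error
of the two colour distributions from the exact master-texture histograms
the renderer uses.

What the scenes do *not* emulate: camera motion and parallax (the
background is static), non-rigid deformation, specular highlights, smoke,
motion blur, and object rotation.  Passing the synthetic suite therefore
demonstrates the mechanisms — background suppression, incremental and
abrupt scale handling, robust median scale estimation, online learning —
not performance on real surgical footage.

## Known limitations

* No re-detection after full occlusion or out-of-view.
* Axis-aligned boxes at fixed aspect ratio; no rotation or affine search.
* The colour segmentation model assumes the target and its surround are
  colour-separable at 512-bin granularity; camouflaged targets degrade the
  weights toward uniform (which recovers plain unweighted patch tracking,
  not failure).
* Video-file input requires an imageio video backend plugin; image
  directories are the fully supported path.
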