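# Methods

This package studies multi-object tracking of group-housed pigs from
overhead video detections: how a DeepSORT-style tracker behaves when the
true population of a pen is effectively constant, and whether two track-
management changes — a second, more permissive round of IoU matching and a
population cap on track creation — reduce identity switches relative to the
classic DeepSORT baseline. Because farm video is rarely shareable, the
package includes a synthetic pen simulator that emulates the structure of
such footage, so the whole improved-vs-baseline experiment runs from a seed
with no data download.

## Shape-IoU bounding-box loss

For a predicted box B = (x_c, y_c, w, h) and ground-truth box
B^gt = (x_c^gt, y_c^gt, w^gt, h^gt), the loss is

    L = 1 − IoU(B, B^gt) + distance_shape + Ω_shape / 2

with shape weights derived from the ground-truth aspect,

    ww = 2 (w^gt)^s / ((w^gt)^s + (h^gt)^s),
    hh = 2 (h^gt)^s / ((w^gt)^s + (h^gt)^s),

a cross-weighted normalized center distance

    distance_shape = hh (Δx / c)² + ww (Δy / c)²,

where c is the diagonal of the smallest box enclosing both operands, and a
shape-discrepancy term

    Ω_shape = Σ_{t∈{w,h}} (1 − e^{−ω_t})^θ,
    ω_w = hh |w − w^gt| / max(w, w^gt),   ω_h = ww |h − h^gt| / max(h, h^gt).

Defaults are scale exponent s = 0 (which collapses ww = hh = 1) and θ = 4.
The x-offset is weighted by hh and the y-offset by ww deliberately: a wide,
flat ground-truth box tolerates horizontal offset more than vertical, so the
weight attached to each axis comes from the *other* dimension's share.
Note that ww + hh = 2 identically, and the breakdown identity above holds
exactly by construction (asserted to 1e-12 in tests). DIoU and CIoU are
included as plain comparison formulas only; no gradients are provided
anywhere — the loss is implemented for analysis, not training.

Degenerate boxes (non-positive width or height) are rejected rather than
clamped; silent clamping would mask upstream simulator or parser bugs.

## CBAM attention forward pass

The channel/spatial attention block is implemented as pure NumPy array math
over a C × H × W feature map: channel gates are
sigmoid(MLP(avgpool) + MLP(maxpool)) with a shared two-layer MLP (reduction
ratio r, ReLU between layers); spatial gates are a 7×7 convolution (zero
padding 3, stride 1) over the stacked channel-mean and channel-max maps.
Weights are supplied or generated from a seed, never trained. Both gates lie
strictly inside (0, 1), so refinement strictly shrinks every nonzero entry —
a property the tests exploit. This module exists to make the attention
computation inspectable and testable outside any deep-learning framework;
assembling it into a detection backbone is out of scope.

## Tracker

The tracker is a DeepSORT-style pipeline per frame:

1. **Predict.** Every track advances one step of a constant-velocity Kalman
   filter over (x_c, y_c, a, h) with velocities, a = w/h. Noise standard
   deviations are proportional to box height (position weight 1/20,
   velocity weight 1/160), the de-facto DeepSORT convention, making the
   filter scale-free across near/far animals.
2. **Appearance cascade.** Confirmed tracks are matched to detections in
   increasing staleness order (time since last update = 1, 2, …), each
   level solving a Hungarian assignment on the minimum cosine distance
   between the detection embedding and the track's gallery (budget 100,
   FIFO), capped at 0.2, with pairs gated out when the squared Mahalanobis
   distance of the measurement under the track's prediction exceeds the
   0.95 χ² quantile with 4 dof (9.4877). Without embeddings the cascade
   degrades to Mahalanobis-gated IoU cost (logged once).
3. **IoU round 1.** Tentative tracks and cascade leftovers that missed
   exactly one frame are matched by Hungarian assignment on 1 − IoU with
   cost cap 0.7.
4. **IoU round 2** (improved mode). All still-unmatched tracks — including
   stale ones — get a final IoU chance at cap 0.85. The looser cap is a
   deliberate design choice: a second round over the same leftover pool
   with the same cost and the same cap is nearly a no-op, because a
   minimum-cost assignment rarely leaves a mutually feasible pair
   unmatched. The recovery round targets exactly the losses the first
   round cannot express — short occlusions and fast-motion frames where
   the predicted box has slipped to 1 − IoU ≈ 0.7–0.85 — and measured on
   the simulator those few frames decide whether a confirmed track
   re-locks or starves to deletion.
5. **Population cap** (improved mode). n = round-half-up mean of the raw
   detection counts of the last 3 frames. On the first frame every
   detection seeds a tentative track; afterwards unmatched detections
   create tracks one at a time only while the live (non-deleted) track
   count is below n, and the rest are dropped. "Live" counts tentative and
   confirmed tracks: counting only confirmed would let a flood of
   tentative tracks blow past n. n is computed from raw counts before
   creation, not from match results.
6. **Lifecycle.** Tentative tracks confirm at 3 consecutive hits and are
   deleted the first frame they go unmatched; confirmed tracks are deleted
   when their time since update *exceeds* 30 frames (31 dies, 30 survives).
   Track ids increase monotonically and are never reused. A track's
   reported behavior is the majority label of its last 3 assigned
   detections, ties broken toward the most recent; behavior never
   influences association — it is carried metadata.

Baseline mode disables the cap and the second round, recovering classic
DeepSORT for A/B comparison. Everything is deterministic given inputs:
there is no randomness in the tracker, and assignment ties resolve to the
deterministic choice of the underlying LAP solver.

The cap's guarantee is conditional and worth stating precisely: the maximum
assigned id stays at the true population as long as no track starves to
deletion (every deletion frees a slot that a later creation fills with a
fresh id). With reliable detection counts and physically plausible motion
the simulated experiments hold the bound; under heavy occlusion the cap
still limits id growth dramatically (tens instead of hundreds over 500
frames) without absolutely bounding it.

## Evaluation

CLEAR-MOT protocol with IoU correspondence at threshold 0.5 (community
default): previous-frame pairs persist while they still overlap at the
threshold, the remainder is matched by minimum-cost assignment on 1 − IoU.
MOTA = 100·(1 − (FN + FP + IDSW)/num_gt). MOTP is reported as the mean IoU
of matched pairs in percent — the overlap form, chosen because a
distance-based MOTP lives on a pixel scale and could not be read as a
number in the 90s. Identity switches are gt-centric: an event where a
ground-truth identity's matched hypothesis id differs from its previous
matched hypothesis id. IDF1 uses the global one-to-one identity assignment
maximizing identity true positives (solved exactly as a padded assignment
problem), IDF1 = 2·IDTP/(2·IDTP + IDFP + IDFN).

The test suite cross-checks both metrics against independent oracles: a
from-scratch CLEAR accounting built on polygon-area IoU (shapely) and an
IDF1 computed by exhaustive enumeration of identity bijections, with
agreement required to 0.01 percentage points on 20 seeded scenes.

## Synthetic pen simulator

The simulator emulates the structure of overhead pen footage: a
2688 × 1520 px arena at 25 fps, 7–16 animals, four behavior states (stand,
lie, eat, attack) with attack as a paired interaction, and day/night
detector degradation. It makes no attempt at photorealism; it generates
box trajectories and a detector-like noisy stream.

* **Motion.** Per-animal velocity follows a mean-reverting AR(1) process
  (coefficient 0.95 per frame, i.e. decorrelation ≈ 0.8 s) whose
  stationary per-axis standard deviation is the behavior's speed scale
  (stand 12 px/frame ≈ 0.5 m/s at this pixel scale, eat 4, lie 0), capped
  at 2.5× the scale. Video-rate animal motion is strongly autocorrelated;
  a white-noise walk of the same magnitude would be physically absurd
  (resolving to multi-body-length accelerations) and untrackable by any
  constant-velocity filter.
* **Exclusion.** Animals cannot stack: any overlapping non-attacking pair
  separates along its least-penetrated axis, with total correction capped
  at 8 px per animal per frame (yielding, not teleporting), and initial
  placements are rejection-sampled to be overlap-free. Attacking pairs
  are exempt so fights still produce heavy occlusion.
* **Behavior.** A first-order Markov chain over the four states; the
  default matrix is sticky and never self-initiates attack, because attack
  is a two-animal interaction: episodes start by explicit pairing (per
  frame, probability 0.01 by default) and run as a mutual pursuit at
  40 px/frame for a geometric-length burst (mean ≈ 11 frames).
* **Degradation.** For every pair overlapping above IoU 0.3 the box with
  the smaller bottom-y (farther from an overhead-oblique camera) is
  dropped with probability 0.7; survivors are missed independently
  (base 0.02, ×2.5 at night), jittered with N(0, 3 px) per coordinate,
  and have their class resampled from a confusion matrix (identity by
  default). False positives arrive as Poisson(0.05)/frame random boxes.
  These rates are calibration knobs describing plausible detector quality,
  not measurements of any real farm.
* **Embeddings.** Each animal owns a fixed random unit vector in 32
  dimensions; per-frame embeddings are the identity vector plus N(0, 0.05)
  noise, renormalized — a stand-in for appearance features with realistic
  same-versus-cross identity contrast. False positives get fresh random
  vectors.
* **Presets.** `sparse_day` (7 pigs), `dense_day` (16), `dense_night`
  (16, night miss rate, attack-heavy, harder occlusion) mirror the
  sparse/dense and day/night axes of the emulated recordings.

One seeded RNG drives the whole scene in fixed consumption order (motion,
behavior, degradation, embeddings per frame), so a config reproduces its
scene exactly.

What passing tests on this simulator do and do not show: they demonstrate
the tracker's management logic (cap, recovery round, lifecycle) under
controlled, physically plausible conditions; they do not certify
performance on real video, where detector errors are correlated over time,
appearance features degrade with lighting, and motion has structure
(troughs, walls, social behavior) the random process lacks.

## Numerical choices

IoU is clamped to [0, 1] against round-off. Kalman updates use a Cholesky
solve and re-symmetrize the posterior covariance, keeping eigenvalues
above −1e-9 over 10⁴ cycles. Assignment infeasibility uses a sentinel just
above the cost cap so capped pairs never distort the optimum. Population
rounding is half-up. Frames are 1-based everywhere. CSV floats are written
with two decimals so a write–read–write cycle is byte-stable.

On the Kalman convergence scale: with the DeepSORT noise convention the
tracking error for a noiseless constant-velocity target decays
geometrically at a speed-proportional level (≈ 0.008·|v| px at cycle 20),
so sub-millipixel error within 20 cycles is reached for slow drifts
(≤ ~0.1 px/frame), while a brisk 3 px/frame target needs ≈ 50 cycles; the
tests assert both regimes.

## Problem sizes

The shipped experiments use 10 scenes of 16 animals × 500 frames (20 s of
video each) for the improved-vs-baseline comparison and the cap-bound
check, 20 scenes of 4 × 60 for metric cross-validation, and 200 random
cost matrices up to 6×6 for assignment verification — sizes chosen so the
full suite and the acceptance script each run in minutes on one CPU while
every statistical check retains a ≥3σ margin.

## Known limitations

* The cap assumes a closed pen; animals entering or leaving would require
  re-estimating n, which the 3-frame window does only as fast as the
  detector reflects the change.
* Appearance embeddings are synthetic; conclusions about the cosine
  cascade transfer to real Re-ID features only qualitatively.
* MOTP-as-overlap and gt-centric switch counting are one of several
  dialects of the CLEAR metrics; numbers are comparable across runs of
  this package but not necessarily across other toolkits' conventions.
* The simulator's attack model covers the mutual-pursuit subtype only;
  head-contact subtypes are not geometrically modeled.
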