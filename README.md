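# pigpen-mot

Multi-object tracking of group-housed pigs from overhead video detections.

Continuous monitoring of pen-housed pigs — who is eating, lying, standing,
or fighting, and for how long — is a practical route to early detection of
health and welfare problems, but it only works if each animal keeps a
stable identity across thousands of frames of occlusion-heavy footage.
Off-the-shelf DeepSORT struggles here: whenever a pig is briefly lost to
occlusion or a burst of fast movement, the tracker spawns a fresh identity,
so the maximum track id quickly exceeds the number of animals actually in
the pen.

This package implements and evaluates a pen-specific variant of DeepSORT
built on one observation: the population of a closed pen is constant. It
provides, as a tested library plus CLI:

* **`geometry`** — box algebra and the **Shape-IoU** regression loss
  `L = 1 − IoU + distance_shape + Ω_shape/2`, where the center-distance and
  shape-discrepancy terms are weighted by the ground-truth box aspect
  (`ww = 2(w^gt)^s/((w^gt)^s+(h^gt)^s)`, `hh` symmetrically; `θ = 4`),
  with DIoU/CIoU as comparison baselines and full per-term breakdowns.
* **`attention`** — the CBAM channel+spatial attention forward pass as pure
  NumPy (shared-MLP channel gates, 7×7 spatial convolution gates), with a
  seeded weight generator and an NPZ-style weight archive. In the detection
  backbone this block replaces the bottleneck inside each C3 unit
  (`C3 → [conv] → CBAM×n → [conv]`, concatenated with the bypass branch);
  only the attention computation itself is in scope here.
* **`tracker`** — improved DeepSORT: Kalman filter over (cx, cy, w/h, h),
  appearance cascade with Mahalanobis gating (χ²₀.₉₅, 4 dof), Hungarian IoU
  matching plus a **second, more permissive IoU round** that re-associates
  tracks lost to short occlusions, and a **population cap**: new tracks are
  created only while the live track count is below n, the rounded 3-frame
  mean detection count. Max track age 30 frames. A baseline mode switches
  both additions off for A/B comparison.
* **`metrics`** — CLEAR-MOT (MOTA, MOTP-as-overlap, Rcll, Prcn, FP/FN, id
  switches) and IDF1 under the exact global identity assignment.
* **`simulate`** — a seeded synthetic pen generator (7–16 pigs,
  2688×1520 px arena, 25 fps, stand/lie/eat/attack behavior chain with
  paired attack pursuits, occlusion-driven detection drops, night mode,
  false positives, appearance embeddings) so the whole experiment runs
  without any video data.

## Worked example

```python
from pigpen_mot import (Box, ShapeIoUParams, shape_iou_loss,
                        Tracker, TrackerConfig, clear_mot, preset, simulate_pen)
import pandas as pd

# Shape-IoU of a unit-offset prediction
b = shape_iou_loss(Box(1, 0, 2, 2), Box(0, 0, 2, 2), ShapeIoUParams(scale=0.0))
print(f"iou={b.iou:.6f} distance={b.distance_shape:.6f} "
      f"omega={b.omega_shape:.6f} loss={b.loss:.6f}")

# a dense night pen, tracked in both modes
scene = simulate_pen(preset("dense_night", n_frames=500, seed=0))
for mode, cfg in [("improved", TrackerConfig()), ("baseline", TrackerConfig.baseline())]:
    results = Tracker(cfg).run(scene.detections)
    hyp = pd.DataFrame(
        [(f, r.track_id, *r.box.to_tlwh()) for f, rows in results.items() for r in rows],
        columns=["frame", "id", "left", "top", "w", "h"])
    r = clear_mot(scene.gt_trajectory(), hyp)
    print(f"{mode:>9}: MOTA {r.mota:5.1f}  MOTP {r.motp:5.1f}  IDF1 {r.idf1:5.1f}  "
          f"IDs {r.ids:3d}  max id {hyp['id'].max()}")
```

prints

```
iou=0.333333 distance=0.076923 omega=0.000000 loss=0.743590
 improved: MOTA  91.2  MOTP  93.0  IDF1  73.2  IDs  31  max id 19
 baseline: MOTA  91.1  MOTP  93.2  IDF1  63.7  IDs  51  max id 101
```

The loss line decomposes `1 − 1/3 + 1/13 ≈ 0.743590`: IoU of the offset
pair is 1/3, the squared center offset normalized by the enclosing-box
diagonal is 1/13, and the shape term vanishes for equal sizes. The tracking
lines show the point of the pen-specific variant: on an identical 16-pig
night scene the improved mode cuts identity switches from 51 to 31, raises
IDF1 by ~10 points, and keeps the largest assigned id near the true 16
animals, while baseline DeepSORT inflates to id 101.

The same pipeline runs from the shell:

```bash
pigpen-mot simulate --preset dense_night --seed 0 \
    --out-gt gt.txt --out-det det.csv --out-emb emb.npz
pigpen-mot track --dets det.csv --emb emb.npz --mode improved --out improved.csv
pigpen-mot track --dets det.csv --emb emb.npz --mode baseline --out baseline.csv
pigpen-mot compare --gt gt.txt --res-baseline baseline.csv \
    --res-improved improved.csv --out report.json
```

Files use MOTChallenge CSV dialects (`frame,id,left,top,w,h,…`, 1-based
frames); every written artifact gets a `.meta.json` sidecar recording the
package version, seed, and config hash. `pigpen-mot loss-table` prints
per-pair Shape-IoU breakdowns for two YOLO-format label files.

Embeddings and CBAM weights are stored as flat named-array archives (NPZ):
the embedding archive holds a single `embeddings` matrix with one unit-norm
row per detection-CSV row in file order; the weight archive holds
`mlp_hidden` (C/r × C), `mlp_out` (C × C/r), `reduction_ratio`,
`spatial_kernel` (7×7×2 over the [mean; max] pooling stack), and
`spatial_bias`.

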