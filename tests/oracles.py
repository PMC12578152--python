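"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's geometry and metrics code paths:
box overlap comes from shapely polygon areas, the CLEAR accounting is a
separate direct transcription of the protocol, and IDF1 is computed by
exhaustive enumeration of identity bijections.
"""

import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment
from shapely.geometry import box as shp_box


def shapely_iou(row_a, row_b):
    """IoU of two (left, top, w, h) boxes via polygon areas."""
    a = shp_box(row_a[0], row_a[1], row_a[0] + row_a[2], row_a[1] + row_a[3])
    b = shp_box(row_b[0], row_b[1], row_b[0] + row_b[2], row_b[1] + row_b[3])
    inter = a.intersection(b).area
    union = a.union(b).area
    return inter / union if union > 0 else 0.0


def _frame_dict(df):
    out = {}
    for f, sub in df.groupby("frame"):
        out[int(f)] = [
            (int(r.id), (r.left, r.top, r.w, r.h)) for r in sub.itertuples(index=False)
        ]
    return out


def reference_clear_mot(gt, hyp, iou_thr=0.5):
    """Direct CLEAR-MOT transcription: persistent pairs, Hungarian on the
    rest, gt-centric switch counting.  Returns a plain dict of counts."""
    gt_frames, hyp_frames = _frame_dict(gt), _frame_dict(hyp)
    fp = fn = idsw = matches = 0
    iou_sum = 0.0
    last = {}   # gt id -> last matched hyp id (ever)
    prev = {}   # gt id -> hyp id matched in the previous frame
    for f in sorted(set(gt_frames) | set(hyp_frames)):
        g = gt_frames.get(f, [])
        h = hyp_frames.get(f, [])
        overlaps = np.array([[shapely_iou(gb, hb) for _, hb in h] for _, gb in g])
        paired_g, paired_h, pairs = set(), set(), []
        # persistence of still-overlapping previous pairs
        for gi, (g_id, _) in enumerate(g):
            h_id = prev.get(g_id)
            if h_id is None:
                continue
            for hi, (hh_id, _) in enumerate(h):
                if hh_id == h_id and overlaps[gi, hi] >= iou_thr:
                    pairs.append((gi, hi))
                    paired_g.add(gi)
                    paired_h.add(hi)
                    break
        free_g = [i for i in range(len(g)) if i not in paired_g]
        free_h = [i for i in range(len(h)) if i not in paired_h]
        if free_g and free_h:
            cost = np.ones((len(free_g), len(free_h)))
            for a, gi in enumerate(free_g):
                for b, hi in enumerate(free_h):
                    if overlaps[gi, hi] >= iou_thr:
                        cost[a, b] = 1.0 - overlaps[gi, hi]
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if overlaps[free_g[a], free_h[b]] >= iou_thr:
                    pairs.append((free_g[a], free_h[b]))
        new_prev = {}
        for gi, hi in pairs:
            g_id, h_id = g[gi][0], h[hi][0]
            matches += 1
            iou_sum += overlaps[gi, hi]
            if g_id in last and last[g_id] != h_id:
                idsw += 1
            last[g_id] = h_id
            new_prev[g_id] = h_id
        fn += len(g) - len(pairs)
        fp += len(h) - len(pairs)
        prev = new_prev
    num_gt = len(gt)
    return {
        "mota": 100.0 * (1.0 - (fn + fp + idsw) / num_gt),
        "motp": 100.0 * iou_sum / matches if matches else 0.0,
        "ids": idsw,
        "fp": fp,
        "fn": fn,
    }


def reference_idf1(gt, hyp, iou_thr=0.5):
    """IDF1 by exhaustive enumeration of injective identity mappings."""
    gt_frames, hyp_frames = _frame_dict(gt), _frame_dict(hyp)
    gt_ids = sorted({int(i) for i in gt["id"]})
    hyp_ids = sorted({int(i) for i in hyp["id"]})
    m = {}
    for f, g in gt_frames.items():
        for g_id, gb in g:
            for h_id, hb in hyp_frames.get(f, []):
                if shapely_iou(gb, hb) >= iou_thr:
                    m[(g_id, h_id)] = m.get((g_id, h_id), 0) + 1
    small, large, flip = (gt_ids, hyp_ids, False) if len(gt_ids) <= len(hyp_ids) else (hyp_ids, gt_ids, True)
    best = 0
    for perm in itertools.permutations(large, len(small)):
        total = 0
        for s, l in zip(small, perm):
            key = (l, s) if flip else (s, l)
            total += m.get(key, 0)
        best = max(best, total)
    idtp = best
    idfn = len(gt) - idtp
    idfp = len(hyp) - idtp
    return 100.0 * 2 * idtp / (2 * idtp + idfp + idfn)
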