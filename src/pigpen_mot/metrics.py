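"""CLEAR-MOT and identity metrics for trajectory files.

Trajectories are pandas DataFrames with columns ``frame, id, left, top, w,
h`` (1-based frames, top-left box form, the MOTChallenge layout).  The
evaluation follows the CLEAR-MOT protocol: per frame, ground-truth/
hypothesis pairs from the previous frame that still overlap at least
``iou_thr`` are kept, the rest are matched by minimum-cost assignment on
1 - IoU; misses, false positives and identity switches accumulate into

    MOTA = 100 * (1 - (FN + FP + IDs) / num_gt)

MOTP is reported as the mean IoU of matched pairs in percent (the overlap
form).  IDF1 uses the global one-to-one assignment between ground-truth and
hypothesis identities that maximizes identity true positives.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import iou_matrix
from .matching import hungarian_assign

__all__ = ["MotReport", "frame_correspondence", "clear_mot", "idf1", "compare_runs"]

TRAJECTORY_COLUMNS = ["frame", "id", "left", "top", "w", "h"]


@dataclass(frozen=True)
class MotReport:
    """Evaluation summary; percentages on the 0-100 scale."""

    mota: float
    motp: float
    idf1: float
    ids: int
    rcll: float
    prcn: float
    fp: int
    fn: int
    num_gt: int
    num_matches: int

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_trajectory(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns {missing}")
    if df.duplicated(subset=["frame", "id"]).any():
        raise ValueError(f"{name} has duplicate (frame, id) pairs")
    if (df["w"] <= 0).any() or (df["h"] <= 0).any():
        raise ValueError(f"{name} contains boxes with non-positive width or height")
    return df


def frame_correspondence(
    gt_boxes: np.ndarray,
    hyp_boxes: np.ndarray,
    prev_matches: list[tuple[int, int]],
    iou_thr: float = 0.5,
) -> list[tuple[int, int]]:
    """One frame of gt/hyp correspondence under the CLEAR-MOT protocol.

    ``prev_matches`` are (gt_index, hyp_index) pairs — indices into the
    current frame's arrays — whose identities were paired in the previous
    frame; such pairs persist whenever they still overlap at ``iou_thr``,
    taking precedence over any fresh assignment.  The remainder is matched
    by minimum-cost assignment on 1 - IoU, rejecting pairs below threshold.
    """
    n_gt, n_hyp = len(gt_boxes), len(hyp_boxes)
    if n_gt == 0 or n_hyp == 0:
        return []
    overlaps = iou_matrix(gt_boxes, hyp_boxes)
    matches: list[tuple[int, int]] = []
    used_gt, used_hyp = set(), set()
    for g, h in prev_matches:
        if g in used_gt or h in used_hyp:
            continue
        if overlaps[g, h] >= iou_thr:
            matches.append((g, h))
            used_gt.add(g)
            used_hyp.add(h)
    free_gt = [g for g in range(n_gt) if g not in used_gt]
    free_hyp = [h for h in range(n_hyp) if h not in used_hyp]
    if free_gt and free_hyp:
        cost = 1.0 - overlaps[np.ix_(free_gt, free_hyp)]
        fresh, _, _ = hungarian_assign(cost, 1.0 - iou_thr)
        matches.extend((free_gt[r], free_hyp[c]) for r, c in fresh)
    return sorted(matches)


def _frames_index(df: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {int(f): sub for f, sub in df.groupby("frame")}


def clear_mot(gt: pd.DataFrame, hyp: pd.DataFrame, iou_thr: float = 0.5) -> MotReport:
    """Full CLEAR-MOT evaluation of a hypothesis against ground truth."""
    gt = _validate_trajectory(gt, "ground truth")
    hyp = _validate_trajectory(hyp, "hypothesis")
    if len(gt) == 0:
        raise ValueError("ground truth is empty")

    gt_frames = _frames_index(gt)
    hyp_frames = _frames_index(hyp)
    all_frames = sorted(set(gt_frames) | set(hyp_frames))

    fp = fn = ids = num_matches = 0
    iou_sum = 0.0
    last_hyp_for_gt: dict[int, int] = {}  # gt id -> last matched hyp id
    prev_pairs: dict[int, int] = {}  # gt id -> hyp id matched in previous frame

    for frame in all_frames:
        g = gt_frames.get(frame)
        h = hyp_frames.get(frame)
        g_ids = g["id"].to_numpy(dtype=int) if g is not None else np.array([], dtype=int)
        h_ids = h["id"].to_numpy(dtype=int) if h is not None else np.array([], dtype=int)
        g_boxes = g[["left", "top", "w", "h"]].to_numpy(dtype=float) if g is not None else np.zeros((0, 4))
        h_boxes = h[["left", "top", "w", "h"]].to_numpy(dtype=float) if h is not None else np.zeros((0, 4))

        gi = {int(v): k for k, v in enumerate(g_ids)}
        hi = {int(v): k for k, v in enumerate(h_ids)}
        carried = [
            (gi[g_id], hi[h_id])
            for g_id, h_id in prev_pairs.items()
            if g_id in gi and h_id in hi
        ]
        pairs = frame_correspondence(g_boxes, h_boxes, carried, iou_thr)

        overlaps = iou_matrix(g_boxes, h_boxes) if len(g_boxes) and len(h_boxes) else None
        frame_pairs: dict[int, int] = {}
        for gidx, hidx in pairs:
            g_id, h_id = int(g_ids[gidx]), int(h_ids[hidx])
            frame_pairs[g_id] = h_id
            num_matches += 1
            iou_sum += overlaps[gidx, hidx]
            if g_id in last_hyp_for_gt and last_hyp_for_gt[g_id] != h_id:
                ids += 1
            last_hyp_for_gt[g_id] = h_id
        fn += len(g_boxes) - len(pairs)
        fp += len(h_boxes) - len(pairs)
        prev_pairs = frame_pairs

    num_gt = len(gt)
    mota = 100.0 * (1.0 - (fn + fp + ids) / num_gt)
    if num_matches == 0:
        warnings.warn("no matched pairs; MOTP undefined, reported as 0", stacklevel=2)
        motp = 0.0
    else:
        motp = 100.0 * iou_sum / num_matches
    rcll = 100.0 * (num_gt - fn) / num_gt
    num_hyp = len(hyp)
    prcn = 100.0 * num_matches / num_hyp if num_hyp else 0.0
    return MotReport(
        mota=float(mota),
        motp=float(motp),
        idf1=float(idf1(gt, hyp, iou_thr)),
        ids=int(ids),
        rcll=float(rcll),
        prcn=float(prcn),
        fp=int(fp),
        fn=int(fn),
        num_gt=int(num_gt),
        num_matches=int(num_matches),
    )


def idf1(gt: pd.DataFrame, hyp: pd.DataFrame, iou_thr: float = 0.5) -> float:
    """Identity F1 in percent under the optimal global id-to-id assignment.

    For every (gt id, hyp id) pair, the number of frames where both are
    present and overlap at least ``iou_thr`` counts as potential identity
    true positives; a minimum-cost assignment over identities (with
    unmatched identities allowed) maximizes total IDTP, and

        IDF1 = 100 * 2 IDTP / (2 IDTP + IDFP + IDFN).
    """
    gt = _validate_trajectory(gt, "ground truth")
    hyp = _validate_trajectory(hyp, "hypothesis")
    if len(gt) == 0:
        raise ValueError("ground truth is empty")
    if len(hyp) == 0:
        return 0.0

    gt_ids = sorted(gt["id"].unique())
    hyp_ids = sorted(hyp["id"].unique())
    gt_len = gt["id"].value_counts().to_dict()
    hyp_len = hyp["id"].value_counts().to_dict()

    # overlap frame counts per (gt id, hyp id)
    binary = np.zeros((len(gt_ids), len(hyp_ids)))
    g_pos = {v: i for i, v in enumerate(gt_ids)}
    h_pos = {v: i for i, v in enumerate(hyp_ids)}
    hyp_frames = _frames_index(hyp)
    for frame, g in gt.groupby("frame"):
        h = hyp_frames.get(int(frame))
        if h is None:
            continue
        overlaps = iou_matrix(
            g[["left", "top", "w", "h"]].to_numpy(dtype=float),
            h[["left", "top", "w", "h"]].to_numpy(dtype=float),
        )
        gi = g["id"].to_numpy(dtype=int)
        hj = h["id"].to_numpy(dtype=int)
        rows, cols = np.nonzero(overlaps >= iou_thr)
        for r, c in zip(rows, cols):
            binary[g_pos[int(gi[r])], h_pos[int(hj[c])]] += 1

    # padded square cost: matching (g, h) costs the induced IDFP + IDFN
    n_g, n_h = len(gt_ids), len(hyp_ids)
    size = n_g + n_h
    big = float(sum(gt_len.values()) + sum(hyp_len.values()) + 1)
    cost = np.full((size, size), big)
    for i, g_id in enumerate(gt_ids):
        cost[i, n_h:] = gt_len[g_id]  # leave gt id unmatched
        for j, h_id in enumerate(hyp_ids):
            cost[i, j] = gt_len[g_id] + hyp_len[h_id] - 2.0 * binary[i, j]
    for j, h_id in enumerate(hyp_ids):
        cost[n_g:, j] = hyp_len[h_id]  # leave hyp id unmatched
    cost[n_g:, n_h:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    idtp = sum(
        binary[r, c] for r, c in zip(rows, cols) if r < n_g and c < n_h
    )
    idfn = sum(gt_len.values()) - idtp
    idfp = sum(hyp_len.values()) - idtp
    return 100.0 * 2.0 * idtp / (2.0 * idtp + idfp + idfn)


def compare_runs(
    gt: pd.DataFrame,
    hyp_baseline: pd.DataFrame,
    hyp_improved: pd.DataFrame,
    iou_thr: float = 0.5,
) -> dict:
    """Evaluate two hypothesis runs against the same ground truth.

    Returns ``{"baseline": ..., "improved": ..., "delta": ...}`` where delta
    is improved minus baseline per metric.
    """
    base = clear_mot(gt, hyp_baseline, iou_thr)
    impr = clear_mot(gt, hyp_improved, iou_thr)
    delta = {
        k: impr.to_dict()[k] - base.to_dict()[k]
        for k in ("mota", "motp", "idf1", "ids", "rcll", "prcn", "fp", "fn")
    }
    return {"baseline": base.to_dict(), "improved": impr.to_dict(), "delta": delta}


def format_comparison(result: dict) -> str:
    """Pretty side-by-side table of a :func:`compare_runs` result."""
    keys = ["idf1", "rcll", "prcn", "ids", "mota", "motp", "fp", "fn"]
    lines = [f"{'metric':>8} {'baseline':>10} {'improved':>10} {'delta':>10}"]
    for k in keys:
        b, i, d = result["baseline"][k], result["improved"][k], result["delta"][k]
        lines.append(f"{k:>8} {b:>10.2f} {i:>10.2f} {d:>+10.2f}")
    return "\n".join(lines)
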