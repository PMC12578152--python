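"""Data association primitives: thresholded Hungarian assignment and costs."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import iou_matrix

__all__ = ["GATED_COST", "hungarian_assign", "cosine_cost_matrix", "iou_cost_matrix"]

# sentinel for infeasible (gated) pairs; large enough never to be accepted
GATED_COST = 1e5


def hungarian_assign(
    cost: np.ndarray, max_cost: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost assignment with a feasibility cap.

    Entries above ``max_cost`` are replaced by a sentinel slightly past the
    cap before solving, so infeasible pairs never distort the optimum; any
    assigned pair whose original cost exceeds ``max_cost`` is discarded to
    the unmatched lists.  Returns (matches, unmatched_rows, unmatched_cols)
    with matches sorted by row index.
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    n_rows, n_cols = cost.shape
    if n_rows == 0 or n_cols == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    capped = np.where(cost > max_cost, max_cost + 1e-5, cost)
    rows, cols = linear_sum_assignment(capped)
    matches: list[tuple[int, int]] = []
    unmatched_rows = set(range(n_rows))
    unmatched_cols = set(range(n_cols))
    for r, c in zip(rows, cols):
        if cost[r, c] <= max_cost:
            matches.append((int(r), int(c)))
            unmatched_rows.discard(int(r))
            unmatched_cols.discard(int(c))
    matches.sort()
    return matches, sorted(unmatched_rows), sorted(unmatched_cols)


def cosine_cost_matrix(galleries: list[np.ndarray], embeddings: np.ndarray) -> np.ndarray:
    """Min cosine distance from each track's embedding gallery to each detection.

    ``galleries[i]`` is an (n_i x d) matrix of unit-norm embeddings;
    ``embeddings`` is (m x d) unit-norm.  Entries lie in [0, 2], in practice
    [0, 1] for non-antipodal features.
    """
    m = embeddings.shape[0]
    out = np.zeros((len(galleries), m))
    for i, g in enumerate(galleries):
        sims = g @ embeddings.T  # n_i x m
        out[i] = 1.0 - sims.max(axis=0)
    return out


def iou_cost_matrix(track_tlwh: np.ndarray, det_tlwh: np.ndarray) -> np.ndarray:
    """1 - IoU cost between predicted track boxes and detection boxes."""
    return 1.0 - iou_matrix(track_tlwh, det_tlwh)
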