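"""DeepSORT-style multi-object tracker with population-capped track creation.

Track management follows the classic DeepSORT lifecycle — tentative tracks
confirm after ``n_init`` consecutive hits, confirmed tracks die after
``max_age`` frames without a matched update — with two additions aimed at
group-housed animal pens where the true population is effectively constant:

* a second round of IoU matching between all still-unmatched tracks and
  detections, recovering targets lost to short occlusions or bursts of fast
  motion that defeat the appearance cascade;
* a population cap on track creation: after the first frame, a new track is
  created from an unmatched detection only while the number of live
  (non-deleted) tracks is below ``n``, the rounded mean detection count of
  the most recent ``cap_window`` frames.  This stops identity inflation from
  spurious detections.

Both additions are switchable so the tracker can run as a plain DeepSORT
baseline for A/B comparison.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .geometry import Box
from .kalman import CHI2_95_4DOF, KalmanFilter, KalmanState
from .matching import GATED_COST, cosine_cost_matrix, hungarian_assign, iou_cost_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "BEHAVIORS",
    "Detection",
    "TrackState",
    "Track",
    "TrackerConfig",
    "PopulationEstimate",
    "TrackOutput",
    "Tracker",
]

BEHAVIORS = ("stand", "lie", "eat", "attack")

_GALLERY_BUDGET = 100


@dataclass(frozen=True)
class Detection:
    """One per-frame observation handed to the tracker."""

    frame: int
    box: Box
    confidence: float = 1.0
    behavior: str = "stand"
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError("frame numbers are 1-based")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}; expected one of {BEHAVIORS}")
        if self.embedding is not None:
            e = np.asarray(self.embedding, dtype=float)
            n = np.linalg.norm(e)
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"embedding must be unit-norm, got |e| = {n}")
            object.__setattr__(self, "embedding", e)

    def to_xyah(self) -> np.ndarray:
        """Measurement vector (cx, cy, aspect, h) for the Kalman filter."""
        b = self.box
        return np.array([b.cx, b.cy, b.w / b.h, b.h])


class TrackState(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackerConfig:
    """Knobs of the tracker; defaults give the improved mode.

    ``max_age`` is the number of frames a confirmed track survives without a
    matched update; ``n_init`` the consecutive hits needed to confirm;
    ``gating_chi2`` the squared-Mahalanobis gate (0.95 chi-square quantile,
    4 dof).  IoU thresholds are caps on the 1-IoU assignment cost.
    """

    max_age: int = 30
    n_init: int = 3
    max_cosine_distance: float = 0.2
    iou_threshold_round1: float = 0.7
    iou_threshold_round2: float = 0.85
    gating_chi2: float = CHI2_95_4DOF
    cap_window: int = 3
    cap_enabled: bool = True
    second_round_enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.max_age, self.n_init, self.cap_window) < 1:
            raise ValueError("max_age, n_init and cap_window must be >= 1")
        for name in ("max_cosine_distance", "iou_threshold_round1", "iou_threshold_round2", "gating_chi2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def baseline(cls, **overrides) -> "TrackerConfig":
        """Plain DeepSORT: no population cap, no second IoU round."""
        overrides.setdefault("cap_enabled", False)
        overrides.setdefault("second_round_enabled", False)
        return cls(**overrides)


class Track:
    """A tracked identity: Kalman state, lifecycle counters, appearance gallery."""

    def __init__(self, track_id: int, kalman: KalmanState, detection: Detection, n_init: int) -> None:
        self.id = track_id
        self.state = TrackState.TENTATIVE
        self.kalman = kalman
        self.hits = 1
        self.age = 1
        self.time_since_update = 0
        self.gallery: deque[np.ndarray] = deque(maxlen=_GALLERY_BUDGET)
        self.behavior_history: deque[str] = deque(maxlen=_GALLERY_BUDGET)
        self._n_init = n_init
        if detection.embedding is not None:
            self.gallery.append(detection.embedding)
        self.behavior_history.append(detection.behavior)

    def predict(self, kf: KalmanFilter) -> None:
        self.kalman = kf.predict(self.kalman)
        self.age += 1
        self.time_since_update += 1

    def update(self, kf: KalmanFilter, detection: Detection) -> None:
        self.kalman = kf.update(self.kalman, detection.to_xyah())
        self.hits += 1
        self.time_since_update = 0
        if detection.embedding is not None:
            self.gallery.append(detection.embedding)
        self.behavior_history.append(detection.behavior)
        if self.state is TrackState.TENTATIVE and self.hits >= self._n_init:
            self.state = TrackState.CONFIRMED

    def mark_missed(self, max_age: int) -> None:
        if self.state is TrackState.TENTATIVE:
            self.state = TrackState.DELETED
        elif self.time_since_update > max_age:
            self.state = TrackState.DELETED

    def behavior(self, window: int) -> str:
        """Majority label of the last ``window`` assigned detections."""
        recent = list(self.behavior_history)[-window:]
        # ties broken by most recent occurrence
        best, best_count = recent[-1], 0
        for label in BEHAVIORS:
            c = recent.count(label)
            if c > best_count:
                best, best_count = label, c
        return best

    def to_tlwh(self) -> np.ndarray:
        cx, cy, a, h = self.kalman.mean[:4]
        w = a * h
        return np.array([cx - w / 2.0, cy - h / 2.0, w, h])

    @property
    def is_confirmed(self) -> bool:
        return self.state is TrackState.CONFIRMED

    @property
    def is_deleted(self) -> bool:
        return self.state is TrackState.DELETED


class PopulationEstimate:
    """Rounded mean of per-frame detection counts over a short ring buffer."""

    def __init__(self, window: int = 3) -> None:
        if window < 1:
            raise ValueError("window must be >= 1")
        self.history: deque[int] = deque(maxlen=window)

    def push(self, count: int) -> None:
        self.history.append(int(count))

    @property
    def n(self) -> int:
        if not self.history:
            return 0
        return population_estimate(list(self.history))


def population_estimate(counts: list[int]) -> int:
    """Round-half-up mean of recent detection counts; 0 for an empty list."""
    if not counts:
        return 0
    return int(math.floor(sum(counts) / len(counts) + 0.5))


@dataclass(frozen=True)
class TrackOutput:
    """One emitted row: a confirmed track updated in the current frame."""

    track_id: int
    box: Box
    state: str
    behavior: str
    confidence: float = 1.0


@dataclass
class Tracker:
    """Frame-by-frame tracking driver; call :meth:`step` once per frame."""

    config: TrackerConfig = field(default_factory=TrackerConfig)

    def __post_init__(self) -> None:
        self.kf = KalmanFilter()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._population = PopulationEstimate(self.config.cap_window)
        self._last_frame = 0
        self._first_frame_seen = False
        self._warned_no_embeddings = False

    # -- association stages -------------------------------------------------

    def _appearance_cost(self, tracks: list[Track], detections: list[Detection]) -> np.ndarray:
        """Gallery cosine cost with chi-square Mahalanobis gating.

        Tracks without gallery entries or detections without embeddings fall
        back to Mahalanobis-gated IoU cost for the affected rows.
        """
        have_embeddings = all(d.embedding is not None for d in detections) and all(
            len(t.gallery) > 0 for t in tracks
        )
        if have_embeddings:
            cost = cosine_cost_matrix(
                [np.stack(t.gallery) for t in tracks],
                np.stack([d.embedding for d in detections]),
            )
        else:
            if not self._warned_no_embeddings:
                logger.info("no appearance embeddings available; cascade uses gated IoU cost")
                self._warned_no_embeddings = True
            cost = iou_cost_matrix(
                np.stack([t.to_tlwh() for t in tracks]),
                np.stack([d.box.to_tlwh() for d in detections]),
            )
        measurements = np.stack([d.to_xyah() for d in detections])
        for i, t in enumerate(tracks):
            gate = self.kf.gating_distance(t.kalman, measurements) > self.config.gating_chi2
            cost[i, gate] = GATED_COST
        return cost

    def _cascade_match(
        self, tracks: list[int], detections: list[Detection]
    ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
        """Staleness-ordered appearance matching over confirmed tracks.

        Track groups with smaller ``time_since_update`` are matched first, so
        recently seen animals keep priority over long-occluded ones.
        """
        have_embeddings = all(d.embedding is not None for d in detections)
        max_cost = self.config.max_cosine_distance if have_embeddings else self.config.iou_threshold_round1
        unmatched_dets = list(range(len(detections)))
        matches: list[tuple[int, int]] = []
        for staleness in range(1, self.config.max_age + 1):
            if not unmatched_dets:
                break
            level = [i for i in tracks if self.tracks[i].time_since_update == staleness]
            if not level:
                continue
            cost = self._appearance_cost(
                [self.tracks[i] for i in level], [detections[j] for j in unmatched_dets]
            )
            level_matches, _, unmatched_cols = hungarian_assign(cost, max_cost)
            matches.extend((level[r], unmatched_dets[c]) for r, c in level_matches)
            unmatched_dets = [unmatched_dets[c] for c in unmatched_cols]
        matched_tracks = {t for t, _ in matches}
        unmatched_tracks = [i for i in tracks if i not in matched_tracks]
        return matches, unmatched_tracks, unmatched_dets

    def _iou_match_round(
        self, track_idx: list[int], det_idx: list[int], detections: list[Detection], threshold: float
    ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
        """Hungarian matching on 1-IoU between predicted boxes and detections."""
        if not track_idx or not det_idx:
            return [], track_idx, det_idx
        cost = iou_cost_matrix(
            np.stack([self.tracks[i].to_tlwh() for i in track_idx]),
            np.stack([detections[j].box.to_tlwh() for j in det_idx]),
        )
        raw, un_r, un_c = hungarian_assign(cost, threshold)
        matches = [(track_idx[r], det_idx[c]) for r, c in raw]
        return matches, [track_idx[r] for r in un_r], [det_idx[c] for c in un_c]

    # -- track creation and pruning -----------------------------------------

    def _create_or_drop(self, unmatched: list[Detection], is_first_frame: bool) -> list[Track]:
        """Create tentative tracks from unmatched detections, subject to the cap.

        The first frame seeds one track per detection.  Afterwards, with the
        cap enabled, tracks are created one at a time only while the live
        (non-deleted) track count stays below the population estimate n;
        excess detections are dropped.  With the cap disabled, every
        unmatched detection spawns a track (baseline DeepSORT behavior).
        """
        created: list[Track] = []
        n = self._population.n
        for det in unmatched:
            alive = sum(1 for t in self.tracks if not t.is_deleted)
            if not is_first_frame and self.config.cap_enabled and alive >= n:
                logger.debug(
                    "frame %d: dropped unmatched detection (alive=%d >= n=%d)",
                    det.frame, alive, n,
                )
                continue
            if self.config.cap_enabled and not is_first_frame:
                assert alive < n, "population cap violated at creation time"
            track = Track(self._next_id, self.kf.initiate(det.to_xyah()), det, self.config.n_init)
            self._next_id += 1
            self.tracks.append(track)
            created.append(track)
        return created

    def _prune(self) -> None:
        self.tracks = [t for t in self.tracks if not t.is_deleted]

    # -- main loop -----------------------------------------------------------

    def step(self, detections: list[Detection]) -> list[TrackOutput]:
        """Advance one frame and return confirmed tracks updated this frame."""
        if detections:
            frames = {d.frame for d in detections}
            if len(frames) > 1:
                raise ValueError(f"detections from multiple frames in one step: {sorted(frames)}")
            frame = frames.pop()
            if frame <= self._last_frame:
                raise ValueError(f"frames must be strictly increasing, got {frame} after {self._last_frame}")
            self._last_frame = frame
        else:
            self._last_frame += 1

        for t in self.tracks:
            t.predict(self.kf)

        confirmed = [i for i, t in enumerate(self.tracks) if t.is_confirmed]
        tentative = [i for i, t in enumerate(self.tracks) if t.state is TrackState.TENTATIVE]

        # stage 1: appearance cascade over confirmed tracks
        if confirmed and detections:
            cascade_matches, cascade_unmatched, unmatched_dets = self._cascade_match(confirmed, detections)
        else:
            cascade_matches, cascade_unmatched = [], confirmed
            unmatched_dets = list(range(len(detections)))

        # stage 2, round 1: IoU matching for tentative tracks and tracks that
        # just fell out of the cascade (missed exactly one frame)
        round1_tracks = tentative + [i for i in cascade_unmatched if self.tracks[i].time_since_update == 1]
        round1_matches, round1_unmatched, unmatched_dets = self._iou_match_round(
            sorted(round1_tracks), unmatched_dets, detections, self.config.iou_threshold_round1
        )

        # stage 2, round 2: all remaining unmatched tracks get an IoU chance,
        # recovering targets lost to short occlusions
        round2_matches: list[tuple[int, int]] = []
        remaining_tracks = sorted(
            set(round1_unmatched) | {i for i in cascade_unmatched if self.tracks[i].time_since_update > 1}
        )
        if self.config.second_round_enabled:
            round2_matches, remaining_tracks, unmatched_dets = self._iou_match_round(
                remaining_tracks, unmatched_dets, detections, self.config.iou_threshold_round2
            )

        for track_i, det_j in cascade_matches + round1_matches + round2_matches:
            self.tracks[track_i].update(self.kf, detections[det_j])
        for track_i in remaining_tracks:
            self.tracks[track_i].mark_missed(self.config.max_age)

        # stage 3: population-capped creation, then pruning
        self._population.push(len(detections))
        is_first = not self._first_frame_seen
        self._first_frame_seen = True
        self._create_or_drop([detections[j] for j in unmatched_dets], is_first)
        self._prune()

        out: list[TrackOutput] = []
        for t in self.tracks:
            if t.is_confirmed and t.time_since_update == 0:
                left, top, w, h = t.to_tlwh()
                out.append(TrackOutput(
                    track_id=t.id,
                    box=Box(left + w / 2.0, top + h / 2.0, w, h),
                    state=t.state.value,
                    behavior=t.behavior(self.config.cap_window),
                ))
        out.sort(key=lambda r: r.track_id)
        return out

    def run(self, frames: dict[int, list[Detection]]) -> dict[int, list[TrackOutput]]:
        """Track a whole sequence: mapping frame -> detections, in frame order."""
        results: dict[int, list[TrackOutput]] = {}
        for frame in sorted(frames):
            results[frame] = self.step(frames[frame])
        return results
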