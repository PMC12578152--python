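"""Synthetic group-housed pig pen: ground-truth trajectories + noisy detections.

The simulator emulates overhead pen footage at 25 fps in a 2688 x 1520 px
arena: 7-16 pigs move as a bounded random walk whose step length depends on
the behavior state (stand / lie / eat / attack, with lying pigs immobile),
behavior evolves as a first-order Markov chain, and attacks are paired
pursuit bursts in which two pigs move rapidly toward each other for a
geometric-length episode.  A degradation stage turns the ground truth into
a detector-like stream: occluded boxes dropped, survivors jittered,
Poisson-distributed false positives added, behavior classes confused, and a
night mode that inflates the miss rate.  Per-identity appearance vectors
with additive noise stand in for Re-ID CNN embeddings.

Everything is driven by one seeded RNG consumed in fixed order (motion,
behavior, degradation, embeddings per frame), so a scene is exactly
reproducible from its config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Box, iou as _iou
from .tracker import BEHAVIORS, Detection

__all__ = [
    "PenConfig",
    "PenScene",
    "simulate_pen",
    "behavior_step",
    "degrade",
    "embed_identity",
    "PRESETS",
    "preset",
]


def _default_transition() -> np.ndarray:
    # rows/cols ordered (stand, lie, eat, attack); sticky states.  Attack is
    # a paired interaction, so the default chain never self-initiates it —
    # attack episodes start via attack_pairing; the attack row only governs
    # decay for user-supplied matrices that do enter the state.
    return np.array([
        [0.96, 0.02, 0.02, 0.00],
        [0.03, 0.96, 0.01, 0.00],
        [0.04, 0.01, 0.95, 0.00],
        [0.30, 0.00, 0.00, 0.70],
    ])


def _default_confusion() -> np.ndarray:
    return np.eye(4)


def _default_speeds() -> dict[str, float]:
    return {"stand": 12.0, "lie": 0.0, "eat": 4.0, "attack": 40.0}


@dataclass(frozen=True)
class PenConfig:
    """Scene parameters; defaults describe a daytime pen of 16 animals."""

    arena_w: float = 2688.0
    arena_h: float = 1520.0
    n_pigs: int = 16
    n_frames: int = 500
    fps: float = 25.0
    behavior_transition: np.ndarray = field(default_factory=_default_transition)
    speed_px: dict[str, float] = field(default_factory=_default_speeds)
    attack_pairing: float = 0.01
    motion_smoothness: float = 0.95  # AR(1) coefficient of the velocity process
    body_w: float = 260.0
    body_h: float = 130.0
    body_jitter: float = 0.15
    occlusion_iou: float = 0.3
    occlusion_drop_p: float = 0.7
    exclusion: float = 0.55
    miss_p: float = 0.02
    night: bool = False
    night_miss_multiplier: float = 2.5
    fp_rate: float = 0.05
    jitter_sigma: float = 3.0
    class_confusion: np.ndarray = field(default_factory=_default_confusion)
    embed_dim: int = 32
    embed_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pigs <= 0:
            raise ValueError("n_pigs must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.arena_w <= 2 * self.body_w or self.arena_h <= 2 * self.body_h:
            raise ValueError("arena too small for the configured body size")
        for mat, name in ((self.behavior_transition, "behavior_transition"),
                          (self.class_confusion, "class_confusion")):
            m = np.asarray(mat, dtype=float)
            if m.shape != (4, 4) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9) or (m < 0).any():
                raise ValueError(f"{name} must be a 4x4 row-stochastic matrix")
        for p_name in ("attack_pairing", "occlusion_drop_p", "miss_p"):
            if not 0.0 <= getattr(self, p_name) <= 1.0:
                raise ValueError(f"{p_name} must lie in [0, 1]")
        if self.night_miss_multiplier < 1.0:
            raise ValueError("night_miss_multiplier must be >= 1")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")

    @property
    def effective_miss_p(self) -> float:
        p = self.miss_p * (self.night_miss_multiplier if self.night else 1.0)
        return min(p, 1.0)


@dataclass
class PenScene:
    """Simulator output: ground truth, degraded detections, identity features."""

    gt: pd.DataFrame  # frame, id, left, top, w, h, behavior
    detections: dict[int, list[Detection]]
    identity_embeddings: np.ndarray  # n_pigs x embed_dim
    config: PenConfig

    def gt_trajectory(self) -> pd.DataFrame:
        """Ground truth in the plain evaluation layout (no behavior column)."""
        return self.gt[["frame", "id", "left", "top", "w", "h"]].copy()


def behavior_step(state: int, transition: np.ndarray, rng: np.random.Generator) -> int:
    """One Markov-chain step over behavior indices (stand, lie, eat, attack)."""
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (4, 4) or not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition must be a 4x4 row-stochastic matrix")
    return int(rng.choice(4, p=transition[state]))


def embed_identity(identity: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    """Per-frame appearance vector: normalize(identity + N(0, noise))."""
    v = identity + rng.normal(0.0, noise, identity.shape) if noise > 0 else identity.copy()
    return v / np.linalg.norm(v)


def _identity_matrix(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(0.0, 1.0, (n, dim))
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def degrade(
    frame: int,
    boxes: list[Box],
    behaviors: list[int],
    identities: np.ndarray,
    cfg: PenConfig,
    rng: np.random.Generator,
) -> list[Detection]:
    """Turn one frame of ground truth into a noisy detection stream.

    Occlusion: for every pair with IoU above ``occlusion_iou`` the box with
    the smaller bottom-edge y (the farther-from-camera proxy under an
    overhead oblique view) is dropped with ``occlusion_drop_p``.  Survivors
    are independently missed with the (night-adjusted) miss probability and
    jittered; Poisson false positives carry no matching identity.
    """
    n = len(boxes)
    dropped = np.zeros(n, dtype=bool)
    # occlusion pass (fixed i<j order for reproducibility)
    for i in range(n):
        for j in range(i + 1, n):
            if dropped[i] or dropped[j]:
                continue
            if _iou(boxes[i], boxes[j]) > cfg.occlusion_iou:
                rear = i if boxes[i].cy < boxes[j].cy else j
                if rng.random() < cfg.occlusion_drop_p:
                    dropped[rear] = True
    detections: list[Detection] = []
    miss_p = cfg.effective_miss_p
    for i in range(n):
        if dropped[i] or (miss_p > 0 and rng.random() < miss_p):
            continue
        b = boxes[i]
        dx, dy, dw, dh = rng.normal(0.0, cfg.jitter_sigma, 4) if cfg.jitter_sigma > 0 else (0, 0, 0, 0)
        w = max(b.w + dw, 4.0)
        h = max(b.h + dh, 4.0)
        cls = int(rng.choice(4, p=np.asarray(cfg.class_confusion, dtype=float)[behaviors[i]]))
        emb = embed_identity(identities[i], cfg.embed_noise, rng)
        detections.append(Detection(
            frame=frame,
            box=Box(b.cx + dx, b.cy + dy, w, h),
            confidence=float(np.clip(rng.normal(0.9, 0.05), 0.05, 1.0)),
            behavior=BEHAVIORS[cls],
            embedding=emb,
        ))
    n_fp = rng.poisson(cfg.fp_rate) if cfg.fp_rate > 0 else 0
    for _ in range(n_fp):
        w = cfg.body_w * (1 + cfg.body_jitter * rng.normal())
        h = cfg.body_h * (1 + cfg.body_jitter * rng.normal())
        w, h = max(w, 10.0), max(h, 10.0)
        cx = rng.uniform(w / 2, cfg.arena_w - w / 2)
        cy = rng.uniform(h / 2, cfg.arena_h - h / 2)
        fake = _identity_matrix(1, cfg.embed_dim, rng)[0]
        detections.append(Detection(
            frame=frame,
            box=Box(cx, cy, w, h),
            confidence=float(np.clip(rng.normal(0.4, 0.1), 0.05, 1.0)),
            behavior=BEHAVIORS[int(rng.integers(4))],
            embedding=fake,
        ))
    return detections


def simulate_pen(cfg: PenConfig) -> PenScene:
    """Generate a full scene; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pigs

    identities = _identity_matrix(n, cfg.embed_dim, rng)
    # body sizes fixed per animal
    bw = cfg.body_w * (1 + cfg.body_jitter * rng.standard_normal(n))
    bh = cfg.body_h * (1 + cfg.body_jitter * rng.standard_normal(n))
    bw = np.clip(bw, 40.0, None)
    bh = np.clip(bh, 20.0, None)

    # place animals without initial overlap (rejection sampling per animal)
    pos = np.zeros((n, 2))
    for i in range(n):
        for _ in range(200):
            cand = np.array([
                rng.uniform(bw[i] / 2, cfg.arena_w - bw[i] / 2),
                rng.uniform(bh[i] / 2, cfg.arena_h - bh[i] / 2),
            ])
            ok = all(
                abs(cand[0] - pos[j, 0]) >= cfg.exclusion * (bw[i] + bw[j]) / 2
                or abs(cand[1] - pos[j, 1]) >= cfg.exclusion * (bh[i] + bh[j]) / 2
                for j in range(i)
            )
            if ok:
                break
        pos[i] = cand
    behavior = rng.integers(0, 3, n)  # start in stand/lie/eat
    attack_partner = np.full(n, -1)  # paired pursuit target, -1 = none
    attack_left = np.zeros(n, dtype=int)
    velocity = np.zeros((n, 2))  # smooth per-animal velocity (px/frame)

    rows = []
    detections: dict[int, list[Detection]] = {}
    speeds = [cfg.speed_px.get(b, 0.0) for b in BEHAVIORS]

    for frame in range(1, cfg.n_frames + 1):
        # -- behavior dynamics ------------------------------------------------
        for i in range(n):
            if attack_partner[i] >= 0:
                attack_left[i] -= 1
                if attack_left[i] <= 0:
                    j = attack_partner[i]
                    attack_partner[i] = -1
                    if j >= 0 and attack_partner[j] == i:
                        attack_partner[j] = -1
                        behavior[j] = 0
                    behavior[i] = 0
            else:
                behavior[i] = behavior_step(int(behavior[i]), cfg.behavior_transition, rng)
        # initiate paired attacks
        if cfg.attack_pairing > 0 and rng.random() < cfg.attack_pairing:
            free = [i for i in range(n) if attack_partner[i] < 0]
            if len(free) >= 2:
                a, b = rng.choice(free, size=2, replace=False)
                burst = 1 + rng.geometric(0.1)  # mean ~11 frames at 25 fps
                attack_partner[a], attack_partner[b] = b, a
                attack_left[a] = attack_left[b] = burst
                behavior[a] = behavior[b] = 3

        # -- motion -----------------------------------------------------------
        # velocities follow a mean-reverting (OU) process so frame-to-frame
        # displacement is autocorrelated, as for real animals filmed at 25 fps
        rho = cfg.motion_smoothness
        accel_scale = math.sqrt(1.0 - rho * rho)
        for i in range(n):
            if attack_partner[i] >= 0:
                target = pos[attack_partner[i]]
                d = target - pos[i]
                dist = np.linalg.norm(d)
                velocity[i] = d / dist * speeds[3] if dist > 1.0 else 0.0
            else:
                s = speeds[int(behavior[i])]
                if s > 0:
                    velocity[i] = rho * velocity[i] + rng.normal(0.0, s * accel_scale, 2)
                    speed = np.linalg.norm(velocity[i])
                    if speed > 2.5 * s:
                        velocity[i] *= 2.5 * s / speed
                else:
                    velocity[i] = 0.0
        pos = pos + velocity
        # physical exclusion: animals cannot stack; overlapping non-attacking
        # pairs separate along the least-penetrated axis.  Attacking pairs are
        # exempt so close-contact fights still produce heavy occlusion.
        if cfg.exclusion > 0:
            max_push = 8.0  # px per animal per frame: animals yield, not teleport
            for _ in range(2):
                push = np.zeros((n, 2))
                for i in range(n):
                    for j in range(i + 1, n):
                        if attack_partner[i] == j:
                            continue
                        px = cfg.exclusion * (bw[i] + bw[j]) / 2 - abs(pos[j, 0] - pos[i, 0])
                        py = cfg.exclusion * (bh[i] + bh[j]) / 2 - abs(pos[j, 1] - pos[i, 1])
                        if px > 0 and py > 0:
                            if px <= py:
                                sign = 1.0 if pos[j, 0] >= pos[i, 0] else -1.0
                                push[i, 0] -= sign * px / 2
                                push[j, 0] += sign * px / 2
                            else:
                                sign = 1.0 if pos[j, 1] >= pos[i, 1] else -1.0
                                push[i, 1] -= sign * py / 2
                                push[j, 1] += sign * py / 2
                norms = np.linalg.norm(push, axis=1)
                over = norms > max_push
                push[over] *= (max_push / norms[over])[:, None]
                pos = pos + push
        pos[:, 0] = np.clip(pos[:, 0], bw / 2, cfg.arena_w - bw / 2)
        pos[:, 1] = np.clip(pos[:, 1], bh / 2, cfg.arena_h - bh / 2)

        boxes = [Box(pos[i, 0], pos[i, 1], bw[i], bh[i]) for i in range(n)]
        for i in range(n):
            rows.append((
                frame, i + 1,
                boxes[i].x1, boxes[i].y1, bw[i], bh[i],
                BEHAVIORS[int(behavior[i])],
            ))
        detections[frame] = degrade(frame, boxes, list(map(int, behavior)), identities, cfg, rng)

    gt = pd.DataFrame(rows, columns=["frame", "id", "left", "top", "w", "h", "behavior"])
    return PenScene(gt=gt, detections=detections, identity_embeddings=identities, config=cfg)


def _sparse_day(**over) -> PenConfig:
    base = dict(n_pigs=7, n_frames=300, night=False)
    base.update(over)
    return PenConfig(**base)


def _dense_day(**over) -> PenConfig:
    base = dict(n_pigs=16, n_frames=500, night=False)
    base.update(over)
    return PenConfig(**base)


def _dense_night(**over) -> PenConfig:
    base = dict(n_pigs=16, n_frames=500, night=True, attack_pairing=0.05,
                occlusion_drop_p=0.85)
    base.update(over)
    return PenConfig(**base)


PRESETS = {
    "sparse_day": _sparse_day,
    "dense_day": _dense_day,
    "dense_night": _dense_night,
}


def preset(name: str, **overrides) -> PenConfig:
    """Named scene presets mirroring the sparse/dense, day/night study axes."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**overrides)
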