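"""MOTChallenge-style CSV readers/writers, YOLO labels, embedding archives.

Three CSV dialects are supported, all 1-based in the frame column and all
carrying boxes in (left, top, width, height) pixel form:

* ``det``    — ``frame,id(-1),left,top,w,h,conf,class,vis`` detector output
* ``gt``     — ``frame,id,left,top,w,h,flag,class,vis`` annotated truth
* ``result`` — ``frame,id,left,top,w,h,conf,-1,-1,-1`` tracker output

Internally boxes become center-form :class:`~pigpen_mot.geometry.Box`
objects where object semantics are needed; trajectory-level evaluation uses
plain DataFrames in top-left form.  Floats are written with two decimals,
so writing what was read from a canonical file reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Box, convert_box
from .tracker import BEHAVIORS, Detection, TrackOutput

__all__ = [
    "read_mot",
    "write_mot",
    "read_detections",
    "write_results",
    "read_yolo_labels",
    "save_embeddings",
    "load_embeddings",
    "write_provenance",
]

_DIALECTS = ("det", "gt", "result")


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _parse_row(line: str, lineno: int, path: str) -> list[float]:
    parts = line.strip().split(",")
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed row {line.strip()!r}") from exc
    if len(vals) < 6:
        raise ValueError(f"{path}:{lineno}: expected at least 6 fields, got {len(vals)}")
    if vals[4] <= 0 or vals[5] <= 0:
        raise ValueError(f"{path}:{lineno}: non-positive box size w={vals[4]}, h={vals[5]}")
    if vals[0] < 1:
        raise ValueError(f"{path}:{lineno}: frames are 1-based, got {vals[0]}")
    return vals


def read_mot(path: str | Path, dialect: str = "gt") -> pd.DataFrame:
    """Read a MOTChallenge CSV into a trajectory DataFrame.

    Columns: ``frame, id, left, top, w, h`` plus ``conf`` and ``cls`` for
    the ``det`` dialect.  Malformed rows raise with the offending line
    number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rows.append(_parse_row(line, lineno, str(path)))
    if not rows:
        raise ValueError(f"{path}: empty file")
    width = max(len(r) for r in rows)
    base_cols = ["frame", "id", "left", "top", "w", "h"]
    extra = [f"c{i}" for i in range(6, width)]
    df = pd.DataFrame([r + [np.nan] * (width - len(r)) for r in rows], columns=base_cols + extra)
    df["frame"] = df["frame"].astype(int)
    df["id"] = df["id"].astype(int)
    if dialect == "det" and width >= 8:
        df = df.rename(columns={"c6": "conf", "c7": "cls"})
    return df


def write_mot(path: str | Path, df: pd.DataFrame, dialect: str = "gt") -> None:
    """Write a trajectory DataFrame in the given dialect; two-decimal floats."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            box = ",".join(_fmt(v) for v in (row.left, row.top, row.w, row.h))
            if dialect == "gt":
                fh.write(f"{int(row.frame)},{int(row.id)},{box},1,1,1.00\n")
            elif dialect == "det":
                conf = getattr(row, "conf", 1.0)
                cls = int(getattr(row, "cls", 1))
                fh.write(f"{int(row.frame)},-1,{box},{_fmt(conf)},{cls},1.00\n")
            else:
                conf = getattr(row, "conf", 1.0)
                fh.write(f"{int(row.frame)},{int(row.id)},{box},{_fmt(conf)},-1,-1,-1\n")


def read_detections(
    path: str | Path, embeddings_path: str | Path | None = None
) -> dict[int, list[Detection]]:
    """Read a det-dialect CSV into per-frame Detection lists.

    The optional sidecar archive holds an ``embeddings`` matrix with one
    unit-norm row per CSV row, in file order.
    """
    df = read_mot(path, dialect="det")
    emb = None
    if embeddings_path is not None:
        emb = load_embeddings(embeddings_path)
        if emb.shape[0] != len(df):
            raise ValueError(
                f"embedding rows ({emb.shape[0]}) do not match detection rows ({len(df)})"
            )
    frames: dict[int, list[Detection]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        conf = float(getattr(row, "conf", 1.0))
        cls = getattr(row, "cls", 0)
        cls = int(cls) if pd.notna(cls) else 0
        behavior = BEHAVIORS[cls] if 0 <= cls < len(BEHAVIORS) else "stand"
        det = Detection(
            frame=int(row.frame),
            box=Box.from_tlwh(row.left, row.top, row.w, row.h),
            confidence=min(max(conf, 0.0), 1.0),
            behavior=behavior,
            embedding=None if emb is None else emb[idx],
        )
        frames.setdefault(det.frame, []).append(det)
    return frames


def detections_to_frame(scene_detections: dict[int, list[Detection]]) -> pd.DataFrame:
    """Flatten per-frame Detection lists into a det-dialect DataFrame."""
    rows = []
    for frame in sorted(scene_detections):
        for d in scene_detections[frame]:
            left, top, w, h = d.box.to_tlwh()
            rows.append((frame, -1, left, top, w, h, d.confidence, BEHAVIORS.index(d.behavior)))
    return pd.DataFrame(rows, columns=["frame", "id", "left", "top", "w", "h", "conf", "cls"])


def write_results(path: str | Path, results: dict[int, list[TrackOutput]]) -> None:
    """Write tracker output as a result-dialect MOTChallenge CSV."""
    rows = []
    for frame in sorted(results):
        for r in results[frame]:
            left, top, w, h = r.box.to_tlwh()
            rows.append((frame, r.track_id, left, top, w, h, r.confidence))
    df = pd.DataFrame(rows, columns=["frame", "id", "left", "top", "w", "h", "conf"])
    write_mot(path, df, dialect="result")


def read_yolo_labels(path: str | Path, image_size: tuple[int, int]) -> list[tuple[int, Box]]:
    """Read a YOLO label file: one ``class cx cy w h`` line per object,
    coordinates normalized to [0, 1]; returns (class, pixel Box) pairs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            cls = int(parts[0])
            vals = [float(p) for p in parts[1:]]
            out.append((cls, convert_box(vals, "yolo", "center", image_size=image_size)))
    return out


def save_embeddings(path: str | Path, embeddings: np.ndarray) -> None:
    """Save an (N x d) embedding matrix as a named-array archive."""
    np.savez(path, embeddings=np.asarray(embeddings, dtype=float))


def load_embeddings(path: str | Path) -> np.ndarray:
    with np.load(path) as z:
        return z["embeddings"]


def scene_embedding_matrix(scene_detections: dict[int, list[Detection]]) -> np.ndarray:
    """Stack detection embeddings in det-CSV row order (frame-major)."""
    rows = [
        d.embedding
        for frame in sorted(scene_detections)
        for d in scene_detections[frame]
        if d.embedding is not None
    ]
    return np.stack(rows) if rows else np.zeros((0, 0))


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_provenance(artifact_path: str | Path, seed: int | None, config: dict) -> Path:
    """Write a ``<artifact>.meta.json`` sidecar recording version/seed/config."""
    from . import __version__

    side = Path(str(artifact_path) + ".meta.json")
    payload = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": {k: str(v) for k, v in config.items()},
    }
    side.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return side
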