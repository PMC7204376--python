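"""68-point facial landmark data model and file I/O.

Landmarks follow the iBUG 68-point convention: 0-based indices, pixel
coordinates with the origin at the top-left of the image and y increasing
downward.  "Left" and "right" mean image-left and image-right (the observer's
view); mapping to the anatomical side is a presentation concern and is not
done here.

Key index semantics used throughout the package::

    36-41  image-left eye contour   (36/39 = outer/inner corner)
    42-47  image-right eye contour  (42/45 = inner/outer corner)
    27     nasal root
    33     nose tip
    19     left-brow reference point
    24     right-brow reference point

Supported on-disk formats:

* ``pts``  — the standard landmark annotation layout
  (``version/n_points/{ ... }``), one file per frame; a directory of ``.pts``
  files is read as one sequence in sorted order.
* ``csv``  — long form, one row per (frame, point) with columns
  ``frame,index,x,y``.
* ``json`` — a direct serialization of the sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
import numpy as np
import pandas as pd

N_LANDMARKS = 68

LEFT_EYE_INDICES = (36, 37, 38, 39, 40, 41)
RIGHT_EYE_INDICES = (42, 43, 44, 45, 46, 47)
NASAL_ROOT = 27
NOSE_TIP = 33
LEFT_BROW_POINT = 19
RIGHT_BROW_POINT = 24


class Source(str, Enum):
    """Provenance of a landmark set."""

    ANNOTATED = "annotated"
    DETECTED = "detected"
    SYNTHETIC = "synthetic"


class LandmarkSchemaError(ValueError):
    """Raised when landmark data violates the 68-point schema."""


class LandmarkParseError(ValueError):
    """Raised when a landmark file cannot be parsed."""


@dataclass(frozen=True)
class LandmarkSet:
    """68 named 2-D points for one frame.

    Parameters
    ----------
    points:
        Array of shape (68, 2), pixel coordinates ``(x, y)``.
    frame_index:
        Non-negative position of the frame in its sequence.
    source:
        Provenance of the coordinates.
    """

    points: np.ndarray
    frame_index: int = 0
    source: Source = Source.SYNTHETIC

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise LandmarkSchemaError(
                f"expected {N_LANDMARKS} (x, y) points, got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise LandmarkSchemaError("landmark coordinates must be finite")
        if self.frame_index < 0:
            raise LandmarkSchemaError("frame_index must be non-negative")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "source", Source(self.source))

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        """Return a copy with replaced coordinates."""
        return LandmarkSet(points=points, frame_index=self.frame_index, source=self.source)


class Expression(str, Enum):
    OPEN_EYE = "open_eye"
    CLOSED_EYE = "closed_eye"
    BARE_TEETH = "bare_teeth"
    BULGE_MOUTH = "bulge_mouth"
    EYE_CYCLE = "eye_cycle"


@dataclass
class FrameSequence:
    """Ordered landmark frames for one subject performing one expression task."""

    frames: list[LandmarkSet]
    expression: Expression = Expression.EYE_CYCLE
    subject_id: str = ""
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        self.expression = Expression(self.expression)
        if self.fps <= 0:
            raise LandmarkSchemaError("fps must be positive")
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise LandmarkSchemaError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> LandmarkSet:
        return self.frames[i]

    def map_points(self, fn) -> "FrameSequence":
        """Apply ``fn(points, frame) -> new_points`` to every frame; returns a new sequence."""
        new = [f.with_points(fn(f.points, f)) for f in self.frames]
        return FrameSequence(new, self.expression, self.subject_id, self.fps)


def eye_point_indices(side: str) -> tuple[int, ...]:
    """Return the six contour indices of one eye.

    ``side`` is image-left (``"left"`` → 36..41) or image-right
    (``"right"`` → 42..47).
    """
    if side == "left":
        return LEFT_EYE_INDICES
    if side == "right":
        return RIGHT_EYE_INDICES
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = ("pts", "csv", "json")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if path.is_dir():
        return "pts"
    if suffix in _FORMATS:
        return suffix
    raise LandmarkParseError(f"cannot infer landmark format from {path}")


def _parse_pts_file(path: Path, frame_index: int, source: Source) -> LandmarkSet:
    lines = path.read_text().splitlines()
    coords: list[tuple[float, float]] = []
    n_declared = None
    in_body = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("version"):
            continue
        if low.startswith("n_points"):
            try:
                n_declared = int(line.split(":")[1])
            except (IndexError, ValueError) as exc:
                raise LandmarkParseError(f"{path}:{lineno}: bad n_points line {line!r}") from exc
            continue
        if line == "{":
            in_body = True
            continue
        if line == "}":
            in_body = False
            continue
        if in_body:
            parts = line.split()
            if len(parts) < 2:
                raise LandmarkParseError(f"{path}:{lineno}: expected 'x y', got {line!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from exc
    if n_declared is not None and n_declared != len(coords):
        raise LandmarkParseError(
            f"{path}: n_points declares {n_declared} but {len(coords)} points found"
        )
    if len(coords) != N_LANDMARKS:
        raise LandmarkSchemaError(f"{path}: expected {N_LANDMARKS} points, found {len(coords)}")
    return LandmarkSet(np.array(coords), frame_index=frame_index, source=source)


def read_landmarks(path: str | Path, format: str | None = None,
                   source: Source = Source.ANNOTATED) -> FrameSequence:
    """Read a landmark sequence from disk.

    ``path`` may be a single pts/csv/json file or a directory of per-frame
    ``.pts`` files (read in sorted name order).  The format is inferred from
    the suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown landmark format {fmt!r}")

    if fmt == "pts":
        if path.is_dir():
            files = sorted(path.glob("*.pts"))
            if not files:
                raise LandmarkParseError(f"no .pts files in directory {path}")
            frames = [_parse_pts_file(f, i, source) for i, f in enumerate(files)]
        else:
            frames = [_parse_pts_file(path, 0, source)]
        return FrameSequence(frames, subject_id=path.stem)

    if fmt == "csv":
        df = pd.read_csv(path)
        required = {"frame", "index", "x", "y"}
        if not required.issubset(df.columns):
            raise LandmarkParseError(
                f"{path}: CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        frames = []
        for frame_idx, grp in df.groupby("frame", sort=True):
            grp = grp.sort_values("index")
            if len(grp) != N_LANDMARKS or not np.array_equal(
                grp["index"].to_numpy(), np.arange(N_LANDMARKS)
            ):
                raise LandmarkSchemaError(
                    f"{path}: frame {frame_idx} must have point indices 0..67, got {len(grp)} rows"
                )
            frames.append(
                LandmarkSet(grp[["x", "y"]].to_numpy(float), frame_index=int(frame_idx),
                            source=source)
            )
        return FrameSequence(frames, subject_id=path.stem)

    # json
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        frames = [
            LandmarkSet(np.array(fr["points"], dtype=float),
                        frame_index=int(fr["frame_index"]),
                        source=Source(fr.get("source", source)))
            for fr in payload["frames"]
        ]
        return FrameSequence(
            frames,
            expression=payload.get("expression", Expression.EYE_CYCLE),
            subject_id=payload.get("subject_id", path.stem),
            fps=payload.get("fps", 30.0),
        )
    except (KeyError, TypeError) as exc:
        raise LandmarkParseError(f"{path}: malformed JSON landmark payload ({exc})") from exc


def write_landmarks(seq: FrameSequence, path: str | Path, format: str | None = None,
                    precision: int = 6) -> None:
    """Write a sequence to disk, lossless to ``precision`` decimals.

    For ``pts``, ``path`` is a directory receiving one ``frame_%04d.pts`` file
    per frame.  ``read_landmarks`` round-trips the output.
    """
    path = Path(path)
    fmt = format or (path.suffix.lower().lstrip(".") or "pts")
    if fmt not in _FORMATS:
        raise ValueError(f"unknown landmark format {fmt!r}")
    for f in seq.frames:
        if not np.all(np.isfinite(f.points)):  # defensive: frozen dataclass already checks
            raise LandmarkSchemaError("sequence contains non-finite coordinates")

    if fmt == "pts":
        path.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(seq.frames):
            body = "\n".join(
                f"{x:.{precision}f} {y:.{precision}f}" for x, y in f.points
            )
            (path / f"frame_{i:04d}.pts").write_text(
                f"version: 1\nn_points: {N_LANDMARKS}\n{{\n{body}\n}}\n"
            )
        return

    if fmt == "csv":
        rows = [
            {"frame": f.frame_index, "index": i,
             "x": round(float(x), precision), "y": round(float(y), precision)}
            for f in seq.frames for i, (x, y) in enumerate(f.points)
        ]
        pd.DataFrame(rows, columns=["frame", "index", "x", "y"]).to_csv(path, index=False)
        return

    payload = {
        "expression": seq.expression.value,
        "subject_id": seq.subject_id,
        "fps": seq.fps,
        "frames": [
            {"frame_index": f.frame_index, "source": f.source.value,
             "points": [[round(float(x), precision), round(float(y), precision)]
                        for x, y in f.points]}
            for f in seq.frames
        ],
    }
    path.write_text(json.dumps(payload))
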