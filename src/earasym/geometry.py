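"""Face tilt correction and geometric normalization.

The geometric model is anchored at the eye midpoint C — the midpoint between
the two eye-contour centers — with interocular distance d between those
centers.  Palsy patients often sway the head during the task, so before EAR
computation each frame is rotated about C until the line through the two
eye-corner centers is horizontal (in-plane tilt only; no 3-D pose).

The normalization crop extends d to each side of C horizontally and from
0.5 d above to 1.5 d below C vertically, giving a 2d × 2d face box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import (
    FrameSequence,
    LandmarkSet,
    LEFT_EYE_INDICES,
    RIGHT_EYE_INDICES,
)


class DegenerateGeometryError(ValueError):
    """Raised when eye geometry degenerates (coincident centers, zero distances)."""


@dataclass(frozen=True)
class NormalizationFrame:
    """Eye-anchored reference frame of one face."""

    eye_midpoint: tuple[float, float]
    interocular_distance: float
    rotation_angle: float  # radians needed to level the eye-corner line
    crop_box: tuple[float, float, float, float]  # left, top, width, height


def eye_centers(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centers of the two eye contours (mean of the six points each)."""
    pts = np.asarray(points, dtype=float)
    return pts[list(LEFT_EYE_INDICES)].mean(axis=0), pts[list(RIGHT_EYE_INDICES)].mean(axis=0)


def interocular_distance(lm: LandmarkSet | np.ndarray) -> float:
    """Euclidean distance between the two eye-contour centers, in pixels.

    This center-to-center convention is stable under eye closure, unlike a
    corner-to-corner distance.
    """
    pts = lm.points if isinstance(lm, LandmarkSet) else np.asarray(lm, dtype=float)
    left, right = eye_centers(pts)
    d = float(np.linalg.norm(right - left))
    if d <= 0.0:
        raise DegenerateGeometryError("eye centers coincide; interocular distance is zero")
    return d


def _corner_centers(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    return (pts[36] + pts[39]) / 2.0, (pts[42] + pts[45]) / 2.0


def _tilt_angle(points: np.ndarray) -> float:
    """Angle of the eye-corner line above horizontal (radians)."""
    left, right = _corner_centers(points)
    v = right - left
    if np.hypot(*v) <= 0.0:
        raise DegenerateGeometryError("eye-corner centers coincide")
    return float(np.arctan2(v[1], v[0]))


def _rotate_about(points: np.ndarray, center: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (points - center) @ rot.T + center


def tilt_correct_points(points: np.ndarray) -> np.ndarray:
    """Rotate one frame's points about C so the eye-corner line is horizontal."""
    pts = np.asarray(points, dtype=float)
    angle = _tilt_angle(pts)
    left, right = eye_centers(pts)
    center = (left + right) / 2.0
    return _rotate_about(pts, center, -angle)


def tilt_correct(seq: FrameSequence) -> FrameSequence:
    """Level every frame of a sequence; the input sequence is not modified.

    Idempotent: correcting an already-level face is the identity (to
    floating-point precision).
    """
    new_frames = []
    for f in seq.frames:
        try:
            new_frames.append(f.with_points(tilt_correct_points(f.points)))
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"frame {f.frame_index}: {exc}") from exc
    return FrameSequence(new_frames, seq.expression, seq.subject_id, seq.fps)


def normalization_frame(lm: LandmarkSet | np.ndarray) -> NormalizationFrame:
    """Eye-anchored crop box of a (tilt-corrected) face.

    The box is ``[Cx - d, Cx + d] x [Cy - 0.5 d, Cy + 1.5 d]``.
    """
    pts = lm.points if isinstance(lm, LandmarkSet) else np.asarray(lm, dtype=float)
    d = interocular_distance(pts)
    left, right = eye_centers(pts)
    cx, cy = (left + right) / 2.0
    angle = _tilt_angle(pts)
    return NormalizationFrame(
        eye_midpoint=(float(cx), float(cy)),
        interocular_distance=d,
        rotation_angle=-angle,
        crop_box=(float(cx - d), float(cy - 0.5 * d), float(2 * d), float(2 * d)),
    )
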