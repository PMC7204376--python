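"""Amplified eye aspect ratio and bilateral asymmetry via the discrete Fréchet distance.

The eye aspect ratio (EAR) of one eye is the sum of the two vertical eyelid
distances over twice the horizontal corner distance — near zero for a closed
eye, roughly constant while the eye is open.  Because a palsy patient's brow
also moves asymmetrically during eye closure while the nasal root and nose
tip stay almost still, the ratio is amplified by the brow-to-nose-tip
distance over the nose length::

    EAR_L = (|LM37-LM41| + |LM38-LM40|) / (2 |LM36-LM39|) * |LM19-LM33| / |LM27-LM33|
    EAR_R = (|LM43-LM47| + |LM44-LM46|) / (2 |LM42-LM45|) * |LM24-LM33| / |LM27-LM33|

Being a ratio of distances, EAR is invariant to translation, rotation and
uniform scaling of the landmark set, so no explicit rescaling into the
normalization box is needed.

The two per-frame EAR series are compared with the discrete Fréchet distance
in the Eiter–Mannila coupling formulation: the minimum over all monotone
couplings of the two sequences of the maximum pointwise gap.  A literal
per-index maximum (identity coupling; equal lengths required) is available as
``coupling="identity"`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .geometry import DegenerateGeometryError, tilt_correct
from .landmarks import FrameSequence, LandmarkSet

# (vertical pair 1, vertical pair 2, horizontal corner pair, brow point)
_EAR_POINTS = {
    "left": ((37, 41), (38, 40), (36, 39), 19),
    "right": ((43, 47), (44, 46), (42, 45), 24),
}
_NASAL_ROOT = 27
_NOSE_TIP = 33


@dataclass
class EARCurvePair:
    """Left and right per-frame EAR series and their Fréchet distance."""

    left: np.ndarray
    right: np.ndarray
    frechet: float | None = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise ValueError("left and right EAR curves must be 1-D and equally long")
        if np.any(self.left < 0) or np.any(self.right < 0):
            raise ValueError("EAR values must be non-negative")


def ear_one_eye(lm: LandmarkSet | np.ndarray, side: str) -> float:
    """Amplified EAR of one eye on one frame.

    Raises :class:`DegenerateGeometryError` if the eye-corner distance or the
    nose length is zero.
    """
    pts = lm.points if isinstance(lm, LandmarkSet) else np.asarray(lm, dtype=float)
    try:
        (v1a, v1b), (v2a, v2b), (ha, hb), brow = _EAR_POINTS[side]
    except KeyError:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}") from None
    width = np.linalg.norm(pts[ha] - pts[hb])
    if width <= 0:
        raise DegenerateGeometryError(f"{side} eye-corner distance is zero")
    nose_len = np.linalg.norm(pts[_NASAL_ROOT] - pts[_NOSE_TIP])
    if nose_len <= 0:
        raise DegenerateGeometryError("nose length |LM27 - LM33| is zero")
    base = (np.linalg.norm(pts[v1a] - pts[v1b]) + np.linalg.norm(pts[v2a] - pts[v2b])) / (2.0 * width)
    amplification = np.linalg.norm(pts[brow] - pts[_NOSE_TIP]) / nose_len
    return float(base * amplification)


def ear_curves(seq: FrameSequence, apply_tilt_correction: bool = True) -> EARCurvePair:
    """Per-frame left/right EAR series of a sequence (Fréchet not yet set)."""
    if len(seq) == 0:
        raise ValueError("sequence is empty")
    if apply_tilt_correction:
        seq = tilt_correct(seq)
    left, right = [], []
    for f in seq.frames:
        try:
            left.append(ear_one_eye(f, "left"))
            right.append(ear_one_eye(f, "right"))
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"frame {f.frame_index}: {exc}") from exc
    return EARCurvePair(np.array(left), np.array(right))


def frechet_distance(P, Q, coupling: str = "eiter_mannila") -> float:
    """Discrete Fréchet distance between two scalar series.

    ``eiter_mannila`` (default): dynamic programming over the |P| x |Q| grid
    with pointwise cost ``|p_i - q_j|``; the minimum over monotone couplings
    of the maximum gap.  ``identity``: literal per-index maximum gap, defined
    only for equal-length series.
    """
    P = np.asarray(P, dtype=float).ravel()
    Q = np.asarray(Q, dtype=float).ravel()
    if P.size == 0 or Q.size == 0:
        raise ValueError("series must be non-empty")
    if coupling == "identity":
        if P.size != Q.size:
            raise ValueError("identity coupling requires equal-length series")
        return float(np.max(np.abs(P - Q)))
    if coupling != "eiter_mannila":
        raise ValueError(f"unknown coupling {coupling!r}")

    dist = np.abs(P[:, None] - Q[None, :])
    n, m = dist.shape
    ca = np.empty((n, m))
    ca[0, 0] = dist[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], dist[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], dist[i, 0])
        row, prev = ca[i], ca[i - 1]
        for j in range(1, m):
            row[j] = max(min(prev[j], prev[j - 1], row[j - 1]), dist[i, j])
    return float(ca[-1, -1])


def frechet_naive(P, Q, guard: int = 16) -> float:
    """Exhaustive discrete Fréchet distance (test oracle).

    Enumerates every monotone coupling path from (0, 0) to (|P|-1, |Q|-1)
    with steps (1,0), (0,1), (1,1) and returns the minimum over paths of the
    maximum pointwise gap.  Exponential; guarded to ``|P| + |Q| <= guard``.
    """
    P = np.asarray(P, dtype=float).ravel()
    Q = np.asarray(Q, dtype=float).ravel()
    if P.size == 0 or Q.size == 0:
        raise ValueError("series must be non-empty")
    if P.size + Q.size > guard:
        raise ValueError(f"series too long for exhaustive oracle (|P|+|Q| > {guard})")
    n, m = P.size, Q.size

    def best_from(i: int, j: int) -> float:
        gap = abs(P[i] - Q[j])
        if i == n - 1 and j == m - 1:
            return gap
        candidates = []
        if i + 1 < n:
            candidates.append(best_from(i + 1, j))
        if j + 1 < m:
            candidates.append(best_from(i, j + 1))
        if i + 1 < n and j + 1 < m:
            candidates.append(best_from(i + 1, j + 1))
        return max(gap, min(candidates))

    return float(best_from(0, 0))


def bilateral_ear_difference(seq: FrameSequence, apply_tilt_correction: bool = True,
                             coupling: str = "eiter_mannila") -> float:
    """Fréchet distance between the two eyes' EAR curves of one sequence.

    The larger the value, the greater the difference between the movements of
    the two eye regions.
    """
    pair = ear_curves(seq, apply_tilt_correction=apply_tilt_correction)
    return frechet_distance(pair.left, pair.right, coupling=coupling)
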