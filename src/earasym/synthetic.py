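"""Seeded synthetic patients and rendered face images.

Clinical palsy image series are not distributable, so this module is the
first-class stand-in: it generates 68-point landmark sequences of a subject
performing one eye open/close cycle, with one hemiface's eyelid motion
attenuated by a grade-dependent residual fraction, plus head-sway rotation
and per-landmark Gaussian jitter; and it renders deterministic face-like
grayscale images from any landmark set, which is the training substrate for
the regression-tree landmark detector.

The eyelid kinematics are a single raised-cosine closure cycle — an
assumption; no quantitative kinematics of patient eyelid motion are
available.  The residual-fraction map discretizes the six clinical eye-score
bands (normal, >75 % of normal, >50 %, <50 %, trace movement, no movement)
as {1: 1.0, 2: 0.8, 3: 0.55, 4: 0.3, 5: 0.1, 6: 0.0}; it is a modeling
choice and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .landmarks import FrameSequence, LandmarkSet, Source, N_LANDMARKS
from .geometry import eye_centers

DEFAULT_RESIDUAL_FRACTIONS = {1: 1.00, 2: 0.80, 3: 0.55, 4: 0.30, 5: 0.10, 6: 0.00}

# Eyelid points that move during closure; corner points (36, 39, 42, 45) are
# static so the EAR denominator stays stable, mirroring real eye kinematics.
_LEFT_TOP_LID = (37, 38)
_LEFT_BOTTOM_LID = (41, 40)
_RIGHT_TOP_LID = (43, 44)
_RIGHT_BOTTOM_LID = (47, 46)


@dataclass(frozen=True)
class SyntheticPatientConfig:
    """Generator settings for one synthetic palsy patient.

    ``closure_amplitude`` is the peak eyelid closure as a fraction of the
    open-eye height (1.0 = complete closure on the healthy side).
    ``head_sway_deg`` bounds the per-frame in-plane rotation; ``jitter_px``
    is the standard deviation of isotropic Gaussian landmark noise.
    """

    grade: int = 1
    n_frames: int = 30
    closure_amplitude: float = 1.0
    residual_fraction_map: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_FRACTIONS)
    )
    affected_side: str = "right"
    head_sway_deg: float = 5.0
    jitter_px: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in self.residual_fraction_map:
            raise ValueError(f"grade {self.grade} not in residual_fraction_map")
        fr = [self.residual_fraction_map[g] for g in sorted(self.residual_fraction_map)]
        if any(b > a for a, b in zip(fr, fr[1:])):
            raise ValueError("residual_fraction_map must be non-increasing in grade")
        if abs(self.residual_fraction_map[min(self.residual_fraction_map)] - 1.0) > 1e-12:
            raise ValueError("lowest grade must map to residual fraction 1.0")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        if self.n_frames < 1 or self.head_sway_deg < 0 or self.jitter_px < 0:
            raise ValueError("invalid generator parameters")


def template_face() -> LandmarkSet:
    """Fixed neutral 68-point face with open eyes.

    Bilaterally mirror-symmetric about the vertical line x = 100 through the
    nasal root (27) and nose tip (33); eye centers at (70, 90) and (130, 90),
    interocular distance 60 px, eye width 24 px, open-eye height 10 px.
    """
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw 0-16: half-ellipse from left temple through chin to right temple
    k = np.arange(17)
    phi = np.pi * (16 - k) / 16
    pts[0:17, 0] = 100 + 60 * np.cos(phi)
    pts[0:17, 1] = 90 + 70 * np.sin(phi)
    # brows 17-21 (left), 22-26 (right); 19 and 24 are the reference points
    pts[17:22] = [(55, 78), (62, 75), (70, 73), (78, 75), (85, 78)]
    pts[22:27] = [(115, 78), (122, 75), (130, 73), (138, 75), (145, 78)]
    # nose bridge 27-30 (27 = nasal root), bottom 31-35 (33 = nose tip)
    pts[27:31] = [(100, 85), (100, 95), (100, 105), (100, 115)]
    pts[31:36] = [(90, 122), (95, 124), (100, 125), (105, 124), (110, 122)]
    # eyes: 36-41 image-left, 42-47 image-right
    pts[36:42] = [(58, 90), (66, 85), (74, 85), (82, 90), (74, 95), (66, 95)]
    pts[42:48] = [(118, 90), (126, 85), (134, 85), (142, 90), (134, 95), (126, 95)]
    # mouth outer 48-59 and inner 60-67
    pts[48:60] = [(80, 140), (86, 136), (93, 134), (100, 133), (107, 134), (114, 136),
                  (120, 140), (114, 145), (107, 147), (100, 148), (93, 147), (86, 145)]
    pts[60:68] = [(84, 140), (92, 138), (100, 137), (108, 138), (116, 140),
                  (108, 142), (100, 143), (92, 142)]
    return LandmarkSet(pts, frame_index=0, source=Source.SYNTHETIC)


def _close_eye(pts: np.ndarray, top: tuple[int, ...], bottom: tuple[int, ...],
               fraction: float) -> None:
    """Move lid points toward the eye's vertical midline by ``fraction`` (in place)."""
    mid_y = (pts[list(top), 1].mean() + pts[list(bottom), 1].mean()) / 2.0
    for i in top + bottom:
        pts[i, 1] += fraction * (mid_y - pts[i, 1])


def simulate_patient(config: SyntheticPatientConfig) -> tuple[FrameSequence, int]:
    """One synthetic patient's eye open/close sequence and its ground-truth grade.

    Frame t closes the healthy eye by ``A (1 - cos(2 pi t / n)) / 2`` of the
    open-eye height and the affected eye by the grade's residual fraction of
    that; every frame is then rotated in-plane by a seeded angle bounded by
    ``head_sway_deg`` about the eye midpoint and jittered with Gaussian noise.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    base = template_face().points
    residual = config.residual_fraction_map[config.grade]
    left_sets = (_LEFT_TOP_LID, _LEFT_BOTTOM_LID)
    right_sets = (_RIGHT_TOP_LID, _RIGHT_BOTTOM_LID)
    affected, healthy = (left_sets, right_sets) if config.affected_side == "left" \
        else (right_sets, left_sets)

    left, right = eye_centers(base)
    center = (left + right) / 2.0

    frames = []
    for t in range(config.n_frames):
        closure = config.closure_amplitude * (1 - np.cos(2 * np.pi * t / config.n_frames)) / 2
        pts = base.copy()
        _close_eye(pts, healthy[0], healthy[1], closure)
        _close_eye(pts, affected[0], affected[1], residual * closure)
        if config.head_sway_deg > 0:
            angle = np.deg2rad(rng.uniform(-config.head_sway_deg, config.head_sway_deg))
            c, s = np.cos(angle), np.sin(angle)
            pts = (pts - center) @ np.array([[c, -s], [s, c]]).T + center
        if config.jitter_px > 0:
            pts = pts + rng.normal(0.0, config.jitter_px, size=pts.shape)
        frames.append(LandmarkSet(pts, frame_index=t, source=Source.SYNTHETIC))
    seq = FrameSequence(frames, expression="eye_cycle",
                        subject_id=f"synthetic-g{config.grade}-s{config.seed}")
    return seq, config.grade


def generate_cohort(n_per_grade: int = 15, base_seed: int = 0,
                    **overrides) -> list[tuple[FrameSequence, int]]:
    """Seeded cohort of ``6 * n_per_grade`` synthetic patients.

    Per-patient seeds are derived from ``base_seed``; the affected side is
    randomized per patient.  Keyword overrides are forwarded to
    :class:`SyntheticPatientConfig`.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    rng = np.random.default_rng(base_seed)
    cohort = []
    for grade in range(1, 7):
        for _ in range(n_per_grade):
            cfg = SyntheticPatientConfig(
                grade=grade,
                affected_side=("left" if rng.random() < 0.5 else "right"),
                seed=int(rng.integers(0, 2**31 - 1)),
                **overrides,
            )
            cohort.append(simulate_patient(cfg))
    return cohort


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SKIN = 170.0
_EYE = 50.0
_BROW = 60.0
_MOUTH = 95.0
_NOSE_SHADOW = 140.0


def _fill(img: np.ndarray, pts: np.ndarray, value: float) -> None:
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=img.shape)
    img[rr, cc] = value


def render_face_image(lm: LandmarkSet, size_px: int = 128,
                      seed: int = 0, noise_sd: float = 3.0) -> tuple[np.ndarray, LandmarkSet]:
    """Deterministic grayscale rendering of a landmark set.

    The landmark bounding box (padded 10 %) is mapped into a ``size_px``
    square: smooth background gradient, filled face hull, dark eye and brow
    polygons, nose shadow, mouth polygon, then Gaussian pixel noise.  Returns
    the image (float array in [0, 255]) and the landmarks in image
    coordinates.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    pts = lm.points
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = float(max(hi - lo))
    pad = 0.10 * span
    scale = (size_px - 1) / (span + 2 * pad)
    mapped = (pts - (lo - pad)) * scale
    if mapped.min() < 0 or mapped.max() > size_px - 1:
        raise ValueError("landmarks fall outside the canvas")

    rng = np.random.default_rng(seed)
    rows = np.arange(size_px, dtype=float)[:, None]
    img = np.broadcast_to(40.0 + 40.0 * rows / (size_px - 1), (size_px, size_px)).copy()

    _fill(img, mapped[0:17], _SKIN)  # face hull from the jaw contour
    # forehead: extend the hull upward to the brow line
    forehead = np.vstack([mapped[0], mapped[17:27], mapped[16]])
    forehead_top = forehead.copy()
    forehead_top[:, 1] -= 0.35 * span * scale
    _fill(img, np.vstack([forehead, forehead_top[::-1]]), _SKIN)
    for sl, val in ((slice(17, 22), _BROW), (slice(22, 27), _BROW)):
        band = mapped[sl]
        lower = band.copy()
        lower[:, 1] += 0.03 * span * scale + 2.0
        _fill(img, np.vstack([band, lower[::-1]]), val)
    _fill(img, np.vstack([mapped[27:31], mapped[31:36][::-1]]), _NOSE_SHADOW)
    _fill(img, mapped[36:42], _EYE)
    _fill(img, mapped[42:48], _EYE)
    _fill(img, mapped[48:60], _MOUTH)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return img, LandmarkSet(mapped, frame_index=lm.frame_index, source=Source.SYNTHETIC)
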