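"""Desk-scale cascaded ensemble-of-regression-trees (ERT) landmark detector.

Each cascade stage t refines the running 68-point shape estimate by the
additive update ``S^{t+1} = S^t + r_t(I, S^t)``, where r_t is a
gradient-boosted ensemble of shallow binary regression trees over
shape-indexed pixel-difference features: a feature pool is drawn once per
stage as offsets from the nearest mean-shape landmark, each sample's pool is
warped through the similarity transform from the mean shape to its current
shape, and every tree node thresholds the intensity difference of two pool
pixels.  Leaves hold shrinkage-scaled least-squares (mean) residuals.

Residuals are fit in per-sample scale-normalized coordinates (divided by the
current shape's interocular distance at stage start), so each boosting tree
provably does not increase the normalized training error and the cascade is
scale-equivariant.

Detection accuracy is measured by the normalized mean error (NME): the mean
per-landmark Euclidean distance between prediction and ground truth divided
by the ground truth's interocular distance.  A squared-distance variant is
available behind ``squared=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.transform import SimilarityTransform, estimate_transform, warp

from .geometry import DegenerateGeometryError, interocular_distance, normalization_frame
from .landmarks import LandmarkSet, Source, N_LANDMARKS, eye_point_indices

EYE_SUBSET = tuple(range(36, 48))
DEFAULT_INCORRECT_NME_THRESHOLD = 0.08


# ---------------------------------------------------------------------------
# Samples and error metric
# ---------------------------------------------------------------------------

@dataclass
class ShapeSample:
    """One (image, running shape, ground-truth shape) training triple."""

    image: np.ndarray
    current_shape: np.ndarray
    target_shape: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.current_shape = np.asarray(self.current_shape, dtype=float).reshape(N_LANDMARKS, 2)
        self.target_shape = np.asarray(self.target_shape, dtype=float).reshape(N_LANDMARKS, 2)
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image intensities must be finite")

    @property
    def residual(self) -> np.ndarray:
        return self.target_shape - self.current_shape


def nme(predicted: LandmarkSet | np.ndarray, truth: LandmarkSet | np.ndarray,
        point_subset=None, squared: bool = False) -> float:
    """Normalized mean error between a predicted and a ground-truth shape.

    Mean over the evaluated points of the Euclidean prediction error divided
    by the truth's interocular distance; zero iff the subset agrees exactly.
    """
    pred = predicted.points if isinstance(predicted, LandmarkSet) else np.asarray(predicted, float)
    true = truth.points if isinstance(truth, LandmarkSet) else np.asarray(truth, float)
    d = interocular_distance(true)
    idx = np.arange(N_LANDMARKS) if point_subset is None else np.asarray(point_subset, int)
    err = np.linalg.norm(pred[idx] - true[idx], axis=1)
    if squared:
        err = err ** 2
    return float(err.mean() / d)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def shape_bounding_box(shape: np.ndarray, pad_fraction: float = 0.2) -> tuple[float, float, float, float]:
    """Tight (left, top, width, height) box of a shape, padded on each side."""
    lo = shape.min(axis=0)
    hi = shape.max(axis=0)
    size = hi - lo
    pad = pad_fraction * size
    return (float(lo[0] - pad[0]), float(lo[1] - pad[1]),
            float(size[0] + 2 * pad[0]), float(size[1] + 2 * pad[1]))


def align_shape_to_box(shape: np.ndarray, box: tuple[float, float, float, float]) -> np.ndarray:
    """Uniformly scale and translate a shape so its tight bbox fits centered in ``box``."""
    shape = np.asarray(shape, dtype=float)
    lo = shape.min(axis=0)
    hi = shape.max(axis=0)
    size = np.maximum(hi - lo, 1e-9)
    left, top, w, h = box
    scale = min(w / size[0], h / size[1])
    centered = (shape - (lo + hi) / 2.0) * scale
    return centered + np.array([left + w / 2.0, top + h / 2.0])


def _similarity_matrix(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation-and-scale part of the least-squares similarity src -> dst."""
    tform = estimate_transform("similarity", src, dst)
    return np.asarray(tform.params)[:2, :2]


def _sample_intensities(image: np.ndarray, locations: np.ndarray) -> np.ndarray:
    """Nearest-pixel intensities at (x, y) locations, clipped to the image."""
    h, w = image.shape[:2]
    cols = np.clip(np.rint(locations[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.rint(locations[:, 1]).astype(int), 0, h - 1)
    return image[rows, cols]


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class CascadeStage:
    """Feature pool plus the boosted trees of one cascade level.

    Trees of depth F are stored as full binary arrays: ``split_u/split_v``
    index the feature pool, ``split_thresh`` holds node thresholds
    (``2**F - 1`` internal nodes per tree) and ``leaf_values`` the
    shrinkage-scaled residual updates (``2**F`` leaves, flattened 68x2).
    """

    pool_landmark: np.ndarray      # (P,) nearest mean-shape landmark per pool pixel
    pool_offset: np.ndarray        # (P, 2) offset from that landmark, mean-shape units
    split_u: np.ndarray            # (K, n_nodes)
    split_v: np.ndarray            # (K, n_nodes)
    split_thresh: np.ndarray       # (K, n_nodes)
    leaf_values: np.ndarray        # (K, n_leaves, 136)

    @property
    def depth(self) -> int:
        return int(np.log2(self.leaf_values.shape[1]))


@dataclass
class ERTModel:
    """A trained cascade: mean shape plus an ordered list of boosted stages."""

    mean_shape: np.ndarray
    stages: list[CascadeStage] = field(default_factory=list)
    learning_rate: float = 0.1
    depth: int = 4
    trees_per_stage: int = 50
    seed: int = 0
    # per-stage lists of RMS normalized training residuals, one entry per
    # boosting tree; non-increasing within each stage by construction
    train_history: list[list[float]] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Serialize to a single ``.npz`` archive; round-trips to identical predictions."""
        arrays: dict[str, np.ndarray] = {
            "mean_shape": self.mean_shape,
            "meta": np.array([self.learning_rate, self.depth, self.trees_per_stage,
                              self.seed, len(self.stages)], dtype=float),
            "train_history": np.asarray(self.train_history, dtype=float).reshape(
                len(self.stages), -1) if self.stages else np.zeros((0, 0)),
        }
        for t, st in enumerate(self.stages):
            arrays[f"s{t}_pool_landmark"] = st.pool_landmark
            arrays[f"s{t}_pool_offset"] = st.pool_offset
            arrays[f"s{t}_split_u"] = st.split_u
            arrays[f"s{t}_split_v"] = st.split_v
            arrays[f"s{t}_split_thresh"] = st.split_thresh
            arrays[f"s{t}_leaf_values"] = st.leaf_values
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ERTModel":
        with np.load(path) as data:
            lr, depth, k, seed, n_stages = data["meta"]
            stages = [
                CascadeStage(
                    pool_landmark=data[f"s{t}_pool_landmark"],
                    pool_offset=data[f"s{t}_pool_offset"],
                    split_u=data[f"s{t}_split_u"],
                    split_v=data[f"s{t}_split_v"],
                    split_thresh=data[f"s{t}_split_thresh"],
                    leaf_values=data[f"s{t}_leaf_values"],
                )
                for t in range(int(n_stages))
            ]
            return cls(mean_shape=data["mean_shape"], stages=stages,
                       learning_rate=float(lr), depth=int(depth),
                       trees_per_stage=int(k), seed=int(seed),
                       train_history=[list(row) for row in data["train_history"]])


# ---------------------------------------------------------------------------
# Training-set construction
# ---------------------------------------------------------------------------

def augment_training_set(images, shapes, factor: int = 10, seed: int = 0,
                         max_rotation_deg: float = 12.0,
                         scale_range: tuple[float, float] = (0.92, 1.08),
                         max_translate_fraction: float = 0.03):
    """Expand a training set ``factor``-fold with random similarity deformations.

    The first copy of each pair is the identity; each further copy applies a
    seeded random rotation/scale/translation consistently to the image and
    its shape.  Deterministic given the seed.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    aug_images, aug_shapes = [], []
    for image, shape in zip(images, shapes):
        image = np.asarray(image, dtype=float)
        shape = np.asarray(shape, dtype=float)
        aug_images.append(image)
        aug_shapes.append(shape.copy())
        h, w = image.shape[:2]
        center = np.array([w / 2.0, h / 2.0])
        for _ in range(factor - 1):
            angle = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
            scale = rng.uniform(*scale_range)
            shift = rng.uniform(-max_translate_fraction, max_translate_fraction, 2) * (w, h)
            tform = (SimilarityTransform(translation=-center)
                     + SimilarityTransform(rotation=angle, scale=scale)
                     + SimilarityTransform(translation=center + shift))
            aug_images.append(warp(image, tform.inverse, preserve_range=True))
            aug_shapes.append(tform(shape))
    return aug_images, aug_shapes


def compute_mean_shape(shapes) -> np.ndarray:
    """Average shape after similarity-aligning every shape to the first."""
    shapes = [np.asarray(s, dtype=float) for s in shapes]
    ref = shapes[0]
    aligned = [estimate_transform("similarity", s, ref)(s) for s in shapes]
    return np.mean(aligned, axis=0)


def generate_initial_samples(images, shapes, n_initializations: int = 1, seed: int = 0,
                             use_mean_shape: bool = False) -> list[ShapeSample]:
    """Seeded training samples with randomized initial shapes.

    Each image yields ``n_initializations`` samples whose starting shape is
    another training shape (or the mean shape) aligned to the image's face
    box — the tight ground-truth bounding box padded 20 %.
    """
    images = list(images)
    shapes = [np.asarray(s, dtype=float) for s in shapes]
    if n_initializations < 1:
        raise ValueError("n_initializations must be >= 1")
    if not use_mean_shape and len(shapes) < 2 and n_initializations > 1:
        raise ValueError("need >= 2 training shapes for multiple random initializations")
    rng = np.random.default_rng(seed)
    mean_shape = compute_mean_shape(shapes)
    samples = []
    for i, (image, target) in enumerate(zip(images, shapes)):
        box = _clip_box_to_image(shape_bounding_box(target, pad_fraction=0.2),
                                 np.asarray(image).shape)
        for _ in range(n_initializations):
            if use_mean_shape or len(shapes) < 2:
                init = mean_shape
            else:
                j = i
                while j == i:
                    j = int(rng.integers(len(shapes)))
                init = shapes[j]
            samples.append(ShapeSample(image=image, current_shape=align_shape_to_box(init, box),
                                       target_shape=target))
    return samples


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _make_feature_pool(mean_shape: np.ndarray, pool_size: int, rng) -> tuple[np.ndarray, np.ndarray]:
    lo = mean_shape.min(axis=0)
    hi = mean_shape.max(axis=0)
    points = rng.uniform(lo, hi, size=(pool_size, 2))
    d2 = ((points[:, None, :] - mean_shape[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    return nearest.astype(np.int64), points - mean_shape[nearest]


def _stage_features(samples_images, current_shapes, mean_shape,
                    pool_landmark, pool_offset) -> np.ndarray:
    """Intensity matrix (n_samples, pool_size) for one stage."""
    X = np.empty((len(samples_images), pool_landmark.size))
    for i, (image, shape) in enumerate(zip(samples_images, current_shapes)):
        M = _similarity_matrix(mean_shape, shape)
        locations = shape[pool_landmark] + pool_offset @ M.T
        X[i] = _sample_intensities(image, locations)
    return X


def _build_tree(X: np.ndarray, residual: np.ndarray, sample_idx: np.ndarray,
                depth: int, n_candidates: int, learning_rate: float, rng):
    """One greedy regression tree on pixel-difference features.

    Node splits maximize the standard boosting gain
    ``|sum_L r|^2 / n_L + |sum_R r|^2 / n_R``; leaves store the
    shrinkage-scaled mean residual of their samples.
    """
    n_nodes = 2 ** depth - 1
    n_leaves = 2 ** depth
    pool_size = X.shape[1]
    split_u = np.zeros(n_nodes, dtype=np.int64)
    split_v = np.zeros(n_nodes, dtype=np.int64)
    split_thresh = np.full(n_nodes, -np.inf)
    leaf_values = np.zeros((n_leaves, residual.shape[1]))

    empty = np.array([], dtype=np.int64)
    node_samples: list[np.ndarray] = [empty] * (n_nodes + n_leaves)
    node_samples[0] = sample_idx
    for node in range(n_nodes):
        idx = node_samples[node]
        if idx.size == 0:
            continue
        u = rng.integers(0, pool_size, n_candidates)
        v = rng.integers(0, pool_size, n_candidates)
        feats = X[np.ix_(idx, u)] - X[np.ix_(idx, v)]          # (n, c)
        span_lo = feats.min(axis=0)
        span_hi = feats.max(axis=0)
        thresh = rng.uniform(span_lo, span_hi)
        left_mask = feats < thresh                              # (n, c)
        n_left = left_mask.sum(axis=0)
        n_right = idx.size - n_left
        R = residual[idx]                                       # (n, d)
        sum_all = R.sum(axis=0)
        sum_left = R.T @ left_mask                              # (d, c)
        sum_right = sum_all[:, None] - sum_left
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = (np.where(n_left > 0, (sum_left ** 2).sum(axis=0) / n_left, 0.0)
                    + np.where(n_right > 0, (sum_right ** 2).sum(axis=0) / n_right, 0.0))
        valid = (n_left > 0) & (n_right > 0)
        if not valid.any():
            # constant features: degenerate split, everything goes right
            best = 0
            split_thresh[node] = -np.inf
        else:
            gain = np.where(valid, gain, -np.inf)
            best = int(gain.argmax())
            split_thresh[node] = thresh[best]
        split_u[node] = u[best]
        split_v[node] = v[best]
        go_left = (X[idx, u[best]] - X[idx, v[best]]) < split_thresh[node]
        node_samples[2 * node + 1] = idx[go_left]
        node_samples[2 * node + 2] = idx[~go_left]

    for leaf in range(n_leaves):
        idx = node_samples[n_nodes + leaf]
        if idx.size > 0:
            leaf_values[leaf] = learning_rate * residual[idx].mean(axis=0)
    return split_u, split_v, split_thresh, leaf_values


def _tree_leaf_index(X: np.ndarray, split_u, split_v, split_thresh, depth: int) -> np.ndarray:
    """Leaf index reached by every sample (vectorized traversal)."""
    node = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(depth):
        feat = X[np.arange(X.shape[0]), split_u[node]] - X[np.arange(X.shape[0]), split_v[node]]
        go_left = feat < split_thresh[node]
        node = 2 * node + np.where(go_left, 1, 2)
    return node - (2 ** depth - 1)


def train_cascade(samples: list[ShapeSample], stages: int = 6, trees_per_stage: int = 50,
                  depth: int = 4, learning_rate: float = 0.1,
                  feature_pool_size: int = 150, seed: int = 0,
                  n_candidate_splits: int = 20) -> ERTModel:
    """Fit the full cascade by stage-wise gradient boosting on shape residuals.

    Residuals are normalized per sample by the current shape's interocular
    distance at stage start, which makes the recorded per-tree training error
    (root-mean-square normalized residual, ``train_history``) provably
    non-increasing across boosting iterations.
    """
    if not samples:
        raise ValueError("no training samples")
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    if depth < 1 or stages < 0 or trees_per_stage < 1:
        raise ValueError("invalid cascade hyperparameters")
    if not 0.0 <= learning_rate <= 1.0:
        raise ValueError("learning_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mean_shape = compute_mean_shape([s.target_shape for s in samples])
    images = [s.image for s in samples]
    current = np.stack([s.current_shape for s in samples])      # (n, 68, 2)
    targets = np.stack([s.target_shape for s in samples])
    n = current.shape[0]

    model = ERTModel(mean_shape=mean_shape, learning_rate=learning_rate, depth=depth,
                     trees_per_stage=trees_per_stage, seed=seed)
    all_idx = np.arange(n)
    for _t in range(stages):
        pool_landmark, pool_offset = _make_feature_pool(mean_shape, feature_pool_size, rng)
        X = _stage_features(images, current, mean_shape, pool_landmark, pool_offset)
        scale = np.array([interocular_distance(c) for c in current])    # fixed per stage
        R = ((targets - current) / scale[:, None, None]).reshape(n, -1)
        stage_history: list[float] = []
        stage = CascadeStage(
            pool_landmark=pool_landmark, pool_offset=pool_offset,
            split_u=np.zeros((trees_per_stage, 2 ** depth - 1), dtype=np.int64),
            split_v=np.zeros((trees_per_stage, 2 ** depth - 1), dtype=np.int64),
            split_thresh=np.zeros((trees_per_stage, 2 ** depth - 1)),
            leaf_values=np.zeros((trees_per_stage, 2 ** depth, 2 * N_LANDMARKS)),
        )
        for k in range(trees_per_stage):
            su, sv, st, leaves = _build_tree(X, R, all_idx, depth, n_candidate_splits,
                                             learning_rate, rng)
            stage.split_u[k], stage.split_v[k], stage.split_thresh[k] = su, sv, st
            stage.leaf_values[k] = leaves
            R = R - leaves[_tree_leaf_index(X, su, sv, st, depth)]
            stage_history.append(float(np.sqrt(np.mean(R ** 2))))
        current = targets - (R.reshape(n, N_LANDMARKS, 2) * scale[:, None, None])
        model.train_history.append(stage_history)
        model.stages.append(stage)
    return model


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def apply_stage(stage: CascadeStage, image: np.ndarray, shape: np.ndarray,
                mean_shape: np.ndarray) -> np.ndarray:
    """One additive cascade update: returns ``shape + r_t(image, shape)``."""
    M = _similarity_matrix(mean_shape, shape)
    locations = shape[stage.pool_landmark] + stage.pool_offset @ M.T
    x = _sample_intensities(image, locations)[None, :]
    scale = interocular_distance(shape)
    delta = np.zeros(2 * N_LANDMARKS)
    for k in range(stage.leaf_values.shape[0]):
        leaf = _tree_leaf_index(x, stage.split_u[k], stage.split_v[k],
                                stage.split_thresh[k], stage.depth)[0]
        delta += stage.leaf_values[k, leaf]
    return shape + scale * delta.reshape(N_LANDMARKS, 2)


def predict_landmarks(model: ERTModel, image: np.ndarray,
                      face_box: tuple[float, float, float, float] | None = None) -> LandmarkSet:
    """Detect 68 landmarks: align the mean shape to the face box, fold the cascade."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    if face_box is None:
        face_box = (0.0, 0.0, float(w), float(h))
    left, top, bw, bh = face_box
    if left < 0 or top < 0 or left + bw > w or top + bh > h or bw <= 0 or bh <= 0:
        raise ValueError(f"face box {face_box} outside image of size {(w, h)}")
    shape = align_shape_to_box(model.mean_shape, face_box)
    for stage in model.stages:
        shape = apply_stage(stage, image, shape, model.mean_shape)
    return LandmarkSet(shape, frame_index=0, source=Source.DETECTED)


def grid_search(train_samples: list[ShapeSample], test_set,
                depths=(2, 4, 5, 10),
                learning_rates=(0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
                **train_kwargs):
    """Train one cascade per (depth, learning-rate) pair; return the test-NME argmin.

    ``test_set`` is a list of (image, truth shape) pairs; each prediction is
    initialized from the truth's padded bounding box.  Returns the best model
    and the full NME table as a DataFrame (rows = depths, columns = rates).
    """
    depths = list(depths)
    learning_rates = list(learning_rates)
    if not depths or not learning_rates:
        raise ValueError("grid must be non-empty")
    table = pd.DataFrame(index=pd.Index(depths, name="depth"),
                         columns=pd.Index(learning_rates, name="learning_rate"), dtype=float)
    best_model, best_nme = None, np.inf
    for depth in depths:
        for lr in learning_rates:
            model = train_cascade(train_samples, depth=depth, learning_rate=lr, **train_kwargs)
            errs = []
            for image, truth in test_set:
                truth = np.asarray(truth, dtype=float)
                box = shape_bounding_box(truth, pad_fraction=0.2)
                box = _clip_box_to_image(box, np.asarray(image).shape)
                pred = predict_landmarks(model, image, box)
                errs.append(nme(pred, truth))
            mean_err = float(np.mean(errs))
            table.loc[depth, lr] = mean_err
            if mean_err < best_nme:
                best_model, best_nme = model, mean_err
    return best_model, table


def _clip_box_to_image(box, shape) -> tuple[float, float, float, float]:
    h, w = shape[:2]
    left = max(box[0], 0.0)
    top = max(box[1], 0.0)
    right = min(box[0] + box[2], float(w))
    bottom = min(box[1] + box[3], float(h))
    return (left, top, right - left, bottom - top)


def flag_incorrect_detection(predicted: LandmarkSet | np.ndarray,
                             truth: LandmarkSet | np.ndarray | None = None,
                             threshold: float = DEFAULT_INCORRECT_NME_THRESHOLD
                             ) -> tuple[bool, str]:
    """Decide whether a detection is unusable for EAR computation.

    With ground truth, the eye-subset NME is compared against ``threshold``.
    Without it, geometric sanity checks are applied: either eye contour
    self-intersecting, eye height exceeding eye width, or eye landmarks
    falling outside the normalization crop box.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pred = predicted.points if isinstance(predicted, LandmarkSet) else np.asarray(predicted, float)
    if truth is not None:
        err = nme(pred, truth, point_subset=EYE_SUBSET)
        if err > threshold:
            return True, f"eye NME {err:.4f} exceeds threshold {threshold:g}"
        return False, ""
    try:
        frame = normalization_frame(pred)
    except DegenerateGeometryError as exc:
        return True, f"degenerate eye geometry: {exc}"
    left, top, w, h = frame.crop_box
    for side in ("left", "right"):
        idx = list(eye_point_indices(side))
        eye = pred[idx]
        width = np.linalg.norm(eye[0] - eye[3])
        height = (np.linalg.norm(eye[1] - eye[5]) + np.linalg.norm(eye[2] - eye[4])) / 2.0
        if width <= 0 or height > width:
            return True, f"{side} eye taller than wide"
        if (eye[:, 0] < left).any() or (eye[:, 0] > left + w).any() \
                or (eye[:, 1] < top).any() or (eye[:, 1] > top + h).any():
            return True, f"{side} eye outside normalization crop box"
        # a legitimately closed eye is a degenerate (zero-area) ring, so the
        # self-intersection check only applies to visibly open eyes
        if height > 0.1 * width and not Polygon(eye).is_valid:
            return True, f"{side} eye contour self-intersects"
    return False, ""
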