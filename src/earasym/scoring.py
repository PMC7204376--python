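"""FNGS 2.0 bookkeeping and EAR-difference → eye-score classification.

FNGS 2.0 (Facial Nerve Grading Scale 2.0) scores four facial regions —
brow, eye, nasolabial fold, oral — from 1 (normal) to 6 (no movement), plus
a 0–3 secondary-movement (synkinesis/contracture) score.  The total maps to
grades I–VI by fixed bands: I = 4, II = 5–9, III = 10–14, IV = 15–19,
V = 20–23, VI = 24 (totals above 24 fall in the top band).

The classification task is deliberately minimal: the single scalar feature
is the bilateral EAR difference (Fréchet distance between the two eyes' EAR
curves), and the default classifier assigns the eye score whose per-class
training median is nearest (ties break toward the lower score).  An
interval-threshold variant (midpoints between consecutive class medians) and
a 3-nearest-neighbour variant are available.  Accuracy is exact six-class
score match; evaluation is seeded k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_GRADE_BANDS = (
    ("I", 4, 4),
    ("II", 5, 9),
    ("III", 10, 14),
    ("IV", 15, 19),
    ("V", 20, 23),
    ("VI", 24, 27),
)


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a zero-variance variable."""


@dataclass(frozen=True)
class FNGSRecord:
    """One patient's FNGS 2.0 worksheet: four regional scores plus synkinesis."""

    brow: int
    eye: int
    nlf: int
    oral: int
    secondary_movement: int = 0

    def __post_init__(self) -> None:
        for name in ("brow", "eye", "nlf", "oral"):
            v = getattr(self, name)
            if not 1 <= v <= 6:
                raise ValueError(f"{name} score must be in 1..6, got {v}")
        if not 0 <= self.secondary_movement <= 3:
            raise ValueError("secondary_movement must be in 0..3")

    @property
    def total(self) -> int:
        return self.brow + self.eye + self.nlf + self.oral + self.secondary_movement

    @property
    def grade(self) -> str:
        return grade_from_total(self.total)


@dataclass
class CohortSample:
    """One subject's bilateral EAR difference paired with the clinical eye score."""

    subject_id: str
    ear_difference: float
    fngs_eye_score: int
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.ear_difference < 0:
            raise ValueError("ear_difference must be non-negative")
        if not 1 <= self.fngs_eye_score <= 6:
            raise ValueError("fngs_eye_score must be in 1..6")
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded samples must carry a reason")


def grade_from_total(total: int) -> str:
    """Map an FNGS 2.0 total score to the grade band I–VI."""
    total = int(total)
    if total < 4:
        raise ValueError(f"total score must be >= 4 (four regions score >= 1 each), got {total}")
    for grade, lo, hi in _GRADE_BANDS:
        if lo <= total <= hi:
            return grade
    return "VI"


def _active(cohort: list[CohortSample]) -> list[CohortSample]:
    return [s for s in cohort if not s.excluded]


def apply_exclusions(cohort: list[CohortSample], flags, reasons=None
                     ) -> tuple[list[CohortSample], dict]:
    """Mark flagged samples excluded; report exclusion counts per eye score.

    Returns the filtered (non-excluded) cohort and a report with per-score
    original / kept / excluded counts.  Counts are conserved:
    original = kept + excluded for every score.
    """
    flags = list(flags)
    if len(flags) != len(cohort):
        raise ValueError(f"{len(flags)} flags for {len(cohort)} samples")
    if reasons is None:
        reasons = ["flagged as incorrect detection"] * len(cohort)
    kept: list[CohortSample] = []
    original = {s: 0 for s in range(1, 7)}
    excluded = {s: 0 for s in range(1, 7)}
    for sample, flag, reason in zip(cohort, flags, reasons):
        original[sample.fngs_eye_score] += 1
        if flag:
            sample.excluded = True
            sample.exclusion_reason = sample.exclusion_reason or reason
            excluded[sample.fngs_eye_score] += 1
        else:
            kept.append(sample)
    report = {
        "original_per_score": original,
        "excluded_per_score": excluded,
        "kept_per_score": {s: original[s] - excluded[s] for s in original},
        "n_original": sum(original.values()),
        "n_excluded": sum(excluded.values()),
        "n_kept": len(kept),
    }
    return kept, report


def median_by_score(cohort: list[CohortSample]) -> dict[int, float]:
    """Per-score median bilateral EAR difference over non-excluded samples.

    Scores with no samples are simply absent from the result.
    """
    out: dict[int, float] = {}
    values: dict[int, list[float]] = {}
    for s in _active(cohort):
        values.setdefault(s.fngs_eye_score, []).append(s.ear_difference)
    for score in sorted(values):
        out[score] = float(np.median(values[score]))
    return out


def score_correlation(cohort: list[CohortSample], method: str = "pearson") -> float:
    """Correlation between per-sample EAR difference and FNGS 2.0 eye score."""
    active = _active(cohort)
    if len(active) < 3:
        raise ValueError("need at least 3 non-excluded samples")
    x = np.array([s.ear_difference for s in active])
    y = np.array([s.fngs_eye_score for s in active], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in EAR difference or score")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class EyeScoreClassifier:
    """Scalar EAR-difference → eye-score classifier.

    ``nearest_median`` (default): predict the score whose training-class
    median is nearest; exact ties break toward the lower score.
    ``thresholds``: decision boundaries at midpoints between consecutive
    sorted class medians.  ``knn3``: majority vote of the 3 nearest training
    samples (distance ties and vote ties break toward lower scores).
    """

    method: str = "nearest_median"
    class_medians: dict[int, float] = field(default_factory=dict)
    _train_x: np.ndarray | None = None
    _train_y: np.ndarray | None = None

    def predict(self, value: float) -> int:
        if not self.class_medians:
            raise ValueError("classifier is not fitted")
        scores = sorted(self.class_medians)
        if self.method == "nearest_median":
            gaps = [abs(value - self.class_medians[s]) for s in scores]
            return scores[int(np.argmin(gaps))]  # argmin takes first, i.e. lower score
        if self.method == "thresholds":
            ordered = sorted(scores, key=lambda s: self.class_medians[s])
            cuts = [(self.class_medians[a] + self.class_medians[b]) / 2.0
                    for a, b in zip(ordered, ordered[1:])]
            return ordered[int(np.searchsorted(cuts, value, side="right"))]
        if self.method == "knn3":
            order = np.lexsort((self._train_y, np.abs(self._train_x - value)))[:3]
            votes = np.bincount(self._train_y[order], minlength=7)
            return int(votes.argmax())
        raise ValueError(f"unknown classifier method {self.method!r}")

    def predict_many(self, values) -> np.ndarray:
        return np.array([self.predict(float(v)) for v in np.asarray(values).ravel()])


def fit_eye_score_classifier(train: list[tuple[float, int]],
                             method: str = "nearest_median") -> EyeScoreClassifier:
    """Fit the classifier from (ear_difference, score) training pairs."""
    if not train:
        raise ValueError("empty training set")
    x = np.array([v for v, _ in train], dtype=float)
    y = np.array([s for _, s in train], dtype=int)
    medians = {int(s): float(np.median(x[y == s])) for s in np.unique(y)}
    return EyeScoreClassifier(method=method, class_medians=medians, _train_x=x, _train_y=y)


def cross_validate(cohort: list[CohortSample], k: int = 10, seed: int = 0,
                   method: str = "nearest_median", stratified: bool = False
                   ) -> tuple[float, list[float]]:
    """Seeded k-fold cross-validation of exact-score accuracy.

    The cohort is shuffled uniformly (optionally stratified by score) and
    split into k folds whose sizes differ by at most one; each fold is
    scored by a classifier fitted on the other k-1 folds.  Returns the mean
    and the per-fold accuracies.
    """
    active = _active(cohort)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(active):
        raise ValueError(f"k={k} exceeds cohort size {len(active)}")
    rng = np.random.default_rng(seed)
    n = len(active)
    if stratified:
        folds: list[list[int]] = [[] for _ in range(k)]
        order = 0
        for score in range(1, 7):
            idx = [i for i, s in enumerate(active) if s.fngs_eye_score == score]
            rng.shuffle(idx)
            for i in idx:
                folds[order % k].append(i)
                order += 1
        fold_arrays = [np.array(f, dtype=int) for f in folds]
    else:
        perm = rng.permutation(n)
        fold_arrays = list(np.array_split(perm, k))

    accuracies = []
    for fold in fold_arrays:
        test = set(fold.tolist())
        train = [(active[i].ear_difference, active[i].fngs_eye_score)
                 for i in range(n) if i not in test]
        clf = fit_eye_score_classifier(train, method=method)
        hits = [clf.predict(active[i].ear_difference) == active[i].fngs_eye_score
                for i in fold]
        accuracies.append(float(np.mean(hits)))
    return float(np.mean(accuracies)), accuracies
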