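"""End-to-end orchestration: landmarks → EAR curves → asymmetry → scoring report.

A cohort lives in a directory with a ``manifest.csv`` listing one row per
subject (``subject_id, landmarks, fngs_eye_score``); the ``landmarks``
column names a per-subject landmark file (csv/json) or pts directory
relative to the manifest.  The pipeline tilt-corrects every sequence,
computes the amplified EAR curves and their Fréchet distance, applies
exclusions, and summarizes the cohort (per-score medians, correlation,
k-fold cross-validated classification accuracy).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .ear import bilateral_ear_difference
from .landmarks import FrameSequence, read_landmarks, write_landmarks
from .scoring import (
    CohortSample,
    apply_exclusions,
    cross_validate,
    median_by_score,
    score_correlation,
)
from .synthetic import SyntheticPatientConfig, generate_cohort

log = logging.getLogger("earasym")


def load_cohort_manifest(manifest_path: str | Path) -> list[tuple[FrameSequence, int]]:
    """Read every subject's landmark sequence listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "landmarks", "fngs_eye_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    cohort = []
    for row in df.itertuples():
        seq = read_landmarks(manifest_path.parent / row.landmarks)
        seq.subject_id = str(row.subject_id)
        cohort.append((seq, int(row.fngs_eye_score)))
    return cohort


def write_synthetic_cohort(out_dir: str | Path, config: PipelineConfig,
                           base_seed: int = 0) -> Path:
    """Generate a synthetic cohort and write it as landmark CSVs plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    cohort = generate_cohort(
        n_per_grade=gen.n_per_grade, base_seed=base_seed,
        n_frames=gen.n_frames, closure_amplitude=gen.closure_amplitude,
        head_sway_deg=gen.head_sway_deg, jitter_px=gen.jitter_px,
        residual_fraction_map=dict(gen.residual_fraction_map),
    )
    rows = []
    for i, (seq, grade) in enumerate(cohort):
        name = f"subject_{i:03d}.csv"
        write_landmarks(seq, out_dir / name, format="csv")
        rows.append({"subject_id": seq.subject_id, "landmarks": name,
                     "fngs_eye_score": grade})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    log.info("wrote %d synthetic subjects to %s", len(rows), out_dir)
    return manifest


def run_pipeline(cohort: list[tuple[FrameSequence, int]] | str | Path,
                 config: PipelineConfig | None = None,
                 exclusion_flags: list[bool] | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full analysis on a cohort and return (and optionally write) the report.

    ``cohort`` is either a manifest path or an in-memory list of
    (sequence, eye score) pairs.  Per-subject failures are collected and
    reported, not silently dropped.
    """
    config = (config or PipelineConfig()).validate()
    if isinstance(cohort, (str, Path)):
        cohort = load_cohort_manifest(cohort)
    log.info("pipeline start: %d subjects", len(cohort))

    samples: list[CohortSample] = []
    failures: list[dict] = []
    for seq, score in cohort:
        try:
            value = bilateral_ear_difference(seq, coupling=config.frechet_coupling)
            samples.append(CohortSample(subject_id=seq.subject_id,
                                        ear_difference=value, fngs_eye_score=score))
        except Exception as exc:  # noqa: BLE001 — reported per subject
            failures.append({"subject_id": seq.subject_id, "error": str(exc)})
    log.info("EAR asymmetry computed for %d/%d subjects", len(samples), len(cohort))

    flags = exclusion_flags if exclusion_flags is not None else [False] * len(samples)
    kept, exclusion_report = apply_exclusions(samples, flags)
    medians = median_by_score(kept)
    correlation = score_correlation(kept) if len(kept) >= 3 else None
    k = min(config.cv.k, len(kept))
    mean_acc, fold_accs = cross_validate(
        kept, k=k, seed=config.cv.seed, method=config.classifier_method,
        stratified=config.cv.stratified,
    )
    log.info("medians for %d scores, correlation=%s, CV accuracy=%.3f",
             len(medians), correlation, mean_acc)

    report = {
        "n_subjects": len(cohort),
        "n_failed": len(failures),
        "failures": failures,
        "exclusions": exclusion_report,
        "median_ear_difference_by_score": {
            str(s): medians.get(s) for s in range(1, 7)
        },
        "correlation": correlation,
        "cv": {"k": k, "mean_accuracy": mean_acc, "fold_accuracies": fold_accs},
        "per_subject": [
            {"subject_id": s.subject_id, "ear_difference": s.ear_difference,
             "fngs_eye_score": s.fngs_eye_score, "excluded": s.excluded,
             "reason": s.exclusion_reason}
            for s in samples
        ],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(report["per_subject"]).to_csv(out_dir / "cohort.csv", index=False)
        log.info("report written to %s", out_dir)
    return report
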