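import numpy as np
import pytest

import earasym as ea
from earasym.detector import generate_initial_samples, train_cascade


@pytest.fixture()
def template():
    return ea.template_face()


def make_eye_config(base_ratio: float = 0.25, amplification: float = 1.0) -> np.ndarray:
    """A landmark array whose left eye has the requested EAR ingredients.

    Eye width is 2 px; the two vertical lid distances are equal and chosen so
    that (v1 + v2) / (2 * width) == base_ratio; the brow-to-nose-tip and nose
    lengths are chosen so their ratio equals ``amplification``.
    """
    pts = ea.template_face().points.copy()
    v = 2.0 * base_ratio  # each vertical distance, width fixed at 2
    pts[36] = (0.0, 0.0)
    pts[39] = (2.0, 0.0)
    pts[37] = (0.5, -v / 2)
    pts[41] = (0.5, v / 2)
    pts[38] = (1.5, -v / 2)
    pts[40] = (1.5, v / 2)
    pts[27] = (10.0, 0.0)
    pts[33] = (10.0, 4.0)  # nose length 4
    pts[19] = (10.0, 4.0 - 4.0 * amplification)  # brow-to-tip = 4 * amplification
    return pts


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded synthetic cohort at generator defaults: 15 patients per grade."""
    return ea.generate_cohort(n_per_grade=15, base_seed=11)


@pytest.fixture(scope="session")
def cohort_samples(default_cohort):
    return [
        ea.CohortSample(subject_id=seq.subject_id,
                        ear_difference=ea.bilateral_ear_difference(seq),
                        fngs_eye_score=grade)
        for seq, grade in default_cohort
    ]


@pytest.fixture(scope="session")
def rendered_faces():
    """75 rendered synthetic faces with varied eye openness, pose and jitter."""
    rng = np.random.default_rng(0)
    cohort = ea.generate_cohort(n_per_grade=3, base_seed=5, jitter_px=0.5, head_sway_deg=8)
    frames = []
    for seq, _grade in cohort:
        for i in rng.choice(len(seq), size=4, replace=False):
            frames.append(seq[int(i)])
    rng.shuffle(frames)
    pairs = [ea.render_face_image(f, size_px=96, seed=int(rng.integers(1 << 30)))
             for f in frames[:75]]
    images = [im for im, _ in pairs]
    shapes = [lm.points for _, lm in pairs]
    return images, shapes


@pytest.fixture(scope="session")
def trained_detector(rendered_faces):
    """Desk-scale cascade trained on 60 rendered faces; 15 held out."""
    images, shapes = rendered_faces
    samples = generate_initial_samples(images[:60], shapes[:60], n_initializations=3, seed=1)
    model = train_cascade(samples, stages=5, trees_per_stage=40, depth=4,
                          learning_rate=0.5, feature_pool_size=120, seed=1)
    return model, (images[60:], shapes[60:]), samples
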