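import numpy as np
import pytest

from euslymph import (
    RatingTable,
    generate_cohort,
    generate_ratings,
    study_cohort_config,
    study_noise_config,
)


@pytest.fixture(scope="session")
def study_cohort():
    """One fixed 68-lesion cohort + rating panel under study conditions."""
    lesions, truth = generate_cohort(study_cohort_config(seed=11))
    ratings = generate_ratings(truth, study_noise_config(seed=12))
    return lesions, truth, ratings


@pytest.fixture()
def tiny_ratings():
    """3 lesions x 3 raters, one binary feature, counts (3,0),(0,3),(2,1)."""
    rows = []
    cats = {"L1": ["clear"] * 3, "L2": ["fuzzy"] * 3, "L3": ["clear", "clear", "fuzzy"]}
    for lid, cs in cats.items():
        for r, c in zip(["R1", "R2", "R3"], cs):
            rows.append((lid, r, "border", c))
    return RatingTable.from_rows(rows)


def binary_counts(truth: np.ndarray, eps: float, n_raters: int, rng) -> np.ndarray:
    """Per-lesion (n, 2) rating counts under the uniform-confusion model."""
    reports = truth[None, :] ^ (rng.random((n_raters, truth.size)) < eps)
    pos = reports.sum(axis=0)
    return np.stack([pos, n_raters - pos], axis=1)
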