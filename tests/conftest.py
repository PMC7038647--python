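"""Shared fixtures.

The expensive objects — the reference synthetic cohort and the model trained
on it — are session-scoped so the learnability, importance-recovery and
heterogeneity tests all reuse a single training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import deeptriage as dt


@pytest.fixture(scope="session")
def reference_cohort() -> dt.synthetic.SyntheticCohort:
    """The default synthetic cohort: 150/class, d=500, 10 planted features,
    natural-log fold change 2, class-A severity gradient on 10 features."""
    return dt.generate_cohort(dt.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def reference_split(reference_cohort):
    cohort = reference_cohort
    train_ids, test_ids = dt.split_cohort(
        cohort.counts.sample_ids, cohort.labels, test_fraction=1 / 3, seed=11
    )
    pos = {s: i for i, s in enumerate(cohort.counts.sample_ids)}
    norm = dt.normalize_counts(cohort.counts, dt.estimate_size_factors(cohort.counts))
    return {
        "train": norm.subset_samples(train_ids),
        "test": norm.subset_samples(test_ids),
        "y_train": cohort.labels[[pos[s] for s in train_ids]],
        "y_test": cohort.labels[[pos[s] for s in test_ids]],
        "test_ids": test_ids,
        "train_ids": train_ids,
    }


@pytest.fixture(scope="session")
def trained_model(reference_split):
    return dt.fit(
        reference_split["train"], reference_split["y_train"], dt.ModelConfig(seed=0)
    )


@pytest.fixture(scope="session")
def reference_importance(trained_model, reference_split):
    imp = dt.score_importance(trained_model, reference_split["test"])
    imp.class_labels = reference_split["y_test"]
    return imp


@pytest.fixture
def tiny_matrix() -> dt.ExpressionMatrix:
    rng = np.random.default_rng(42)
    return dt.ExpressionMatrix(
        [f"s{i}" for i in range(4)],
        [f"g{i}" for i in range(6)],
        rng.integers(1, 50, size=(4, 6)).astype(float),
    )
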