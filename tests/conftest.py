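import logging

import numpy as np
import pytest

from evtgraph import (default_spec, drop_sparse_variables, generate_cohort,
                      impute_median, preprocess_pipeline)

logging.getLogger("evtgraph").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    """One deterministic 220-patient synthetic cohort."""
    return generate_cohort(spec, 220, 7)


@pytest.fixture(scope="session")
def clean_cohort(cohort):
    """Cohort after the 10%-missingness filter and full-cohort imputation."""
    table, _ = drop_sparse_variables(cohort)
    return impute_median(table)


@pytest.fixture(scope="session")
def followup_matrix(cohort):
    """Fully preprocessed follow-up design matrix for the good-outcome task."""
    return preprocess_pipeline(cohort, "good_outcome", "followup")


def count_gating_recoveries(n_seeds=10, n=120):
    """Planted-gating experiment: labels driven by sex; count the seeds in
    which the grid search returns a sex-containing rule."""
    from evtgraph.popgraph import GatingRule, gating_grid_search

    candidates = [
        GatingRule("mortality", (("sex", "equal", 0.0),)),
        GatingRule("mortality", (("age", "absdiff_lt", 5.0),)),
        GatingRule("mortality", (("nihss", "absdiff_lt", 5.0),)),
        GatingRule("mortality", (("prev_mrs", "absdiff_lt", 1.0),)),
    ]
    hits = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        sex = rng.integers(0, 2, n)
        meta = np.column_stack([
            rng.normal(70, 10, n), sex,
            rng.integers(0, 30, n), rng.integers(0, 3, n),
        ]).astype(float)
        y = (rng.random(n) < np.where(sex == 1, 0.85, 0.15)).astype(int)
        split_rng = np.random.default_rng(seed)
        splits = []
        for _ in range(2):
            idx = split_rng.permutation(n)
            val = np.zeros(n, bool)
            val[idx[: n // 4]] = True
            splits.append((~val, val))
        best, _ = gating_grid_search(meta, y, splits, grid=candidates)
        hits += any(c[0] == "sex" for c in best.conditions)
    return hits


def three_way_masks(n, seed, n_test=None, n_val=None):
    """Deterministic disjoint train/val/test boolean masks."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_test = n // 5 if n_test is None else n_test
    n_val = n // 6 if n_val is None else n_val
    test = np.zeros(n, bool)
    val = np.zeros(n, bool)
    test[idx[:n_test]] = True
    val[idx[n_test:n_test + n_val]] = True
    return ~test & ~val, val, test
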