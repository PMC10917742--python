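"""Fold design, metrics oracles, comparison tests, sweep, orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evtgraph.baselines import small_grids
from evtgraph.chebnet import GCNConfig
from evtgraph.cohort import planted_spec
from evtgraph.evaluate import (compute_metrics, make_fold_plan,
                               paired_ttest_models, uncertainty_sweep,
                               univariate_table)
from evtgraph.experiment import ExperimentConfig, run_full_experiment


def auc_concordance_oracle(scores, labels):
    """Exhaustive pairwise concordance count (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def bh_stepup_oracle(pvals):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


class TestFoldPlan:
    def test_stratification_within_one_patient(self):
        rng = np.random.default_rng(0)
        labels = np.zeros(220, int)
        labels[rng.choice(220, 81, replace=False)] = 1
        plan = make_fold_plan(labels, n_folds=5, seed=1)
        per_fold_pos = [int(labels[plan.fold_id == f].sum()) for f in range(5)]
        assert sorted(per_fold_pos) in ([16, 16, 16, 16, 17],
                                        [16, 16, 16, 17, 17],
                                        [16, 16, 17, 17, 17])
        assert max(per_fold_pos) - min(per_fold_pos) <= 1

    def test_folds_partition_patients(self):
        labels = np.tile([0, 0, 1], 40)
        plan = make_fold_plan(labels, seed=2)
        assert np.all(plan.fold_id >= 0)
        sizes = np.bincount(plan.fold_id)
        assert sizes.sum() == 120 and max(sizes) - min(sizes) <= 1

    def test_masks_disjoint_and_validation_from_training(self):
        labels = np.tile([0, 1], 60)
        plan = make_fold_plan(labels, seed=3)
        for f in range(plan.n_folds):
            train, val, test = plan.masks(f)
            assert not (train & val).any()
            assert not (train & test).any()
            assert not (val & test).any()
            assert (train | val | test).all()
            assert val.sum() == pytest.approx(0.2 * (train.sum() + val.sum()),
                                              abs=2)

    def test_same_seed_same_plan(self):
        labels = np.tile([0, 1], 50)
        a = make_fold_plan(labels, seed=4)
        b = make_fold_plan(labels, seed=4)
        assert np.array_equal(a.fold_id, b.fold_id)
        assert np.array_equal(a.val_id, b.val_id)

    def test_duplicate_patient_ids_share_a_fold(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(np.arange(60), 2)  # every patient acquired twice
        labels = np.repeat(rng.integers(0, 2, 60), 2)
        plan = make_fold_plan(labels, seed=5, groups=groups)
        for g in np.unique(groups):
            assert np.unique(plan.fold_id[groups == g]).size == 1

    def test_class_smaller_than_folds_rejected(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            make_fold_plan(labels, n_folds=5)


class TestComputeMetrics:
    def test_perfect_ranking(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.auc == 1.0 and m.accuracy == 1.0 and m.balanced_accuracy == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 4000)
        scores = rng.random(4000)
        assert compute_metrics(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_toy_set_matches_concordance_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        m = compute_metrics(scores, labels)
        assert m.auc == pytest.approx(auc_concordance_oracle(scores, labels))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_auc_equals_concordance_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # force some ties
        m = compute_metrics(scores, labels)
        assert m.auc == pytest.approx(auc_concordance_oracle(scores, labels))

    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        scores = np.array([0.9, 0.6, 0.4, 0.8, 0.3, 0.2])
        labels = np.array([1, 0, 1, 1, 0, 0])
        m = compute_metrics(scores, labels)
        pred = scores >= 0.5
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        assert m.balanced_accuracy == pytest.approx((sens + spec) / 2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.9], [1, 1])


class TestPairedTtest:
    def test_hand_computed_t_statistic(self):
        a = np.array([0.80, 0.84, 0.78, 0.90, 0.83])
        b = np.array([0.76, 0.81, 0.80, 0.85, 0.80])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        table = pd.DataFrame({"m1": a, "m2": b})
        P = paired_ttest_models(table)
        assert P.loc["m1", "m2"] == pytest.approx(p_hand)

    def test_identical_columns_report_p_one(self):
        table = pd.DataFrame({"a": [0.8, 0.7, 0.9], "b": [0.8, 0.7, 0.9]})
        assert paired_ttest_models(table).loc["a", "b"] == 1.0

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.random((5, 3)), columns=list("abc"))
        P = paired_ttest_models(table)
        assert np.allclose(P.values, P.values.T)
        assert np.all(np.diag(P.values) == 1.0)


class TestUnivariateTable:
    def test_chi2_matches_hand_formula(self, cohort):
        # 2x2 shortcut: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 10, 20, 30, 40
        n = a + b + c + d
        chi2_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        table = np.array([[a, b], [c, d]])
        res = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2_hand)
        df = univariate_table(cohort, "good_outcome")
        row = df[df.variable == "diabetes"].iloc[0]
        x = cohort.data["diabetes"].to_numpy()
        y = (cohort.data["mrs_3month"] <= 2).to_numpy()
        cont = np.array([[np.sum((x == v) & (y == g)) for v in (0, 1)]
                         for g in (0, 1)])
        expected = stats.chi2_contingency(cont, correction=False).pvalue
        assert row.p_value == pytest.approx(expected)

    def test_continuous_uses_t_test(self, cohort):
        df = univariate_table(cohort, "good_outcome")
        row = df[df.variable == "age"].iloc[0]
        assert row.test == "t-test"
        good = cohort.data["mrs_3month"] <= 2
        expected = stats.ttest_ind(cohort.data.loc[good, "age"],
                                   cohort.data.loc[~good, "age"]).pvalue
        assert row.p_value == pytest.approx(expected)
        assert "±" in row.group1_summary

    def test_age_discriminates_in_default_cohort(self, cohort):
        df = univariate_table(cohort, "good_outcome").set_index("variable")
        assert df.loc["age", "p_adjusted"] < 0.01

    def test_identical_group_distributions_large_p(self):
        from evtgraph.cohort import generate_cohort

        table = generate_cohort(planted_spec(
            {"admission": 0, "post_evt": 0, "followup": 0}), 2000, 0)
        df = univariate_table(table, "good_outcome").set_index("variable")
        assert df.loc["admission_noise_0", "p_adjusted"] > 0.2

    def test_adjusted_p_matches_bh_oracle(self):
        pvals = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(multipletests(pvals, method="fdr_bh")[1],
                           bh_stepup_oracle(pvals))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bh_oracle_on_random_pvalue_sets(self, seed):
        rng = np.random.default_rng(seed)
        pvals = rng.random(int(rng.integers(2, 30)))
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(multipletests(pvals, method="fdr_bh")[1],
                           bh_stepup_oracle(pvals))

    def test_adjusted_never_below_raw(self, cohort):
        df = univariate_table(cohort, "mortality").dropna(subset=["p_value"])
        assert np.all(df.p_adjusted >= df.p_value - 1e-12)
        assert np.all(df.p_adjusted <= 1.0 + 1e-12)


class TestUncertaintySweep:
    def _data(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        noise_scale = rng.random(n)  # higher -> noisier prediction
        scores = np.clip(
            labels + rng.normal(0, 0.2 + 1.2 * noise_scale, n), -0.49, 1.49
        )
        scores = (scores + 0.49) / 1.98
        u = np.clip(0.693 * noise_scale + rng.normal(0, 0.05, n), 0, 0.693)
        return scores, u, labels

    def test_threshold_above_max_recovers_global_metrics(self):
        scores, u, labels = self._data()
        sweep = uncertainty_sweep(scores, u, labels, thresholds=(0.8,))
        global_m = compute_metrics(scores, labels)
        assert sweep.n_certain[0] == labels.size
        assert sweep.auc[0] == pytest.approx(global_m.auc)

    def test_zero_threshold_accepts_nobody(self):
        scores, u, labels = self._data()
        sweep = uncertainty_sweep(scores, u, labels, thresholds=(0.0, 0.3))
        assert sweep.n_certain[0] == 0
        assert np.isnan(sweep.auc[0])

    def test_n_certain_monotone_in_threshold(self):
        for seed in range(5):
            scores, u, labels = self._data(seed)
            sweep = uncertainty_sweep(scores, u, labels)
            assert np.all(np.diff(sweep.n_certain) >= 0)

    def test_stricter_threshold_improves_auc_when_uncertainty_tracks_error(self):
        hits = 0
        for seed in range(10):
            scores, u, labels = self._data(seed)
            sweep = uncertainty_sweep(scores, u, labels).set_index("threshold")
            hits += sweep.loc[0.3, "auc"] >= sweep.loc[0.7, "auc"]
        assert hits >= 8


@pytest.fixture(scope="module")
def quick_config():
    return ExperimentConfig(
        n_patients=150, seed=3,
        tasks=("good_outcome",),
        timepoints=("admission", "followup"),
        algorithms=("logistic_regression", "gcn"),
        n_folds=3, grids=small_grids(),
        gcn=GCNConfig(max_epochs=200, patience=20),
        cohort_spec=planted_spec(),
    )


@pytest.fixture(scope="module")
def report(quick_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    import dataclasses
    cfg = dataclasses.replace(quick_config, out_dir=str(out))
    return run_full_experiment(cfg), out


class TestFullExperiment:
    def test_emits_all_three_report_tables(self, report):
        rep, out = report
        assert (out / "performance.csv").exists()
        assert (out / "univariate_good_outcome.csv").exists()
        assert (out / "uncertainty_sweep_good_outcome.csv").exists()
        assert set(rep.performance.algorithm) == {"logistic_regression", "gcn"}
        assert len(rep.per_fold) == 2 * 2 * 3  # timepoints x algorithms x folds

    def test_sweep_table_well_formed(self, report):
        rep, _ = report
        sweep = rep.sweeps["good_outcome"]
        assert np.all(np.diff(sweep.n_certain) >= 0)
        assert sweep.threshold.tolist() == pytest.approx(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        )

    def test_ttest_matrices_present_and_symmetric(self, report):
        rep, _ = report
        P = rep.ttests[("good_outcome", "followup")]
        assert np.allclose(P.values, P.values.T)

    def test_identical_seed_reproduces_report(self, quick_config, tmp_path):
        import dataclasses
        a = run_full_experiment(quick_config)
        b = run_full_experiment(quick_config)
        pd.testing.assert_frame_equal(a.performance, b.performance)
        pd.testing.assert_frame_equal(
            a.sweeps["good_outcome"], b.sweeps["good_outcome"]
        )

    def test_followup_beats_admission_with_planted_late_signal(self):
        """Later-timepoint information helps when it carries the signal."""
        spec = planted_spec({"admission": 0.25, "post_evt": 0.6, "followup": 1.8})
        hits = 0
        for seed in range(10):
            cfg = ExperimentConfig(
                n_patients=150, seed=seed,
                tasks=("good_outcome",),
                timepoints=("admission", "followup"),
                algorithms=("logistic_regression",),
                n_folds=3, grids=small_grids(),
                cohort_spec=spec,
            )
            perf = run_full_experiment(cfg).performance.set_index("timepoint")
            hits += perf.loc["followup", "auc"] >= perf.loc["admission", "auc"]
        assert hits >= 8
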