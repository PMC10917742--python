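"""Spectral convolution, training behavior and MC-dropout uncertainty."""

import numpy as np
import pytest
import scipy.sparse as sp

from evtgraph.chebnet import (ChebNet, GCNConfig, PredictionDistribution,
                              cheb_conv, cheb_polynomials, make_gcn_trainer,
                              mc_dropout_predict, predictive_std,
                              predictive_uncertainty, scaled_laplacian,
                              train_semi_supervised)
from evtgraph.cohort import generate_cohort, planted_spec
from evtgraph.popgraph import GOOD_OUTCOME_RULE, build_graph, meta_from_cohort
from evtgraph.preprocess import preprocess_pipeline

from conftest import three_way_masks


def random_graph(n, seed, density=0.2):
    rng = np.random.default_rng(seed)
    A = rng.random((n, n)) < density
    W = np.triu(A, 1) * rng.random((n, n))
    W = W + W.T
    return W


def cheb_eigen_oracle(L_tilde, k):
    """T_k(L~) through the eigendecomposition: T_k on eigenvalues via the
    trigonometric definition cos(k arccos x) on [-1, 1]."""
    lam, V = np.linalg.eigh((L_tilde + L_tilde.T) / 2)
    tk = np.cos(k * np.arccos(np.clip(lam, -1.0, 1.0)))
    return (V * tk) @ V.T


class TestScaledLaplacian:
    def test_edgeless_graph_spectrum_in_unit_interval(self):
        L = scaled_laplacian(np.zeros((4, 4)))
        lam = np.linalg.eigvalsh(L)
        assert lam.min() >= -1 - 1e-6 and lam.max() <= 1 + 1e-6

    def test_two_node_single_edge_hand_result(self):
        # W = [[0,1],[1,0]]: normalized Laplacian [[1,-1],[-1,1]], lambda_max
        # = 2, so L~ = L - I = [[0,-1],[-1,0]]
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = scaled_laplacian(W)
        assert np.allclose(L, [[0, -1], [-1, 0]], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_spectrum_range_on_random_graphs(self, seed):
        W = random_graph(50, seed)
        lam = np.linalg.eigvalsh(scaled_laplacian(W))
        assert lam.min() >= -1 - 1e-6 and lam.max() <= 1 + 1e-6

    def test_isolated_nodes_contribute_identity_rows(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        L = scaled_laplacian(W)  # node 2 isolated
        lam = np.linalg.eigvalsh(L)
        assert lam.min() >= -1 - 1e-9 and lam.max() <= 1 + 1e-9


class TestChebConv:
    def test_matches_dense_eigen_oracle(self):
        """Output equals explicit polynomial evaluation on small instances."""
        rng = np.random.default_rng(0)
        for seed in range(5):
            n, fin, fout, K = 12, 4, 3, 3
            W = random_graph(n, seed + 100)
            L = scaled_laplacian(W)
            X = rng.normal(size=(n, fin))
            weights = rng.normal(size=(K + 1, fin, fout))
            expected = sum(
                cheb_eigen_oracle(L, k) @ X @ weights[k] for k in range(K + 1)
            )
            got = cheb_conv(L, X, weights)
            assert np.allclose(got, expected, atol=1e-8)

    def test_edgeless_graph_collapses_to_dense_linear_maps(self):
        # L~ = I on an edgeless graph: T_k(I) = I, so the layer is X @ sum W_k
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 3))
        weights = rng.normal(size=(2, 3, 2))  # K = 1
        out = cheb_conv(scaled_laplacian(np.zeros((6, 6))), X, weights)
        assert np.allclose(out, X @ (weights[0] + weights[1]), atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n = 10
        W = random_graph(n, 3)
        X = rng.normal(size=(n, 4))
        weights = rng.normal(size=(4, 4, 2))
        perm = rng.permutation(n)
        base = cheb_conv(scaled_laplacian(W), X, weights)
        permuted = cheb_conv(
            scaled_laplacian(W[np.ix_(perm, perm)]), X[perm], weights
        )
        assert np.allclose(permuted[np.argsort(perm)], base, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cheb_conv(np.eye(3), np.ones((3, 2)), np.ones((2, 5, 4)))


@pytest.fixture(scope="module")
def separable_setup():
    """Strongly separable synthetic cohort with its graph and matrix."""
    spec = planted_spec({"admission": 2.5, "post_evt": 2.5, "followup": 2.5})
    table = generate_cohort(spec, 200, 5)
    fm = preprocess_pipeline(table, "good_outcome", "followup")
    graph = build_graph(meta_from_cohort(table), GOOD_OUTCOME_RULE)
    return graph, fm


class TestTraining:
    def test_separable_cohort_reaches_high_validation_auc(self, separable_setup):
        from sklearn.metrics import roc_auc_score

        graph, fm = separable_setup
        train, val, test = three_way_masks(fm.n_patients, 0)
        model, log = train_semi_supervised(
            graph, fm, GCNConfig(seed=0), train, val
        )
        probs = model.predict_proba(model.polynomials, fm.X)[:, 1]
        assert roc_auc_score(fm.y[val], probs[val]) >= 0.85

    def test_label_permutation_destroys_signal(self, separable_setup):
        """Shuffled labels: mean validation AUC near chance over 10 seeds."""
        from sklearn.metrics import roc_auc_score

        graph, fm = separable_setup
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(fm.y)
            train, val, _ = three_way_masks(fm.n_patients, seed)
            cfg = GCNConfig(seed=seed, max_epochs=200)
            model, _ = train_semi_supervised(
                graph, fm.X, cfg, train, val, y=y_perm
            )
            probs = model.predict_proba(model.polynomials, fm.X)[:, 1]
            aucs.append(roc_auc_score(y_perm[val], probs[val]))
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_identical_seed_gives_identical_training_log(self, separable_setup):
        graph, fm = separable_setup
        train, val, _ = three_way_masks(fm.n_patients, 1)
        cfg = GCNConfig(seed=11, max_epochs=60)
        _, log1 = train_semi_supervised(graph, fm, cfg, train, val)
        _, log2 = train_semi_supervised(graph, fm, cfg, train, val)
        assert log1["train_loss"] == log2["train_loss"]
        assert log1["val_loss"] == log2["val_loss"]

    def test_overlapping_masks_rejected(self, separable_setup):
        graph, fm = separable_setup
        mask = np.zeros(fm.n_patients, bool)
        mask[:50] = True
        with pytest.raises(ValueError, match="overlap"):
            train_semi_supervised(graph, fm, GCNConfig(), mask, mask)

    def test_gcn_trainer_factory_rates_graphs(self, separable_setup):
        graph, fm = separable_setup
        train, val, _ = three_way_masks(fm.n_patients, 2)
        trainer = make_gcn_trainer(fm, GCNConfig(max_epochs=80, seed=3))
        auc = trainer(graph, fm.y, train, val)
        assert 0.5 < auc <= 1.0


@pytest.fixture(scope="module")
def trained_model(separable_setup):
    graph, fm = separable_setup
    train, val, _ = three_way_masks(fm.n_patients, 0)
    model, _ = train_semi_supervised(graph, fm, GCNConfig(seed=0), train, val)
    return model, fm


class TestMcDropout:
    def test_zero_dropout_gives_identical_passes(self, trained_model):
        model, fm = trained_model
        dist = mc_dropout_predict(model, None, fm, T=5, p=0.0, seed=0)
        assert np.allclose(dist.probs, dist.probs[0][None], atol=1e-12)

    def test_same_seed_reproduces_distribution(self, trained_model):
        model, fm = trained_model
        d1 = mc_dropout_predict(model, None, fm, T=10, p=0.1, seed=4)
        d2 = mc_dropout_predict(model, None, fm, T=10, p=0.1, seed=4)
        assert np.array_equal(d1.probs, d2.probs)

    def test_probability_vectors_sum_to_one(self, trained_model):
        model, fm = trained_model
        dist = mc_dropout_predict(model, None, fm, T=20, p=0.1, seed=1)
        assert np.allclose(dist.probs.sum(axis=2), 1.0, atol=1e-6)
        assert np.allclose(dist.mean_probs, dist.probs.mean(axis=0))

    def test_pass_variance_increases_with_dropout_rate(self, trained_model):
        model, fm = trained_model
        mean_stds = []
        for p in (0.05, 0.1, 0.3):
            per_seed = [
                predictive_std(
                    mc_dropout_predict(model, None, fm, T=30, p=p, seed=s)
                ).mean()
                for s in range(10)
            ]
            mean_stds.append(np.mean(per_seed))
        assert mean_stds[0] < mean_stds[1] < mean_stds[2]

    def test_too_few_passes_rejected(self, trained_model):
        model, fm = trained_model
        with pytest.raises(ValueError):
            mc_dropout_predict(model, None, fm, T=1, p=0.1, seed=0)


class TestUncertaintyMetrics:
    def _dist(self, mu):
        mu = np.asarray(mu, float)[None]  # one node
        return PredictionDistribution(np.repeat(mu[None], 2, axis=0), seed=0)

    def test_confident_prediction_has_zero_entropy(self):
        assert predictive_uncertainty(self._dist([1.0, 0.0]))[0] == 0.0

    def test_uniform_prediction_hits_ln2_ceiling(self):
        u = predictive_uncertainty(self._dist([0.5, 0.5]))[0]
        assert u == pytest.approx(np.log(2))
        assert round(u, 1) == 0.7

    def test_vectorized_entropy_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        raw = rng.random((50, 2))
        mu = raw / raw.sum(axis=1, keepdims=True)
        dist = PredictionDistribution(np.repeat(mu[None], 3, axis=0), seed=0)
        got = predictive_uncertainty(dist)
        for i in range(50):
            expected = -sum(
                p * np.log(p) for p in mu[i] if p > 0
            )
            assert abs(got[i] - expected) < 1e-12

    def test_entropy_maximal_iff_uniform_zero_iff_onehot(self):
        grid = np.linspace(0.0, 1.0, 101)
        mu = np.column_stack([grid, 1 - grid])
        dist = PredictionDistribution(np.repeat(mu[None], 2, axis=0), seed=0)
        u = predictive_uncertainty(dist)
        assert np.all(u >= -1e-12) and np.all(u <= np.log(2) + 1e-12)
        assert u.argmax() == 50  # p = 0.5
        assert u[0] == 0.0 and u[-1] == 0.0

    def test_identical_passes_have_zero_std(self):
        probs = np.repeat(np.array([[[0.3, 0.7]]]), 4, axis=0)
        dist = PredictionDistribution(probs, seed=0)
        assert predictive_std(dist)[0] == 0.0

    def test_alternating_passes_hand_std(self):
        # positive-class probability alternates 0/1 -> population sd = 0.5
        probs = np.zeros((4, 1, 2))
        probs[::2, 0, 1] = 1.0
        probs[1::2, 0, 0] = 1.0
        dist = PredictionDistribution(probs, seed=0)
        assert predictive_std(dist)[0] == pytest.approx(0.5)

    def test_std_bounded_for_probabilities(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet((1, 1), size=(30, 8)).transpose(0, 1, 2)
        dist = PredictionDistribution(probs, seed=0)
        s = predictive_std(dist)
        assert np.all(s >= 0) and np.all(s <= 0.5 + 1e-12)


def test_full_pipeline_smoke_within_budget():
    """220-node cohort trains to convergence quickly on one CPU."""
    import time

    from evtgraph.cohort import default_spec
    from evtgraph.mrmr import mrmr_select

    table = generate_cohort(default_spec(), 220, 3)
    fm = preprocess_pipeline(table, "good_outcome", "followup")
    fm = fm.select_columns(mrmr_select(fm, k=10).selected)
    graph = build_graph(meta_from_cohort(table), GOOD_OUTCOME_RULE)
    train, val, _ = three_way_masks(220, 0)
    t0 = time.time()
    model, log = train_semi_supervised(graph, fm, GCNConfig(seed=0), train, val)
    assert time.time() - t0 < 120
    assert model.fitted and len(log["train_loss"]) >= 30
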