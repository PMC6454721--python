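import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ddibalance import (
    BrsnmfConfig,
    PlantedSpec,
    assign_communities,
    brsnmf,
    default_prediction_rank,
    objective,
    planted_signed_network,
    semi_nmf,
    within_between_report,
)
from ddibalance.factorization import (
    UnassignableNodeError,
    neg_part,
    pos_part,
    update_h,
    update_w,
)

from conftest import random_signed_network


def spectral_partition(net, k, seed=0):
    """Independent oracle: k-means on the top-|eigenvalue| eigenvectors."""
    from sklearn.cluster import KMeans

    vals, vecs = np.linalg.eigh(net.adjacency.astype(float))
    top = np.argsort(-np.abs(vals))[:k]
    emb = vecs[:, top] * np.abs(vals[top])
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)


class TestParts:
    def test_pos_neg_decomposition(self):
        x = np.array([[1.5, -2.0], [0.0, 3.0]])
        np.testing.assert_array_equal(pos_part(x), [[1.5, 0.0], [0.0, 3.0]])
        np.testing.assert_array_equal(neg_part(x), [[0.0, 2.0], [0.0, 0.0]])
        np.testing.assert_array_equal(pos_part(x) - neg_part(x), x)
        assert (pos_part(x) >= 0).all() and (neg_part(x) >= 0).all()


class TestObjective:
    def test_term_by_term_oracle(self):
        """Recompute fit, sparsity and balance terms independently."""
        net = random_signed_network(8, 0, density=0.8)
        a = net.adjacency.astype(float)
        rng = np.random.default_rng(1)
        w = rng.normal(size=(8, 3))
        h = rng.uniform(size=(8, 3))
        cfg = BrsnmfConfig(k=3, alpha=0.7, beta=1.3, eta=0.9, sigma=1.1)
        aplus, aminus = pos_part(a), neg_part(a)
        lplus = np.diag(aplus.sum(axis=1)) - aplus
        fit = np.trace((a - w @ h.T).T @ (a - w @ h.T))
        sparsity = np.trace(h @ np.ones((3, 3)) @ h.T)
        reward = np.trace(h.T @ (cfg.sigma * np.eye(8) - cfg.eta * (aminus + lplus)) @ h)
        expected = fit + cfg.alpha * sparsity - cfg.beta * reward
        assert objective(a, w, h, cfg) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        a = random_signed_network(5, 0).adjacency
        with pytest.raises(ValueError, match="shape"):
            objective(a, np.ones((5, 2)), np.ones((5, 3)), BrsnmfConfig(k=3))


class TestUpdateW:
    def test_identity_indicator_recovers_a(self):
        a = random_signed_network(6, 2).adjacency.astype(float)
        np.testing.assert_allclose(update_w(a, np.eye(6)), a, atol=1e-6)

    def test_single_ones_column_gives_row_means(self):
        a = random_signed_network(7, 3).adjacency.astype(float)
        w = update_w(a, np.ones((7, 1)))
        np.testing.assert_allclose(w[:, 0], a.mean(axis=1), atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_normal_equation_optimality(self, seed):
        """W solves the least-squares problem: perturbing it raises the fit."""
        a = random_signed_network(10, seed).adjacency.astype(float)
        h = np.random.default_rng(seed).uniform(0.1, 1.0, size=(10, 3))
        w = update_w(a, h)
        base = np.linalg.norm(a - w @ h.T) ** 2
        rng = np.random.default_rng(seed + 50)
        for _ in range(5):
            pert = w + 0.01 * rng.normal(size=w.shape)
            assert np.linalg.norm(a - pert @ h.T) ** 2 >= base - 1e-8


class TestUpdateH:
    def test_zero_indicator_is_fixed_point(self):
        a = random_signed_network(6, 0).adjacency.astype(float)
        cfg = BrsnmfConfig(k=2)
        h = np.zeros((6, 2))
        w = np.random.default_rng(0).normal(size=(6, 2))
        np.testing.assert_array_equal(update_h(a, w, h, cfg), h)

    @pytest.mark.parametrize("seed", range(6))
    def test_nonnegativity_and_single_step_descent(self, seed):
        net = random_signed_network(12, seed, density=0.7)
        a = net.adjacency.astype(float)
        cfg = BrsnmfConfig(k=3, seed=seed)
        rng = np.random.default_rng(seed)
        h = rng.uniform(0.1, 1.0, size=(12, 3))
        w = update_w(a, h)
        h_new = update_h(a, w, h, cfg)
        assert (h_new >= 0).all()
        assert objective(a, w, h_new, cfg) <= objective(a, w, h, cfg) + 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_unregularized_update_matches_semi_nmf_formula(self, seed):
        """With alpha = beta = 0 the step reduces to the classic rule."""
        a = random_signed_network(9, seed).adjacency.astype(float)
        rng = np.random.default_rng(seed)
        h = rng.uniform(0.1, 1.0, size=(9, 2))
        w = rng.normal(size=(9, 2))
        cfg = BrsnmfConfig(k=2, alpha=0.0, beta=0.0)
        aw, wtw = a @ w, w.T @ w
        classic = h * np.sqrt(
            (pos_part(aw) + h @ neg_part(wtw))
            / (neg_part(aw) + h @ pos_part(wtw) + cfg.epsilon)
        )
        np.testing.assert_allclose(update_h(a, w, h, cfg), classic, rtol=1e-12)


class TestSemiNmf:
    def test_recovers_planted_low_rank_matrix(self):
        """A ~ W H^T exactly when A was built as such a product."""
        rng = np.random.default_rng(0)
        h_true = np.zeros((12, 3))
        h_true[np.arange(12), np.repeat(np.arange(3), 4)] = 1.0
        w_true = rng.normal(size=(12, 3))
        a = w_true @ h_true.T
        a = (a + a.T) / 2
        res = semi_nmf(a, k=12, max_iter=2000, tol=1e-14, seed=0, init="random")
        assert np.linalg.norm(a - res.W @ res.H.T) / np.linalg.norm(a) < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_monotone(self, seed):
        net = random_signed_network(15, seed, density=0.6)
        res = semi_nmf(net, k=3, seed=seed, max_iter=200)
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-8 * np.maximum(np.abs(res.objective_trace[:-1]), 1)).all()

    def test_full_rank_factorization_near_exact(self):
        a = random_signed_network(8, 1, density=0.9).adjacency.astype(float)
        res = semi_nmf(a, k=8, max_iter=3000, tol=1e-14, seed=3, init="random")
        assert np.linalg.norm(a - res.W @ res.H.T) / max(np.linalg.norm(a), 1) < 0.05


class TestBrsnmf:
    @pytest.mark.parametrize("seed", range(5))
    def test_reduces_to_semi_nmf_without_regularizers(self, seed):
        net = random_signed_network(12, seed, density=0.7)
        cfg = BrsnmfConfig(k=3, alpha=0.0, beta=0.0, seed=seed, max_iter=60)
        r1 = brsnmf(net, cfg)
        r2 = semi_nmf(net, k=3, seed=seed, max_iter=60)
        np.testing.assert_allclose(r1.H, r2.H, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(r1.W, r2.W, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(r1.objective_trace, r2.objective_trace, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_monotone_with_regularizers(self, seed):
        net = random_signed_network(15, seed, density=0.6)
        res = brsnmf(net, BrsnmfConfig(k=3, seed=seed, max_iter=200))
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-8 * np.maximum(np.abs(res.objective_trace[:-1]), 1)).all()

    def test_recovers_two_planted_communities_exactly(self):
        spec = PlantedSpec(
            community_sizes=(20, 20),
            within_edge_prob=0.9,
            between_edge_prob=0.9,
            flip_rate=0.05,
            seed=0,
        )
        net, truth = planted_signed_network(spec)
        res = brsnmf(net, BrsnmfConfig(k=2, seed=0))
        found = assign_communities(res.H)
        assert adjusted_rand_score(truth.assignment, found.assignment) == 1.0

    def test_matches_spectral_oracle_on_two_blocks(self):
        spec = PlantedSpec(
            community_sizes=(20, 20),
            within_edge_prob=0.9,
            between_edge_prob=0.9,
            flip_rate=0.05,
            seed=1,
        )
        net, _ = planted_signed_network(spec)
        found = assign_communities(brsnmf(net, BrsnmfConfig(k=2, seed=1)).H)
        oracle = spectral_partition(net, 2, seed=1)
        assert adjusted_rand_score(oracle, found.assignment) == 1.0

    def test_weakly_balanced_block_detected_as_degressive(self):
        """A planted all-negative community shows a negative within-contrast."""
        spec = PlantedSpec(
            community_sizes=(20, 20, 20),
            within_edge_prob=0.9,
            between_edge_prob=0.9,
            within_sign=(1, 1, -1),
            flip_rate=0.05,
            seed=0,
        )
        net, truth = planted_signed_network(spec)
        rep = within_between_report(net, truth)
        assert rep.delta_within[2] < 0 < min(rep.delta_within[0], rep.delta_within[1])

    def test_permutation_equivariance(self):
        """Relabeling the nodes permutes the recovered partition identically."""
        spec = PlantedSpec(
            community_sizes=(15, 15),
            within_edge_prob=0.9,
            between_edge_prob=0.9,
            flip_rate=0.05,
            seed=4,
        )
        net, _ = planted_signed_network(spec)
        base = assign_communities(brsnmf(net, BrsnmfConfig(k=2, seed=0)).H)
        perm = np.random.default_rng(7).permutation(net.n_nodes)
        from ddibalance import SignedNetwork

        net_p = SignedNetwork(
            labels=tuple(net.labels[i] for i in perm),
            adjacency=net.adjacency[np.ix_(perm, perm)],
        )
        permuted = assign_communities(brsnmf(net_p, BrsnmfConfig(k=2, seed=0)).H)
        assert adjusted_rand_score(
            base.assignment[perm], permuted.assignment
        ) == 1.0

    def test_indicator_stays_nonnegative(self):
        net = random_signed_network(20, 5, density=0.6)
        res = brsnmf(net, BrsnmfConfig(k=4, seed=5, max_iter=100))
        assert (res.H >= 0).all()

    def test_k_larger_than_nodes_rejected(self):
        net = random_signed_network(4, 0)
        with pytest.raises(ValueError, match="exceeds"):
            brsnmf(net, BrsnmfConfig(k=5))


class TestAssignCommunities:
    def test_argmax_with_low_index_tie_break(self):
        h = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.9]])
        part = assign_communities(h)
        np.testing.assert_array_equal(part.assignment, [1, 1, 2])

    def test_zero_row_rejected(self):
        h = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(UnassignableNodeError):
            assign_communities(h)

    def test_empty_community_compacted_with_warning(self):
        h = np.array([[1.0, 0.0, 0.1], [0.8, 0.0, 0.2], [0.1, 0.0, 0.9]])
        with pytest.warns(UserWarning, match="empty"):
            part = assign_communities(h)
        assert part.k == 2
        np.testing.assert_array_equal(part.assignment, [1, 1, 2])


class TestDefaultPredictionRank:
    def test_tenth_of_numerical_rank(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(size=(60, 30))
        a = h @ h.T  # rank 30 -> k = 3
        assert default_prediction_rank(a) == 3

    def test_floor_of_one(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1.0
        assert default_prediction_rank(a) == 1
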