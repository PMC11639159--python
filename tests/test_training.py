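"""Augmentation, view encoding, loss identities, and the training loop."""

import numpy as np
import pytest

from dtifuse import autodiff as ad
from dtifuse.autodiff import Tensor
from dtifuse.data_model import ValidationError
from dtifuse.dtp import DTPGraph, DTPNode, build_adjacency
from dtifuse.training import (
    CausalLossParams,
    DTPAttentionEncoder,
    TrainConfig,
    augment,
    bce_loss,
    causal_loss,
    classify,
    encode_view,
    normalize_dims,
    select_stable_nodes,
    train,
)


def _random_graph(rng, n=30, d=6):
    A = (rng.random((n, n)) < 0.15).astype(int)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0)
    return A, rng.normal(size=(n, d))


class TestAugment:
    def test_zero_rate_is_identity(self, rng):
        A, H = _random_graph(rng)
        v = augment(A, H, 0.0, rng)
        assert np.array_equal(v.A_aug, A) and np.array_equal(v.H_aug, H)

    def test_full_rate_empties_everything(self, rng):
        A, H = _random_graph(rng)
        v = augment(A, H, 1.0, rng)
        assert v.A_aug.sum() == 0 and np.all(v.H_aug == 0.0)

    def test_only_removals_and_exact_column_zeroing(self, rng):
        A, H = _random_graph(rng)
        v = augment(A, H, 0.4, rng)
        assert np.all(v.A_aug <= A)
        dropped = ~v.feat_mask
        assert np.all(v.H_aug[:, dropped] == 0.0)
        assert np.array_equal(v.H_aug[:, v.feat_mask], H[:, v.feat_mask])

    def test_drop_fraction_within_binomial_band(self):
        # pooled over 50 seeds: dropped edges ~ Binomial(50 E, rho)
        rho, n = 0.3, 60
        A = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        E = n * (n - 1) // 2
        total, dropped = 0, 0
        for seed in range(50):
            v = augment(A, np.ones((n, 2)), rho, np.random.default_rng(seed))
            total += E
            dropped += E - int(v.edge_mask.sum())
        sd = np.sqrt(total * rho * (1 - rho))
        assert abs(dropped - rho * total) <= 3 * sd

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValidationError):
            augment(np.zeros((2, 2)), np.zeros((2, 2)), 1.5, rng)


class TestEncodeView:
    def test_identical_views_encode_identically(self, rng):
        A, H = _random_graph(rng)
        enc = DTPAttentionEncoder(6, 5, 4, np.random.default_rng(0))
        X1 = encode_view(A, H, enc)
        X2 = encode_view(A, H, enc)
        assert np.array_equal(X1.data, X2.data)

    def test_permutation_equivariance(self, rng):
        A, H = _random_graph(rng, n=12)
        enc = DTPAttentionEncoder(6, 5, 4, np.random.default_rng(0))
        perm = rng.permutation(12)
        X = encode_view(A, H, enc).data
        Xp = encode_view(A[np.ix_(perm, perm)], H[perm], enc).data
        assert np.allclose(Xp, X[perm], atol=1e-10)

    def test_isolated_node_depends_only_on_own_features(self, rng):
        A, H = _random_graph(rng, n=10)
        A[3, :] = 0
        A[:, 3] = 0
        enc = DTPAttentionEncoder(6, 5, 4, np.random.default_rng(1))
        X = encode_view(A, H, enc).data
        H2 = H.copy()
        H2[[i for i in range(10) if i != 3]] += 1.0  # perturb everyone else
        X2 = encode_view(A, H2, enc).data
        assert np.allclose(X[3], X2[3])


class TestNormalizeDims:
    def test_two_element_column_hand_values(self):
        X = Tensor(np.array([[1.0], [-1.0]]))
        Xt, s = normalize_dims(X)
        assert np.allclose(Xt.data[:, 0], [1 / np.sqrt(2), -1 / np.sqrt(2)])
        assert np.allclose(s.data, [1.0])  # population std

    def test_constant_column_floored_not_raised(self):
        Xt, s = normalize_dims(Tensor(np.full((4, 2), 3.0)))
        assert np.allclose(Xt.data, 0.0) and np.allclose(s.data, 0.0)

    def test_unit_norm_columns(self, rng):
        Xt, s = normalize_dims(Tensor(rng.normal(size=(20, 5))))
        norms = np.linalg.norm(Xt.data, axis=0)
        assert np.all(norms <= 1.0 + 1e-12) and np.all(norms >= 1.0 - 1e-6)


def causal_loss_loop_oracle(X1, X2, alpha, beta, lam):
    """Independent per-column implementation: center, normalize, dot, penalty."""
    total = 0.0
    for i in range(X1.shape[1]):
        a = X1[:, i] - X1[:, i].mean()
        b = X2[:, i] - X2[:, i].mean()
        s1 = np.sqrt((a ** 2).mean())
        s2 = np.sqrt((b ** 2).mean())
        an = a / (np.linalg.norm(a) + 1e-12)
        bn = b / (np.linalg.norm(b) + 1e-12)
        total += -alpha * (an @ bn) + beta * ((s1 - lam) ** 2 + (s2 - lam) ** 2)
    return total


class TestCausalLoss:
    def test_identical_views_with_std_lambda_give_minus_alpha_d(self, rng):
        d = 7
        X = rng.normal(size=(50, d))
        X = (X - X.mean(0)) / X.std(0)  # per-dimension std exactly 1 = lambda
        loss, parts = causal_loss(Tensor(X), Tensor(X.copy()),
                                  CausalLossParams(alpha=1.0, beta=1.0, lam=1.0))
        assert loss.item() == pytest.approx(-d, abs=1e-9)
        assert parts["std_penalty"] == pytest.approx(0.0, abs=1e-12)

    def test_anti_aligned_views_give_plus_alpha_d(self, rng):
        X = rng.normal(size=(30, 4))
        X = X - X.mean(0)
        loss, _ = causal_loss(Tensor(X), Tensor(-X),
                              CausalLossParams(alpha=1.0, beta=0.0, lam=1.0))
        assert loss.item() == pytest.approx(4.0, abs=1e-9)

    def test_matches_per_column_loop_oracle(self, rng):
        X1 = rng.normal(size=(4, 3))
        X2 = rng.normal(size=(4, 3))
        p = CausalLossParams(alpha=0.7, beta=1.3, lam=0.9)
        loss, _ = causal_loss(Tensor(X1), Tensor(X2), p)
        assert loss.item() == pytest.approx(
            causal_loss_loop_oracle(X1, X2, 0.7, 1.3, 0.9), abs=1e-6)

    def test_invariant_to_common_node_permutation(self, rng):
        X1 = rng.normal(size=(12, 5))
        X2 = rng.normal(size=(12, 5))
        p = CausalLossParams()
        perm = rng.permutation(12)
        l1, _ = causal_loss(Tensor(X1), Tensor(X2), p)
        l2, _ = causal_loss(Tensor(X1[perm]), Tensor(X2[perm]), p)
        assert l1.item() == pytest.approx(l2.item(), abs=1e-10)

    def test_finite_difference_gradients(self, rng):
        X1 = rng.normal(size=(5, 4))
        X2 = rng.normal(size=(5, 4))
        p = CausalLossParams(alpha=1.0, beta=1.0, lam=1.0)
        t1, t2 = Tensor(X1, requires_grad=True), Tensor(X2, requires_grad=True)
        loss, _ = causal_loss(t1, t2, p)
        loss.backward()
        eps = 1e-6
        for t, X in ((t1, X1), (t2, X2)):
            num = np.zeros_like(X)
            for i in range(X.shape[0]):
                for j in range(X.shape[1]):
                    Xp, Xm = X.copy(), X.copy()
                    Xp[i, j] += eps
                    Xm[i, j] -= eps
                    lp, _ = causal_loss(Tensor(Xp if t is t1 else X1),
                                        Tensor(Xp if t is t2 else X2), p)
                    lm, _ = causal_loss(Tensor(Xm if t is t1 else X1),
                                        Tensor(Xm if t is t2 else X2), p)
                    num[i, j] = (lp.item() - lm.item()) / (2 * eps)
            assert np.allclose(t.grad, num, atol=1e-4)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            causal_loss(Tensor(rng.normal(size=(3, 2))),
                        Tensor(rng.normal(size=(4, 2))), CausalLossParams())


class TestClassifierAndBCE:
    def test_zero_parameters_give_half(self):
        X = Tensor(np.random.default_rng(0).normal(size=(6, 4)))
        pi = classify(X, Tensor(np.zeros((4, 1))), Tensor(np.zeros(1)))
        assert np.allclose(pi.data, 0.5)

    def test_saturation_and_monotonicity(self):
        w = Tensor(np.array([[2.0]]))
        b = Tensor(np.zeros(1))
        lo = classify(Tensor([[1.0]]), w, b).data
        hi = classify(Tensor([[50.0]]), w, b).data
        assert hi > lo and hi > 0.999

    def test_bce_closed_form_at_half(self):
        pi = Tensor(np.full((10, 1), 0.5))
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0])
        assert bce_loss(pi, y).item() == pytest.approx(10 * np.log(2))

    def test_bce_hand_example_and_mean_reduction(self):
        pi = Tensor(np.array([[0.9], [0.2]]))
        y = np.array([1, 0])
        expected = -(np.log(0.9) + np.log(0.8))
        assert bce_loss(pi, y).item() == pytest.approx(expected)
        assert bce_loss(pi, y, reduction="mean").item() == pytest.approx(expected / 2)

    def test_bce_clamps_and_warns_on_saturated_probabilities(self):
        pi = Tensor(np.array([[1.0], [0.0]]))
        with pytest.warns(RuntimeWarning):
            loss = bce_loss(pi, np.array([1, 0]))
        assert np.isfinite(loss.item())


def _toy_graph(rng, n_pairs=40):
    nodes = [DTPNode(int(rng.integers(5)), int(rng.integers(6)), int(rng.integers(2)))
             for _ in range(n_pairs)]
    H = rng.normal(size=(n_pairs, 6))
    # make labels weakly learnable from features
    H[:, 0] += 2.0 * np.array([nd.label for nd in nodes])
    A = build_adjacency(nodes, "shared_entity")
    return DTPGraph(nodes, H, A, "shared_entity")


class TestTrainLoop:
    def test_frozen_seed_reproduces_loss_history_exactly(self, rng):
        g = _toy_graph(rng)
        idx = np.arange(g.n_nodes)
        cfg = TrainConfig(epochs=8, d_out=4, hidden=5)
        h1 = train(g, idx, cfg, seed=3).history
        h2 = train(g, idx, cfg, seed=3).history
        assert np.array_equal(h1["L"].to_numpy(), h2["L"].to_numpy())

    def test_supervised_training_reduces_loss(self, rng):
        g = _toy_graph(rng, n_pairs=60)
        idx = np.arange(g.n_nodes)
        cfg = TrainConfig(epochs=50, d_out=4, hidden=8, alpha=0.0, beta=0.0,
                          rho=0.0, dropout=0.0)
        h = train(g, idx, cfg, seed=0, variant="supervised").history
        first = h["L_CE"].iloc[:5].mean()
        last = h["L_CE"].iloc[-5:].mean()
        assert last < first

    def test_no_causal_variant_logs_but_does_not_step_on_lcl(self, rng):
        g = _toy_graph(rng)
        idx = np.arange(g.n_nodes)
        cfg = TrainConfig(epochs=5, d_out=4, hidden=5)
        r = train(g, idx, cfg, seed=1, variant="no_causal")
        assert np.isfinite(r.history["L_CL"]).all()
        assert np.array_equal(r.history["L"].to_numpy(),
                              r.history["L_CE"].to_numpy())

    def test_attention_rows_normalized_throughout_training(self, rng):
        g = _toy_graph(rng)
        idx = np.arange(g.n_nodes)
        r = train(g, idx, TrainConfig(epochs=5, d_out=4, hidden=5), seed=2)
        assert r.max_attention_row_dev < 1e-6

    def test_unknown_variant_rejected(self, rng):
        g = _toy_graph(rng)
        with pytest.raises(ValidationError):
            train(g, np.arange(g.n_nodes), TrainConfig(epochs=1), 0, variant="bogus")


class TestStableNodeSelector:
    def test_selects_least_changed_nodes(self):
        X1 = np.zeros((4, 2))
        X2 = np.array([[0.0, 0.0], [5.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        assert list(select_stable_nodes(X1, X2, 0.5)) == [0, 2]
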