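import numpy as np
import pytest

from genemorph.morphology import (
    ModelParams,
    MorphologyGeneModel,
    SlideBag,
    TrainConfig,
    dis_loss,
    encode_patches,
    gene_project,
    graph_loss,
    pool_slide,
    predict,
    total_loss,
    train,
    _backward,
    _forward,
)
from genemorph.network import CoexpressionNetwork, laplacian

from conftest import make_bags


def _params(seed=0, P=6, H=4, W=5, G=3, dtype="float64"):
    rng = np.random.default_rng(seed)
    p = ModelParams.init(rng, P, H, G, width=W, dtype=dtype, head_noise=1.0)
    p.wc = rng.standard_normal(G) * 0.4
    p.bc = 0.2
    return p


class TestForwardOps:
    def test_shared_encoder_maps_identical_rows_identically(self):
        p = _params()
        X = np.vstack([np.ones(6), np.ones(6), np.zeros(6)])
        Z = encode_patches(X, p)
        np.testing.assert_array_equal(Z[0], Z[1])
        assert not np.allclose(Z[0], Z[2])

    def test_encoder_deterministic_bit_for_bit(self):
        p = _params(1)
        X = np.random.default_rng(2).standard_normal((4, 6))
        np.testing.assert_array_equal(encode_patches(X, p), encode_patches(X, p))

    def test_encoder_dimension_mismatch(self):
        with pytest.raises(ValueError):
            encode_patches(np.ones((2, 9)), _params())

    def test_gene_project_identity_block_and_bias_only(self):
        Z = np.random.default_rng(0).standard_normal((3, 4))
        W = np.zeros((2, 4))
        W[0, 0] = W[1, 1] = 1.0
        np.testing.assert_allclose(gene_project(Z, W, np.zeros(2)), Z[:, :2])
        b = np.array([1.5, -2.0])
        np.testing.assert_allclose(gene_project(Z, np.zeros((2, 4)), b), np.tile(b, (3, 1)))

    def test_gene_project_matches_row_loop(self):
        rng = np.random.default_rng(3)
        Z, W, b = rng.standard_normal((4, 5)), rng.standard_normal((3, 5)), rng.standard_normal(3)
        expected = np.array([[W[j] @ z + b[j] for j in range(3)] for z in Z])
        np.testing.assert_allclose(gene_project(Z, W, b), expected)

    def test_pool_examples_and_commutativity(self):
        assert pool_slide(np.array([[1.0, 2.0]])).tolist() == [1.0, 2.0]
        np.testing.assert_allclose(pool_slide(np.array([[1.0, 2], [3, 4]])), [2.0, 3.0])
        rng = np.random.default_rng(4)
        Z, W, b = rng.standard_normal((6, 5)), rng.standard_normal((3, 5)), rng.standard_normal(3)
        np.testing.assert_allclose(
            pool_slide(gene_project(Z, W, b)), W @ Z.mean(axis=0) + b, atol=1e-6
        )
        with pytest.raises(ValueError):
            pool_slide(np.empty((0, 3)))

    def test_predict_sigmoid(self):
        assert predict(np.array([1.0]), np.array([0.0]), 0.0) == 0.5
        assert predict(np.array([1.0]), np.array([0.3]), 0.2) == pytest.approx(
            1 / (1 + np.exp(-0.5))
        )
        assert predict(np.array([1.0]), np.array([0.0]), 50.0) > 1 - 1e-9


class TestLosses:
    def test_graph_loss_constants_and_hand_value(self):
        L = laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert graph_loss(np.array([3.0, 3.0]), L) == 0.0
        assert graph_loss(np.array([1.0, 0.0]), L) == pytest.approx(1.0)

    def test_graph_loss_dual_form(self, small_network):
        rng = np.random.default_rng(5)
        g = rng.standard_normal(small_network.n_genes)
        A = small_network.adjacency
        pairwise = 0.5 * np.sum(A * (g[:, None] - g[None, :]) ** 2)
        assert graph_loss(g, small_network.laplacian) == pytest.approx(pairwise, rel=1e-9)

    def test_dis_loss_orthonormal_and_collapsed(self):
        assert dis_loss(np.eye(3)) == pytest.approx(0.0)
        col = np.array([[1.0], [0.0]])
        two_identical = np.hstack([col, col])
        assert dis_loss(two_identical) == pytest.approx(np.sqrt(2.0))

    def test_dis_loss_matches_definitional_oracle(self):
        rng = np.random.default_rng(6)
        G = rng.standard_normal((6, 3))
        Gt = G / np.linalg.norm(G, axis=0)
        expected = np.linalg.norm(Gt.T @ Gt - np.eye(3))
        assert dis_loss(G) == pytest.approx(expected, rel=1e-12)

    def test_dis_loss_single_patch_rejected(self):
        with pytest.raises(ValueError):
            dis_loss(np.ones((1, 3)))

    def test_total_loss_composition(self, small_network):
        rng = np.random.default_rng(7)
        G = small_network.n_genes
        Gmat = rng.standard_normal((4, G))
        Ghat = Gmat.mean(axis=0)
        L = small_network.laplacian
        lb = total_loss(0.8, 1, Ghat, Gmat, L, 1.0, 0.1)
        assert lb.total == pytest.approx(lb.cls + lb.graph + 0.1 * lb.dis, rel=1e-12)
        lb0 = total_loss(0.8, 1, Ghat, Gmat, L, 0.0, 0.0)
        assert lb0.total == pytest.approx(lb0.cls)
        assert lb0.cls == pytest.approx(-np.log(0.8))

    def test_total_loss_clamps_extreme_predictions(self, small_network):
        G = small_network.n_genes
        Gmat = np.ones((3, G))
        lb = total_loss(1.0, 0, Gmat.mean(0), Gmat, small_network.laplacian)
        assert np.isfinite(lb.cls) and lb.cls > 10


class TestGradients:
    def test_backward_matches_finite_differences(self, small_network):
        """Analytic gradients of the full composite loss vs central differences."""
        rng = np.random.default_rng(0)
        G = small_network.n_genes
        p = _params(0, P=7, H=5, W=6, G=G)
        L = small_network.laplacian
        X = rng.standard_normal((5, 7))
        y = 1
        cfg = TrainConfig(lambda_graph=0.7, lambda_dis=0.3, dropout=0.0,
                          width=6, hidden=5, dtype="float64", align_weight=0.2)
        target = rng.standard_normal(G)

        def loss_at():
            c = _forward(X, p)
            lb = total_loss(c["yhat"], y, c["Ghat"], c["Gmat"], L,
                            cfg.lambda_graph, cfg.lambda_dis)
            return lb.total + cfg.align_weight * np.mean((c["Ghat"] - target) ** 2)

        g = _backward(X, y, _forward(X, p), p, L, cfg, align_target=target)
        eps = 1e-6
        for name in ("W1", "b1", "W2", "b2", "Wg", "bg", "wc"):
            arr = getattr(p, name)
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss_at()
                arr[idx] = orig - eps
                lm = loss_at()
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-8), name


class TestTraining:
    def _net(self, dim=3):
        A = np.full((dim, dim), 0.5)
        np.fill_diagonal(A, 0.0)
        return CoexpressionNetwork.from_adjacency([f"g{i}" for i in range(dim)], A)

    def test_single_epoch_history_bookkeeping(self, tiny_bags):
        cfg = TrainConfig(epochs=1, width=8, hidden=4, seed=0)
        params, history, tr, va = train(tiny_bags, self._net(), cfg)
        assert len(history) == 1
        assert set(tr).isdisjoint(va)
        assert len(tr) + len(va) == len(tiny_bags)

    def test_fixed_seed_reproduces_history_exactly(self, tiny_bags):
        cfg = TrainConfig(epochs=3, width=8, hidden=4, seed=5)
        net = self._net()
        _, h1, tr1, _ = train(tiny_bags, net, cfg)
        _, h2, tr2, _ = train(tiny_bags, net, cfg)
        assert tr1 == tr2
        assert h1.equals(h2)

    def test_single_class_rejected(self):
        bags = make_bags(6)
        labels = {b.slide_id: 1 for b in bags}
        with pytest.raises(ValueError):
            train(bags, self._net(), TrainConfig(width=8, hidden=4), labels=labels)

    def test_loss_composition_holds_every_step(self, tiny_bags):
        # the in-run identity assertion would raise if violated
        cfg = TrainConfig(epochs=2, width=8, hidden=4, seed=1,
                          lambda_graph=1.0, lambda_dis=0.1)
        _, history, _, _ = train(tiny_bags, self._net(), cfg)
        for _, row in history.iterrows():
            assert row["train_total"] == pytest.approx(
                row["train_cls"] + row["train_graph"] + 0.1 * row["train_dis"], rel=1e-5
            )

    def test_model_learns_separable_bags(self):
        bags = make_bags(n_slides=24, n_patches=5, dim=8, seed=3, signal=4.0)
        net = self._net(4)
        cfg = TrainConfig(epochs=25, width=16, hidden=8, seed=0, lr=1e-3)
        res = MorphologyGeneModel(bags, net, cfg).fit()
        assert res.validation_auc == 1.0
        scores = res.predict(bags)
        assert scores.shape == (24,)
        latents = res.gene_latents(bags[:3])
        assert latents.shape == (3, 4)
        assert "validation AUC" in res.summary()

    def test_params_npz_round_trip(self, tmp_path, tiny_bags):
        cfg = TrainConfig(epochs=1, width=8, hidden=4, seed=2)
        res = MorphologyGeneModel(tiny_bags, self._net(), cfg).fit()
        p = tmp_path / "m.npz"
        res.params.to_npz(p)
        back = ModelParams.from_npz(p)
        np.testing.assert_array_equal(back.W1, res.params.W1)
        assert back.bc == res.params.bc
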