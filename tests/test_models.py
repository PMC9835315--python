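"""Classical classifiers, the autodiff engine, and the attention networks."""

import numpy as np
import pytest

from molfusion.models import autodiff as ad
from molfusion.models.classical import (
    CLASSICAL_FAMILIES,
    ModelSpec,
    load_search_spaces,
    randomized_search,
    train_classical,
)
from molfusion.models.networks import (
    AttentionConfig,
    SelfAttention,
    build_fusion_net,
    build_smiles_net,
    train_network,
)


def _separable(n=80, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    X[y == 1] += 2.0
    return X, y


class TestClassical:
    def test_all_families_fit_and_score_in_unit_interval(self):
        X, y = _separable()
        for family in CLASSICAL_FAMILIES:
            model = train_classical(ModelSpec(family, {}, seed=0), X, y)
            s = model.score(X)
            assert s.shape == (len(X),)
            assert (s >= 0).all() and (s <= 1).all()
            preds = model.predict(X)
            np.testing.assert_array_equal(preds.labels, (preds.scores >= 0.5))

    @pytest.mark.parametrize("family", ["DT", "RF"])
    def test_trees_memorize_separable_data(self, family):
        X, y = _separable()
        model = train_classical(ModelSpec(family, {}, 0), X, y)
        assert (model.predict(X).labels == y).mean() == 1.0

    def test_gnb_label_flip_symmetry(self):
        from sklearn.metrics import roc_auc_score
        X, y = _separable(n=200, seed=1)
        s = train_classical(ModelSpec("GNB", {}, 0), X, y).score(X)
        s_flip = train_classical(ModelSpec("GNB", {}, 0), X, 1 - y).score(X)
        auc = roc_auc_score(y, s)
        auc_flip = roc_auc_score(y, s_flip)
        assert auc_flip == pytest.approx(1 - auc, abs=1e-9)

    def test_deterministic_families_repeat_bitwise(self):
        X, y = _separable(n=120, seed=2)
        for family, hp in (("ABDT", {"n_estimators": 50}), ("GNB", {}),
                           ("LR", {"C": 1.0})):
            runs = [train_classical(ModelSpec(family, hp, seed), X, y).score(X)
                    for seed in (0, 1, 2)]
            np.testing.assert_array_equal(runs[0], runs[1])
            np.testing.assert_array_equal(runs[0], runs[2])

    def test_single_class_labels_rejected(self):
        X, _ = _separable()
        with pytest.raises(ValueError, match="single class"):
            train_classical(ModelSpec("RF", {}, 0), X, np.zeros(len(X), int))

    def test_search_spaces_cover_all_families(self):
        spaces = load_search_spaces()
        assert set(spaces) == set(CLASSICAL_FAMILIES)

    def test_randomized_search_singleton_and_determinism(self):
        X, y = _separable(n=100, seed=3)
        spec, _ = randomized_search("LR", X, y, seed=0,
                                    search_space={"C": [2.0]})
        assert spec.hyperparameters == {"C": 2.0}
        s1, _ = randomized_search("RF", X, y, n_iter=3, seed=5)
        s2, _ = randomized_search("RF", X, y, n_iter=3, seed=5)
        assert s1.hyperparameters == s2.hyperparameters


class TestAutodiff:
    """Finite-difference gradient checks for the engine's operations."""

    def _check(self, build, shapes, seed=0):
        rng = np.random.default_rng(seed)
        tensors = [ad.Tensor(rng.normal(size=s), requires_grad=True)
                   for s in shapes]
        out = build(*tensors)
        out.backward()
        eps = 1e-6
        for t in tensors:
            flat_idx = np.unravel_index(rng.integers(t.data.size), t.data.shape)
            orig = t.data[flat_idx]
            t.data[flat_idx] = orig + eps
            lp = float(build(*tensors).data)
            t.data[flat_idx] = orig - eps
            lm = float(build(*tensors).data)
            t.data[flat_idx] = orig
            num = (lp - lm) / (2 * eps)
            assert t.grad[flat_idx] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_matmul_and_arithmetic(self):
        self._check(lambda a, b: ((a @ b) * 2.0 + a.sum()).sum(),
                    [(3, 4), (4, 2)])

    def test_batched_matmul_broadcasting(self):
        self._check(lambda a, b: (a @ b).sum(), [(2, 3, 4), (4, 5)])

    def test_nonlinearities_and_softmax(self):
        self._check(lambda a: (a.tanh().sigmoid() + a.softmax()).sum(), [(3, 5)])

    def test_slicing_and_stack(self):
        self._check(lambda a, b: ad.stack([a[:, :2], b[:, 2:]], axis=1).sum(),
                    [(3, 4), (3, 4)])

    def test_embedding_and_bce(self):
        ids = np.array([[1, 2], [2, 0]])
        y = np.array([[1.0], [0.0]])

        def build(w, h):
            e = ad.embedding_lookup(w, ids)
            pooled = e.sum(axis=1)
            return ad.bce_with_logits(pooled @ h, y)

        self._check(build, [(4, 3), (3, 1)])

    def test_lstm_network_gradient(self):
        net = build_smiles_net(AttentionConfig(lstm_hidden=4, attention_dim=3),
                               {"C": 1, "O": 2}, seed=0)
        seqs = np.array([[1, 2, 1, 0], [2, 1, 0, 0]])
        y = np.array([1.0, 0.0])
        loss = ad.bce_with_logits(net.forward(seqs), y)
        loss.backward()
        w = net.lstm[1].Wh
        idx = (2, 5)
        eps = 1e-6
        orig = w.data[idx]
        w.data[idx] = orig + eps
        lp = float(ad.bce_with_logits(net.forward(seqs), y).data)
        w.data[idx] = orig - eps
        lm = float(ad.bce_with_logits(net.forward(seqs), y).data)
        w.data[idx] = orig
        assert w.grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)


class TestSelfAttention:
    def test_identical_inputs_give_identical_outputs(self):
        rng = np.random.default_rng(0)
        att = SelfAttention(6, 4, rng)
        x = np.tile(rng.normal(size=(1, 1, 6)), (2, 5, 1))
        out = att(ad.Tensor(x)).data
        for t in range(1, 5):
            np.testing.assert_allclose(out[:, t], out[:, 0], atol=1e-12)

    def test_length_one_sequence_is_v_projection(self):
        rng = np.random.default_rng(1)
        att = SelfAttention(6, 4, rng)
        x = rng.normal(size=(3, 1, 6))
        out = att(ad.Tensor(x)).data
        np.testing.assert_allclose(out, x @ att.Wv.data, atol=1e-12)

    def test_softmax_rows_normalized(self):
        z = ad.Tensor(np.random.default_rng(2).normal(size=(4, 7)))
        s = z.softmax().data
        np.testing.assert_allclose(s.sum(axis=-1), 1.0, atol=1e-12)

    def test_padding_positions_are_ignored(self):
        rng = np.random.default_rng(3)
        att = SelfAttention(6, 4, rng)
        x = rng.normal(size=(1, 5, 6))
        mask = np.array([[True, True, True, False, False]])
        out_masked = att(ad.Tensor(x), pad_mask=mask).data
        x2 = x.copy()
        x2[:, 3:] = 99.0  # garbage in padded positions
        out_masked2 = att(ad.Tensor(x2), pad_mask=mask).data
        np.testing.assert_allclose(out_masked[:, :3], out_masked2[:, :3], atol=1e-9)


class TestNetworks:
    def test_fusion_net_shapes_and_scores(self):
        cfg = AttentionConfig(projection_dim=8, attention_dim=4, hidden_dim=8)
        for n_blocks in (1, 2, 3):
            net = build_fusion_net(cfg, n_blocks, block_dim=16, seed=0)
            blocks = [np.random.default_rng(n_blocks).normal(size=(10, 16))
                      for _ in range(n_blocks)]
            s = net.scores(blocks)
            assert s.shape == (10,)
            assert ((s > 0) & (s < 1)).all()
            # four fully connected layers in total
            assert len(net.projections) + len(net.hidden) + 1 == 4

    def test_untrained_fusion_scores_center_near_half(self):
        cfg = AttentionConfig(projection_dim=16, attention_dim=8)
        net = build_fusion_net(cfg, 3, block_dim=32, seed=1)
        blocks = [np.random.default_rng(i).normal(size=(1000, 32))
                  for i in range(3)]
        assert 0.4 < net.scores(blocks).mean() < 0.6

    def test_smiles_net_contract(self):
        cfg = AttentionConfig(lstm_hidden=4, attention_dim=3)
        vocab = {"C": 1, "O": 2, "N": 3}
        net = build_smiles_net(cfg, vocab, seed=0)
        assert net.embedding.data.shape[1] == 100
        assert len(net.lstm) == 4
        assert np.all(net.embedding.data[0] == 0)  # pad row
        with pytest.raises(ValueError, match="all-pad"):
            net.forward(np.zeros((2, 5), dtype=int))
        with pytest.raises(ValueError, match="vocabulary"):
            net.forward(np.array([[9, 9]]))

    def test_embedding_dim_and_layer_count_are_fixed(self):
        with pytest.raises(ValueError):
            AttentionConfig(embedding_dim=64)
        with pytest.raises(ValueError):
            AttentionConfig(lstm_layers=2)

    def test_training_is_seed_deterministic(self):
        rng = np.random.default_rng(0)
        X = [rng.normal(size=(60, 8)), rng.normal(size=(60, 8))]
        y = (X[0][:, 0] > 0).astype(float)
        cfg = AttentionConfig(projection_dim=6, attention_dim=4, hidden_dim=6,
                              max_epochs=3, batch_size=32)

        def run():
            net = build_fusion_net(cfg, 2, block_dim=8, seed=7)
            train_network(net, [X[0][:40], X[1][:40]], y[:40],
                          [X[0][40:], X[1][40:]], y[40:], cfg, seed=7)
            return [p.data.copy() for p in net.params()]

        for p1, p2 in zip(run(), run()):
            np.testing.assert_array_equal(p1, p2)

    def test_network_learns_separable_signal(self):
        rng = np.random.default_rng(1)
        X = [rng.normal(size=(300, 8)), rng.normal(size=(300, 8))]
        y = (X[0][:, 0] + X[1][:, 1] > 0).astype(float)
        cfg = AttentionConfig(projection_dim=8, attention_dim=4, hidden_dim=8,
                              max_epochs=40, patience=8, batch_size=64)
        net = build_fusion_net(cfg, 2, block_dim=8, seed=0)
        log = train_network(net, [X[0][:240], X[1][:240]], y[:240],
                            [X[0][240:], X[1][240:]], y[240:], cfg, seed=0)
        assert log.best_val_auc > 0.9
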