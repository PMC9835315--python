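"""Imbalance strategies: SMOTE, SMILES enumeration, decoy selection."""

import numpy as np
import pytest
from rdkit import Chem

from molfusion import rebalance as rb
from molfusion.chem_records import canonicalize


class TestSmote:
    def test_one_dimensional_interpolation_stays_in_segment(self):
        X = np.array([[0.0], [1.0]])
        synth, _ = rb.smote(X, n_new=50, k_neighbors=1, seed=0)
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_synthetic_points_lie_on_parent_segments(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        synth, records = rb.smote(X, n_new=100, k_neighbors=5, seed=1)
        for row, rec in zip(synth, records):
            i, j = rec.parent_ids
            d = X[j] - X[i]
            # solve row = X[i] + u*d for u; all coordinates must agree
            denom = np.where(d == 0, 1.0, d)
            u = (row - X[i]) / denom
            u_ref = u[np.abs(d) > 1e-12][0] if (np.abs(d) > 1e-12).any() else 0.0
            np.testing.assert_allclose(row, X[i] + u_ref * d, atol=1e-10)
            assert -1e-12 <= u_ref <= 1 + 1e-12

    def test_neighbors_are_true_nearest(self):
        # brute-force oracle: parent j must be among the k nearest of i
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        _, records = rb.smote(X, n_new=60, k_neighbors=3, seed=2)
        from scipy.spatial.distance import cdist
        D = cdist(X, X)
        np.fill_diagonal(D, np.inf)
        for rec in records:
            i, j = rec.parent_ids
            assert j in np.argsort(D[i])[:3]

    def test_deterministic_and_column_ranges(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 4))
        s1, _ = rb.smote(X, 40, seed=9)
        s2, _ = rb.smote(X, 40, seed=9)
        np.testing.assert_array_equal(s1, s2)
        assert (s1.min(0) >= X.min(0) - 1e-12).all()
        assert (s1.max(0) <= X.max(0) + 1e-12).all()

    def test_minority_too_small_raises(self):
        with pytest.raises(ValueError, match="k"):
            rb.smote(np.zeros((3, 2)), 5, k_neighbors=5)


class TestEnumeration:
    def test_variants_canonicalize_back(self):
        smi = canonicalize("CC(=O)Oc1ccccc1C(=O)O")  # aspirin
        variants = rb.enumerate_smiles(smi, 10, seed=0)
        assert len(variants) == 10
        assert len(set(variants)) == 10
        for v in variants:
            assert canonicalize(v) == smi

    def test_deterministic_under_seed(self):
        smi = canonicalize("CC(=O)Oc1ccccc1C(=O)O")
        assert rb.enumerate_smiles(smi, 10, seed=3) == rb.enumerate_smiles(smi, 10, seed=3)

    def test_methane_has_single_form(self):
        assert rb.enumerate_smiles("C", 5, seed=0) == ["C"]

    def test_invalid_molecule_rejected(self):
        with pytest.raises(ValueError):
            rb.enumerate_smiles("C1CC", 3)


class TestMaxMin:
    def test_pick_two_matches_brute_force(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        picked = rb.maxmin_select(D, 2)
        best = max(((i, j) for i in range(5) for j in range(i + 1, 5)),
                   key=lambda p: D[p])
        assert set(picked) == set(best)

    def test_requesting_all_returns_all(self):
        D = np.ones((4, 4)) - np.eye(4)
        assert sorted(rb.maxmin_select(D, 4)) == [0, 1, 2, 3]


def _decoy_fixture():
    # actives: sulfonamide-bearing scaffolds; pool: unrelated scaffolds with
    # matched size/properties
    actives = [canonicalize(s) for s in (
        "O=C(Nc1ccc(S(=O)(=O)N)cc1)c1ccc(C)c(C)c1",
        "c1cc(S(=O)(=O)NC)ccc1Oc1ccc(CC)c(C)c1",
        "O=C(Nc1ccc(S(=O)(=O)NCC)cc1)NCc1ccc(OC)c(C)c1",
    )]
    pool = [canonicalize(s) for s in (
        "c1cc(CC)ccc1-c1nc2cc(C)c(OC)cc2[nH]1",
        "O=C1N(Cc2ccc(OC)cc2)C(=O)c2cc(CC)c(C)cc21",
        "c1cc(OC)ccc1CN1CCN(c2ccc(C)c(CC)c2)CC1",
        "c1cc(C)ccc1-c1ccc2nc(CC)c(OC)nc2c1",
        "c1cc(OCC)ccc1-c1cc2cc(C)c(C)cc2o1",
        "O=C(Nc1ccc(S(=O)(=O)N)cc1)c1ccc(C)c(C)c1",  # identical to an active
    )]
    return actives, pool


def test_decoy_funnel_excludes_actives_and_selected_repass():
    actives, pool = _decoy_fixture()
    crit = rb.DecoyCriteria(max_tanimoto=0.5, n_requested=2)
    decoys, records, funnel = rb.select_decoys(actives, pool, crit, seed=0)
    assert pool[-1] not in decoys          # Tanimoto 1 to an active
    assert 1 <= len(decoys) <= 2
    assert funnel["n"].is_monotonic_decreasing
    assert rb.check_decoys(decoys, actives, crit)


def test_decoy_empty_pool_rejected():
    actives, _ = _decoy_fixture()
    with pytest.raises(ValueError, match="empty"):
        rb.select_decoys(actives, [], rb.DecoyCriteria())


class TestBalanceTrainingSets:
    def _imbalanced(self, n_pos=80, n_neg=20, n_test=30, seed=0):
        rng = np.random.default_rng(seed)
        n = n_pos + n_neg + n_test
        X = rng.normal(size=(n, 6))
        y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int),
                            rng.integers(0, 2, n_test)])
        part = np.array(["train"] * (n_pos + n_neg) + ["test"] * n_test)
        return X, y, part

    def test_smote_balances_train_and_preserves_test(self):
        X, y, part = self._imbalanced()
        X_orig = X.copy()
        out = rb.balance_training_sets(part, y, "smote", features=X, seed=0)
        yb, pb = out["labels"], out["partition"]
        tv = pb != "test"
        assert (yb[tv] == 1).sum() == (yb[tv] == 0).sum()
        # original rows (including every test row) are byte-identical
        np.testing.assert_array_equal(out["features"][: len(X)], X_orig)
        np.testing.assert_array_equal(pb[: len(part)], part)
        # no synthetic item in the test partition
        assert (pb[len(part):] == "train").all()

    def test_already_balanced_is_noop(self):
        X, y, part = self._imbalanced(n_pos=50, n_neg=50)
        out = rb.balance_training_sets(part, y, "smote", features=X, seed=0)
        assert out["features"] is X and out["records"] == []

    def test_strategy_feature_mismatch(self):
        X, y, part = self._imbalanced()
        with pytest.raises(ValueError, match="SMILES"):
            rb.balance_training_sets(part, y, "enumeration", features=X)

    def test_enumeration_balances_sequence_data(self, severe_bench):
        compounds, _ = severe_bench
        smiles = [c.canonical_smiles for c in compounds]
        y = np.array([c.label for c in compounds])
        part = np.array(["train"] * len(y))
        part[-100:] = "test"
        out = rb.balance_training_sets(part, y, "enumeration",
                                       smiles=smiles, seed=1)
        yb, pb = out["labels"], out["partition"]
        tv = pb != "test"
        assert (yb[tv] == 1).sum() == (yb[tv] == 0).sum()
        # every generated variant is a valid molecule equal to its parent
        for rec in out["records"][:20]:
            parent = smiles[rec.parent_ids[0]]
            assert canonicalize(rec.payload) == parent
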