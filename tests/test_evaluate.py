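"""Metrics, aggregation, significance tests, overlap, chemical-space maps."""

import numpy as np
import pandas as pd
import pytest

from molfusion import evaluate as ev
from molfusion.models.classical import PredictionSet


class TestComputeMetrics:
    def test_perfect_predictions(self):
        truth = np.array([0, 1, 1, 0, 1])
        preds = PredictionSet(scores=truth.astype(float))
        m = ev.compute_metrics(preds, truth)
        assert m == {"ACC": 1.0, "F1": 1.0, "AUC": 1.0}

    def test_confusion_example(self):
        # TP=2, FP=1, FN=1, TN=2
        truth = np.array([1, 1, 1, 0, 0, 0])
        labels = np.array([1, 1, 0, 1, 0, 0])
        m = ev.compute_metrics(labels, truth)
        assert m["ACC"] == pytest.approx(4 / 6)
        assert m["F1"] == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))

    def test_constant_scores_give_half_auc(self):
        truth = np.array([0, 1, 0, 1])
        preds = PredictionSet(scores=np.full(4, 0.7))
        assert ev.compute_metrics(preds, truth)["AUC"] == pytest.approx(0.5)

    def test_single_class_truth_flags_auc(self):
        m = ev.compute_metrics(np.array([1, 1]), np.array([1, 1]),
                               scores=np.array([0.9, 0.8]))
        assert np.isnan(m["AUC"]) and m["ACC"] == 1.0

    def test_agrees_with_reference_implementations(self):
        """ACC/F1/AUC match scikit-learn to 1e-10 on random instances."""
        from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(10, 60)
            truth = rng.integers(0, 2, n)
            if len(np.unique(truth)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounded -> ties occur
            preds = PredictionSet(scores=scores)
            m = ev.compute_metrics(preds, truth)
            assert m["ACC"] == pytest.approx(
                accuracy_score(truth, preds.labels), abs=1e-10)
            assert m["F1"] == pytest.approx(
                f1_score(truth, preds.labels, zero_division=0), abs=1e-10)
            assert m["AUC"] == pytest.approx(
                roc_auc_score(truth, scores), abs=1e-10)


class TestWelch:
    def test_identical_vectors(self):
        r = ev.pairwise_ttest(np.ones(5) * 0.8, np.ones(5) * 0.8)
        assert r.t_statistic == 0.0 and r.p_value == 1.0 and not r.significant

    def test_zero_variance_unequal_means(self):
        r = ev.pairwise_ttest(np.ones(5) * 0.9, np.ones(5) * 0.8)
        assert r.significant and r.p_value == 0.0

    def test_swap_negates_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0.9, 0.01, 30), rng.normal(0.8, 0.01, 30)
        r1 = ev.pairwise_ttest(a, b)
        r2 = ev.pairwise_ttest(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_separated_means_strongly_significant(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0.9, 0.01, 30), rng.normal(0.8, 0.01, 30)
        assert ev.pairwise_ttest(a, b).p_value < 1e-6

    def test_agrees_with_scipy_to_1e10(self):
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(3)
        for _ in range(100):
            n1, n2 = rng.integers(3, 40, 2)
            a = rng.normal(0.8, rng.uniform(0.005, 0.1), n1)
            b = rng.normal(0.82, rng.uniform(0.005, 0.1), n2)
            r = ev.pairwise_ttest(a, b)
            t_ref, p_ref = ttest_ind(a, b, equal_var=False)
            assert r.t_statistic == pytest.approx(t_ref, abs=1e-10)
            assert r.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_too_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            ev.pairwise_ttest(np.array([1.0]), np.array([1.0, 2.0]))


class TestRepeatOverSeeds:
    def test_constant_metric_zero_sd(self):
        summ = ev.repeat_over_seeds(
            lambda s: {"ACC": 0.9, "F1": 0.9, "AUC": 0.9}, seeds=range(5))
        assert summ.mean("ACC") == 0.9 and summ.sd("ACC") == 0.0

    def test_sd_conventions(self):
        vals = iter([0.8, 0.9])
        summ = ev.repeat_over_seeds(
            lambda s: {"ACC": next(vals), "F1": 0, "AUC": 0}, seeds=[0, 1])
        assert summ.mean("ACC") == pytest.approx(0.85)
        assert summ.sd("ACC") == pytest.approx(0.05)       # population
        summ.sd_mode = "sample"
        assert summ.sd("ACC") == pytest.approx(0.0707107, abs=1e-6)

    def test_failed_seed_marked_incomplete(self):
        def exp(seed):
            if seed == 1:
                raise RuntimeError("boom")
            return {"ACC": 1.0, "F1": 1.0, "AUC": 1.0}
        summ = ev.repeat_over_seeds(exp, seeds=[0, 1, 2])
        assert summ.per_seed["ACC"].isna().sum() == 1

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError):
            ev.repeat_over_seeds(lambda s: {}, seeds=[1, 1])


class TestOverlap:
    def test_identical_predictions_fully_shared(self):
        truth = np.array([0, 1, 1, 0])
        p = np.array([0, 1, 0, 0])
        s = ev.prediction_overlap(p, p, truth)
        assert s.only_a == s.only_b == 0
        assert s.both_correct == 3 and s.both_wrong == 1
        assert s.correct_overlap_fraction() == 1.0

    def test_complementary_predictions(self):
        truth = np.array([1, 0])
        s = ev.prediction_overlap(np.array([1, 1]), np.array([0, 0]), truth)
        assert s.both_correct == 0 and s.only_a == 1 and s.only_b == 1

    def test_set_arithmetic(self):
        # A correct on {1,2,3}, B correct on {2,3,4} of five compounds
        truth = np.array([1, 1, 1, 1, 1])
        a = np.array([0, 1, 1, 1, 0])
        b = np.array([0, 0, 1, 1, 1])
        s = ev.prediction_overlap(a, b, truth)
        assert (s.both_correct, s.only_a, s.only_b, s.both_wrong) == (2, 1, 1, 1)
        assert s.total == 5

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            ev.prediction_overlap(np.ones(3), np.ones(4), np.ones(4))

    def test_venn_figure_written(self, tmp_path):
        s = ev.prediction_overlap(np.array([1, 1]), np.array([1, 0]),
                                  np.array([1, 1]))
        out = tmp_path / "venn.png"
        ev.plot_overlap_venn(s, "A", "B", out)
        assert out.stat().st_size > 0


class TestChemspaceMap:
    def test_shape_determinism_and_separation(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-4, 0.5, size=(40, 20)),
                       rng.normal(4, 0.5, size=(40, 20))])
        y = np.repeat([0, 1], 40)
        e1 = ev.chemspace_map({"desc": X}, y, seed=1)
        e2 = ev.chemspace_map({"desc": X}, y, seed=1)
        assert e1["desc"].shape == (80, 2)
        np.testing.assert_array_equal(e1["desc"], e2["desc"])
        emb = e1["desc"]
        c0, c1 = emb[y == 0].mean(0), emb[y == 1].mean(0)
        spread = np.linalg.norm(emb[y == 0] - c0, axis=1).mean()
        assert np.linalg.norm(c0 - c1) > spread

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            ev.chemspace_map({"x": np.zeros((5, 4))}, np.zeros(5))


class TestGrid:
    def test_experiment_catalogue_arithmetic(self):
        classical = [e for e, (kind, _) in ev.EXPERIMENTS.items()
                     if kind == "classical"]
        assert len(classical) == 7  # x 9 families = 63 models per group
        assert len(ev.EXPERIMENTS) == 15
        assert len(ev.GROUPS) == 15
        # decoy strategies apply only at the 10 uM cutoff
        for gid, (_, cutoff, strategy) in ev.GROUPS.items():
            if strategy is not None:
                assert cutoff == 10.0

    def test_empty_selection_is_noop(self, bench_features):
        data = ev.GridData([], np.array([]), {}, np.zeros((0, 5)), {}, np.array([]))
        out = ev.run_experiment_grid(data, [], [], [], None)
        assert out.empty

    def test_small_grid_row_accounting(self, bench_features, balanced_bench):
        """2 families x 2 seeds on experiment 2 (ECFP4) -> 2 rows, n_seeds=2."""
        from molfusion.scaffold_split import ClusterAssignment, make_split
        from molfusion.featurize import build_vocab, encode_smiles

        compounds, manifest = balanced_bench
        smiles = bench_features["smiles"]
        vocab = build_vocab(smiles)
        enc = encode_smiles(smiles, vocab, max_len=80)
        data = ev.GridData(
            smiles=smiles,
            activity_um=bench_features["activity_um"],
            raw_blocks={"ECFP4": bench_features["ecfp"]},
            sequences=enc.sequences,
            vocabulary=vocab,
            cluster_labels=bench_features["families"],
        )
        assignment = ClusterAssignment(
            len(np.unique(bench_features["families"])),
            bench_features["families"], pd.DataFrame())

        def split_builder(labels, seed):
            return make_split(assignment, labels, seed=seed)

        table = ev.run_experiment_grid(
            data, groups=["I"], experiments=[2], seeds=[0, 1],
            split_builder=split_builder, families=("GNB", "LR"),
            n_search_iter=2)
        assert len(table) == 2
        assert set(table["family"]) == {"GNB", "LR"}
        assert (table["n_seeds"] == 2).all()
        assert table["AUC_mean"].between(0, 1).all()
        # infeasible: experiment 2 outside the SMILES group's range
        empty = ev.run_experiment_grid(
            data, groups=["XI"], experiments=[2], seeds=[0],
            split_builder=split_builder)
        assert empty.empty
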