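"""Evaluation: metrics, multi-seed aggregation, significance, overlap, maps.

Metrics are ACC, F1 (positive class = active) and AUC computed from the
rank statistic with tie correction. Experiments are repeated over seeds and
summarized as mean +/- SD (population SD by default); model pairs are
compared with a two-sided Welch t-test. Prediction overlap between two
models is reported as the four-way agreement partition behind a Venn
figure, and 2-D chemical-space maps come from t-SNE per modality.

The experiment grid couples models x feature combos x cutoff/rebalancing
groups exactly as in the benchmark design: experiments 1-7 are the nine
classical families on the numeric combos, 8-14 the fusion network on the
same combos, 15 the SMILES sequence network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from . import rebalance as reb
from .featurize import FUSION_COMBOS, fuse, preprocess_block, apply_preprocess
from .models.classical import (
    CLASSICAL_FAMILIES,
    ModelSpec,
    PredictionSet,
    randomized_search,
    train_classical,
)
from .models.networks import (
    AttentionConfig,
    build_fusion_net,
    build_smiles_net,
    train_network,
)

logger = logging.getLogger(__name__)

#: experiment id -> (model kind, feature combo id); combo None = SMILES
EXPERIMENTS: dict[int, tuple[str, int | None]] = {
    **{i: ("classical", c) for i, c in zip(range(1, 8), (1, 2, 3, 5, 6, 7, 8))},
    **{i: ("fusion", c) for i, c in zip(range(8, 15), (1, 2, 3, 5, 6, 7, 8))},
    15: ("smiles", None),
}

#: group id -> (experiment range, cutoff uM, rebalancing strategy)
GROUPS: dict[str, tuple[tuple[int, int], float, str | None]] = {
    "I": ((1, 7), 0.5, None),
    "II": ((1, 7), 1.0, None),
    "III": ((1, 7), 10.0, None),
    "IV": ((1, 7), 10.0, "smote"),
    "V": ((1, 7), 10.0, "decoys"),
    "VI": ((8, 14), 0.5, None),
    "VII": ((8, 14), 1.0, None),
    "VIII": ((8, 14), 10.0, None),
    "IX": ((8, 14), 10.0, "smote"),
    "X": ((8, 14), 10.0, "decoys"),
    "XI": ((15, 15), 0.5, None),
    "XII": ((15, 15), 1.0, None),
    "XIII": ((15, 15), 10.0, None),
    "XIV": ((15, 15), 10.0, "enumeration"),
    "XV": ((15, 15), 10.0, "decoys"),
}


@dataclass
class MetricSummary:
    """Per-seed metrics of one grid cell with mean/SD aggregation."""

    experiment_id: int
    group_id: str
    model_family: str
    feature_combo: int | None
    per_seed: pd.DataFrame  # columns: seed, ACC, F1, AUC
    sd_mode: str = "population"

    @property
    def n_seeds(self) -> int:
        return len(self.per_seed)

    def mean(self, metric: str) -> float:
        return float(self.per_seed[metric].mean())

    def sd(self, metric: str) -> float:
        ddof = 0 if self.sd_mode == "population" else 1
        return float(self.per_seed[metric].std(ddof=ddof))

    def as_row(self) -> dict:
        row = {
            "experiment": self.experiment_id, "group": self.group_id,
            "family": self.model_family, "combo": self.feature_combo,
            "n_seeds": self.n_seeds,
        }
        for m in ("ACC", "F1", "AUC"):
            row[f"{m}_mean"] = self.mean(m)
            row[f"{m}_sd"] = self.sd(m)
        return row


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    metric: str
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass
class OverlapSummary:
    """Four-way agreement partition of two models' test predictions."""

    both_correct: int
    only_a: int
    only_b: int
    both_wrong: int

    @property
    def total(self) -> int:
        return self.both_correct + self.only_a + self.only_b + self.both_wrong

    def correct_overlap_fraction(self) -> float:
        """Shared correct / union of correct predictions."""
        union = self.both_correct + self.only_a + self.only_b
        return self.both_correct / union if union else 1.0


def compute_metrics(predictions: PredictionSet | np.ndarray,
                    truth: np.ndarray,
                    scores: np.ndarray | None = None) -> dict[str, float]:
    """ACC, F1 and tie-corrected rank AUC for one prediction set.

    Accepts either a :class:`PredictionSet` or raw (labels, truth, scores).
    AUC is NaN (flagged) when the truth has a single class.
    """
    if isinstance(predictions, PredictionSet):
        labels = predictions.labels
        scores = predictions.scores
    else:
        labels = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(labels) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    n = len(truth)
    acc = float((labels == truth).sum() / n)
    tp = int(((labels == 1) & (truth == 1)).sum())
    fp = int(((labels == 1) & (truth == 0)).sum())
    fn = int(((labels == 0) & (truth == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    if scores is None:
        scores = labels.astype(float)
    n1 = int((truth == 1).sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        logger.warning("AUC undefined: single-class truth")
        auc = np.nan
    else:
        ranks = stats.rankdata(scores)  # average ranks handle ties
        auc = (ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return {"ACC": acc, "F1": float(f1), "AUC": float(auc)}


def repeat_over_seeds(experiment, seeds, experiment_id: int = 0,
                      group_id: str = "", model_family: str = "",
                      feature_combo: int | None = None,
                      sd_mode: str = "population") -> MetricSummary:
    """Run ``experiment(seed) -> {"ACC":..,"F1":..,"AUC":..}`` per seed.

    Failed seeds are recorded with NaN metrics and the summary keeps going
    (marked incomplete by the NaN rows).
    """
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    rows = []
    for seed in seeds:
        try:
            metrics = experiment(seed)
        except Exception:
            logger.exception("seed %d failed", seed)
            metrics = {"ACC": np.nan, "F1": np.nan, "AUC": np.nan}
        rows.append({"seed": seed, **metrics})
    return MetricSummary(experiment_id, group_id, model_family, feature_combo,
                         pd.DataFrame(rows), sd_mode=sd_mode)


def pairwise_ttest(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
                   model_a: str = "A", model_b: str = "B",
                   metric: str = "") -> ComparisonResult:
    """Two-sided Welch t-test on per-seed metric vectors.

    Zero-variance conventions: both constant and equal -> t=0, p=1; both
    constant but different -> flagged significant with p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return ComparisonResult(model_a, model_b, metric, 0.0, 1.0, False, alpha)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return ComparisonResult(model_a, model_b, metric, t, 0.0, True, alpha)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return ComparisonResult(model_a, model_b, metric, float(t), float(p),
                            bool(p < alpha), alpha)


def prediction_overlap(preds_a: np.ndarray, preds_b: np.ndarray,
                       truth: np.ndarray) -> OverlapSummary:
    """Agreement partition of two models' hard predictions on one test set."""
    preds_a, preds_b, truth = map(np.asarray, (preds_a, preds_b, truth))
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("mismatched compound sets")
    ca, cb = preds_a == truth, preds_b == truth
    return OverlapSummary(
        both_correct=int((ca & cb).sum()),
        only_a=int((ca & ~cb).sum()),
        only_b=int((~ca & cb).sum()),
        both_wrong=int((~ca & ~cb).sum()),
    )


def plot_overlap_venn(summary: OverlapSummary, label_a: str, label_b: str,
                      path, correct: bool = True) -> None:
    """Two-circle Venn figure for correct (or incorrect) predictions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if correct:
        only_a, shared, only_b = summary.only_a, summary.both_correct, summary.only_b
        title = "Correct predictions"
    else:
        only_a, shared, only_b = summary.only_b, summary.both_wrong, summary.only_a
        title = "Incorrect predictions"
    total = max(only_a + shared + only_b, 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((-0.5, 0), 1.0, alpha=0.4, color="tab:blue"))
    ax.add_patch(Circle((0.5, 0), 1.0, alpha=0.4, color="tab:orange"))
    for x, v in ((-1.0, only_a), (0.0, shared), (1.0, only_b)):
        ax.text(x, 0, f"{v}\n({100 * v / total:.1f}%)", ha="center", va="center")
    ax.text(-0.9, 1.15, label_a, ha="center")
    ax.text(0.9, 1.15, label_b, ha="center")
    ax.set_xlim(-2, 2); ax.set_ylim(-1.5, 1.6)
    ax.set_aspect("equal"); ax.axis("off"); ax.set_title(title)
    fig.savefig(path, dpi=120); plt.close(fig)


def chemspace_map(blocks: dict[str, np.ndarray], labels: np.ndarray,
                  seed: int = 0, perplexity: float = 30.0) -> dict[str, np.ndarray]:
    """Seeded 2-D t-SNE embedding per modality."""
    labels = np.asarray(labels)
    out = {}
    for name, mat in blocks.items():
        if mat.shape[0] < 10:
            raise ValueError("need at least 10 compounds for an embedding")
        perp = min(perplexity, (mat.shape[0] - 1) / 3)
        ts = TSNE(n_components=2, random_state=seed, perplexity=perp, init="pca")
        out[name] = ts.fit_transform(mat)
    return out


def plot_chemspace(embeddings: dict[str, np.ndarray], labels: np.ndarray,
                   path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(embeddings), figsize=(4 * len(embeddings), 4))
    axes = np.atleast_1d(axes)
    for ax, (name, xy) in zip(axes, embeddings.items()):
        for y, color in ((0, "tab:gray"), (1, "tab:red")):
            m = labels == y
            ax.scatter(xy[m, 0], xy[m, 1], s=6, c=color,
                       label="active" if y else "inactive", alpha=0.6)
        ax.set_title(name); ax.legend(frameon=False)
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

@dataclass
class GridData:
    """Everything the grid needs, prepared once per dataset.

    ``raw_blocks`` are unprocessed FeatureBlocks keyed by modality;
    ``sequences``/``lengths``/``vocabulary`` encode the SMILES corpus;
    ``cluster_labels`` come from K-means on the conjoint representation.
    """

    smiles: list[str]
    activity_um: np.ndarray
    raw_blocks: dict
    sequences: np.ndarray
    vocabulary: dict[str, int]
    cluster_labels: np.ndarray
    decoy_pool: list[str] | None = None


def _prepare_numeric(data: GridData, split, seed: int):
    """Leakage-free preprocessing of the three numeric blocks."""
    fit_rows = np.flatnonzero(split.partition != "test")
    processed = {}
    for name, block in data.raw_blocks.items():
        mat, _ = preprocess_block(block, fit_rows, seed=seed)
        processed[name] = mat
    return processed


def run_cell(data: GridData, experiment_id: int, group_id: str,
             seed: int, split, net_config: AttentionConfig | None = None,
             n_search_iter: int = 10,
             families: tuple[str, ...] = CLASSICAL_FAMILIES) -> list[MetricSummary]:
    """Execute one (experiment, group) cell for one seed; returns per-model
    single-seed summaries (callers aggregate over seeds)."""
    kind, combo = EXPERIMENTS[experiment_id]
    _, cutoff, strategy = GROUPS[group_id]
    labels = (data.activity_um < cutoff).astype(int)
    part = split.partition
    train_idx = np.flatnonzero(part == "train")
    val_idx = np.flatnonzero(part == "validation")
    test_idx = np.flatnonzero(part == "test")

    results = []
    if kind in ("classical", "fusion"):
        blocks = _prepare_numeric(data, split, seed)
        fused = fuse(blocks, combo)
        X, y = fused.matrix, labels
        Xtr = np.vstack([X[train_idx], X[val_idx]])
        ytr = np.concatenate([y[train_idx], y[val_idx]])
        part_tr = np.concatenate([part[train_idx], part[val_idx]])
        if strategy == "smote":
            out = reb.balance_training_sets(part_tr, ytr, "smote",
                                            features=Xtr, seed=seed)
            Xtr, ytr = out["features"], out["labels"]
        elif strategy == "decoys":
            if data.decoy_pool is None:
                logger.warning("cell (%s, %s) skipped: no decoy pool",
                               experiment_id, group_id)
                return []
            smi_tr = [data.smiles[i] for i in train_idx] + \
                     [data.smiles[i] for i in val_idx]
            out = reb.balance_training_sets(
                part_tr, ytr, "decoys", smiles=smi_tr,
                decoy_pool=data.decoy_pool, seed=seed)
            new_smiles = out["smiles"][len(smi_tr):]
            if new_smiles:
                from .featurize import compute_descriptors, compute_fingerprint
                extra_blocks = {
                    "descriptors": compute_descriptors(new_smiles),
                    "ECFP4": compute_fingerprint(new_smiles, "ECFP4"),
                    "MACCS": compute_fingerprint(new_smiles, "MACCS"),
                }
                fit_rows = np.flatnonzero(part != "test")
                extra = {}
                for name, block in data.raw_blocks.items():
                    _, state = preprocess_block(block, fit_rows, seed=seed)
                    extra[name] = apply_preprocess(extra_blocks[name], state)
                extra_fused = fuse({m: extra[m] for m in fused.modalities}, combo)
                Xtr = np.vstack([Xtr, extra_fused.matrix])
                ytr = out["labels"]
        if kind == "classical":
            for family in families:
                spec, _ = randomized_search(family, Xtr, ytr,
                                            n_iter=n_search_iter, seed=seed)
                spec = ModelSpec(family, spec.hyperparameters, seed)
                model = train_classical(spec, Xtr, ytr)
                preds = model.predict(X[test_idx])
                metrics = compute_metrics(preds, y[test_idx])
                results.append(MetricSummary(
                    experiment_id, group_id, family, combo,
                    pd.DataFrame([{"seed": seed, **metrics}])))
        else:
            cfg = net_config or AttentionConfig()
            bounds = fused.block_boundaries
            def split_blocks(rows):
                return [X[rows][:, bounds[i]:bounds[i + 1]]
                        for i in range(len(bounds) - 1)]
            net = build_fusion_net(cfg, n_blocks=len(bounds) - 1, seed=seed)
            tr_blocks = [Xtr[:, bounds[i]:bounds[i + 1]]
                         for i in range(len(bounds) - 1)]
            train_network(net, tr_blocks, ytr,
                          split_blocks(val_idx), y[val_idx], cfg, seed=seed)
            scores = net.scores(split_blocks(test_idx))
            metrics = compute_metrics(PredictionSet(scores), y[test_idx])
            results.append(MetricSummary(
                experiment_id, group_id, "FusionNet", combo,
                pd.DataFrame([{"seed": seed, **metrics}])))
    elif kind == "smiles":
        cfg = net_config or AttentionConfig()
        seqs, y = data.sequences, labels
        tr_seqs = np.vstack([seqs[train_idx], seqs[val_idx]])
        ytr = np.concatenate([y[train_idx], y[val_idx]])
        part_tr = np.concatenate([part[train_idx], part[val_idx]])
        if strategy == "enumeration":
            smi_tr = [data.smiles[i] for i in train_idx] + \
                     [data.smiles[i] for i in val_idx]
            out = reb.balance_training_sets(part_tr, ytr, "enumeration",
                                            smiles=smi_tr, seed=seed)
            from .featurize import encode_smiles
            enc = encode_smiles(out["smiles"][len(smi_tr):], data.vocabulary,
                                max_len=seqs.shape[1])
            tr_seqs = np.vstack([tr_seqs, enc.sequences])
            ytr = out["labels"]
        elif strategy == "decoys":
            if data.decoy_pool is None:
                logger.warning("cell (%s, %s) skipped: no decoy pool",
                               experiment_id, group_id)
                return []
            smi_tr = [data.smiles[i] for i in train_idx] + \
                     [data.smiles[i] for i in val_idx]
            out = reb.balance_training_sets(part_tr, ytr, "decoys",
                                            smiles=smi_tr,
                                            decoy_pool=data.decoy_pool, seed=seed)
            from .featurize import encode_smiles, build_vocab
            new_smiles = out["smiles"][len(smi_tr):]
            enc = encode_smiles(new_smiles, data.vocabulary, max_len=seqs.shape[1])
            tr_seqs = np.vstack([tr_seqs, enc.sequences])
            ytr = out["labels"]
        net = build_smiles_net(cfg, data.vocabulary, seed=seed)
        train_network(net, tr_seqs, ytr, seqs[val_idx], y[val_idx], cfg, seed=seed)
        scores = net.scores(seqs[test_idx])
        metrics = compute_metrics(PredictionSet(scores), y[test_idx])
        results.append(MetricSummary(
            experiment_id, group_id, "SmilesNet", None,
            pd.DataFrame([{"seed": seed, **metrics}])))
    else:  # pragma: no cover
        raise ValueError(f"unknown experiment kind {kind!r}")
    return results


def run_experiment_grid(data: GridData, groups: list[str], experiments: list[int],
                        seeds: list[int], split_builder,
                        net_config: AttentionConfig | None = None,
                        families: tuple[str, ...] = CLASSICAL_FAMILIES,
                        n_search_iter: int = 10) -> pd.DataFrame:
    """Run the requested grid cells and aggregate per-seed metrics.

    ``split_builder(labels, seed)`` must return a SplitSpec for a label
    vector (splits depend on the cutoff through the class-ratio matching).
    Infeasible cells (experiment outside the group's range, or a missing
    decoy pool) are skipped with a logged reason. Returns a tidy table of
    mean +/- SD rows, one per (group, experiment, model).
    """
    if not groups or not experiments:
        logger.info("empty grid selection; nothing to run")
        return pd.DataFrame()
    cell_rows: dict[tuple, list[pd.DataFrame]] = {}
    meta: dict[tuple, MetricSummary] = {}
    for group_id in groups:
        (lo, hi), cutoff, _ = GROUPS[group_id]
        labels = (data.activity_um < cutoff).astype(int)
        for experiment_id in experiments:
            if not lo <= experiment_id <= hi:
                logger.info("experiment %d infeasible in group %s; skipped",
                            experiment_id, group_id)
                continue
            for seed in seeds:
                split = split_builder(labels, seed)
                for summ in run_cell(data, experiment_id, group_id, seed, split,
                                     net_config=net_config, families=families,
                                     n_search_iter=n_search_iter):
                    key = (group_id, experiment_id, summ.model_family)
                    cell_rows.setdefault(key, []).append(summ.per_seed)
                    meta[key] = summ
    rows = []
    for key, frames in cell_rows.items():
        summ = meta[key]
        merged = MetricSummary(summ.experiment_id, summ.group_id,
                               summ.model_family, summ.feature_combo,
                               pd.concat(frames, ignore_index=True))
        rows.append(merged.as_row())
    return pd.DataFrame(rows)
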