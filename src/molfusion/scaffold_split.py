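"""Cluster-based hold-out splitting.

Compounds are clustered by K-means on a *conjoint representation* — the
standardized concatenation of the raw descriptor, MACCS and ECFP4 blocks —
so that held-out test chemotypes are structurally unseen during training.
The cluster count is chosen by consensus of three internal indices
(silhouette coefficient, Davies-Bouldin, Calinski-Harabasz); whole clusters
are then assigned to the test partition such that the test class ratio
tracks the overall ratio, and a stratified validation set is drawn from the
remaining compounds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

logger = logging.getLogger(__name__)

DEFAULT_N_TEST_CLUSTERS = 3
DEFAULT_VAL_FRACTION = 0.05
DEFAULT_TEST_SIZE_BAND = (0.08, 0.16)


@dataclass
class ClusterAssignment:
    """K-means labels plus the per-k quality table used to choose k."""

    k: int
    labels: np.ndarray
    quality: pd.DataFrame  # columns: k, CHS, DBI, SC

    def __post_init__(self) -> None:
        found = np.unique(self.labels)
        if len(found) != self.k:
            raise ValueError(f"expected {self.k} non-empty clusters, found {len(found)}")


@dataclass
class SplitSpec:
    """Partition assignment (train/validation/test) with provenance."""

    partition: np.ndarray  # str array: 'train' | 'validation' | 'test'
    cluster_labels: np.ndarray
    test_clusters: tuple[int, ...]
    class_ratio_report: pd.DataFrame = field(default=None)

    def indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.partition == name)


def conjoint_representation(blocks: list[np.ndarray]) -> np.ndarray:
    """Horizontal concatenation of (already standardized) raw blocks."""
    if not blocks:
        raise ValueError("no blocks given")
    n = blocks[0].shape[0]
    for b in blocks:
        if b.shape[0] != n:
            raise ValueError(f"row-count mismatch: {b.shape[0]} != {n}")
    return blocks[0] if len(blocks) == 1 else np.hstack(blocks)


def select_cluster_count(
    matrix: np.ndarray,
    k_range: range | list[int] = range(2, 21),
    seed: int = 0,
    fixed_k: int | None = None,
) -> ClusterAssignment:
    """K-means over candidate k; choose k by index consensus.

    Consensus rule: highest silhouette coefficient, ties broken by lowest
    Davies-Bouldin index, then highest Calinski-Harabasz score. Pass
    ``fixed_k`` to bypass selection while still recording the quality table.
    """
    n = matrix.shape[0]
    ks = [] if fixed_k is not None else [k for k in k_range if 2 <= k <= n - 1]
    if not ks and fixed_k is None:
        raise ValueError(f"no valid k in range for n={n}")
    if np.allclose(matrix.var(axis=0), 0):
        logger.warning("degenerate input: zero variance in every dimension")
    rows = []
    fits: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(matrix)
        fits[k] = labels
        if len(np.unique(labels)) < 2:
            continue
        rows.append({
            "k": k,
            "CHS": calinski_harabasz_score(matrix, labels),
            "DBI": davies_bouldin_score(matrix, labels),
            "SC": silhouette_score(matrix, labels),
        })
    quality = pd.DataFrame(rows)
    if fixed_k is not None:
        if fixed_k not in fits:
            km = KMeans(n_clusters=fixed_k, n_init=10, random_state=seed)
            fits[fixed_k] = km.fit_predict(matrix)
        return ClusterAssignment(fixed_k, fits[fixed_k], quality)
    best = quality.sort_values(
        ["SC", "DBI", "CHS"], ascending=[False, True, False]
    ).iloc[0]
    k = int(best["k"])
    logger.info("selected k=%d (SC=%.3f, DBI=%.3f, CHS=%.1f)",
                k, best["SC"], best["DBI"], best["CHS"])
    return ClusterAssignment(k, fits[k], quality)


def _candidate_subsets(cluster_ids: np.ndarray, n_test: int, greedy_cap: int = 20):
    if len(cluster_ids) <= greedy_cap:
        yield from itertools.combinations(cluster_ids.tolist(), n_test)
    else:
        # greedy enumeration is unnecessary below the cap; above it, sample
        # a deterministic subset of combinations
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(2000):
            combo = tuple(sorted(rng.choice(cluster_ids, n_test, replace=False).tolist()))
            if combo not in seen:
                seen.add(combo)
                yield combo


def make_split(
    assignment: ClusterAssignment,
    labels: np.ndarray,
    n_test_clusters: int = DEFAULT_N_TEST_CLUSTERS,
    val_fraction: float = DEFAULT_VAL_FRACTION,
    seed: int = 0,
    test_size_band: tuple[float, float] = DEFAULT_TEST_SIZE_BAND,
) -> SplitSpec:
    """Hold out whole clusters as the test set; stratified validation.

    Among all subsets of ``n_test_clusters`` clusters whose total size lies
    inside ``test_size_band`` (fraction of compounds), the subset whose
    positive rate is closest to the overall positive rate is chosen. The
    band is widened with a warning when no subset fits. Validation compounds
    are drawn stratified by label from the remaining (training) clusters.
    """
    labels = np.asarray(labels)
    cl = np.asarray(assignment.labels)
    cluster_ids = np.unique(cl)
    if len(cluster_ids) <= n_test_clusters:
        raise ValueError(
            f"need more than {n_test_clusters} clusters, have {len(cluster_ids)}")
    n = len(labels)
    overall_rate = labels.mean()
    sizes = {c: int((cl == c).sum()) for c in cluster_ids}
    pos = {c: int(labels[cl == c].sum()) for c in cluster_ids}

    lo, hi = test_size_band
    best = None
    while best is None:
        for combo in _candidate_subsets(cluster_ids, n_test_clusters):
            size = sum(sizes[c] for c in combo)
            if not (lo * n <= size <= hi * n):
                continue
            rate = sum(pos[c] for c in combo) / size
            score = abs(rate - overall_rate)
            if best is None or score < best[0]:
                best = (score, combo)
        if best is None:
            lo, hi = max(0.0, lo - 0.04), min(1.0, hi + 0.04)
            logger.warning("no cluster subset in size band; widening to (%.2f, %.2f)",
                           lo, hi)
            if lo == 0.0 and hi == 1.0 and best is None:
                # final pass over all subsets regardless of size
                for combo in _candidate_subsets(cluster_ids, n_test_clusters):
                    size = sum(sizes[c] for c in combo)
                    rate = sum(pos[c] for c in combo) / size
                    score = abs(rate - overall_rate)
                    if best is None or score < best[0]:
                        best = (score, combo)
                break
    test_clusters = tuple(sorted(best[1]))

    partition = np.full(n, "train", dtype=object)
    test_mask = np.isin(cl, test_clusters)
    partition[test_mask] = "test"

    rng = np.random.default_rng(seed)
    trainval = np.flatnonzero(~test_mask)
    n_val = int(round(val_fraction * len(trainval)))
    val_idx: list[int] = []
    for y in (0, 1):
        cls_idx = trainval[labels[trainval] == y]
        n_take = int(round(n_val * len(cls_idx) / max(len(trainval), 1)))
        n_take = min(n_take, len(cls_idx))
        val_idx.extend(rng.choice(cls_idx, size=n_take, replace=False).tolist())
    partition[np.array(val_idx, dtype=int)] = "validation"

    report = pd.DataFrame([
        {
            "partition": p,
            "n": int((partition == p).sum()),
            "positive_rate": float(labels[partition == p].mean())
            if (partition == p).any() else np.nan,
        }
        for p in ("train", "validation", "test")
    ])
    logger.info("split sizes/ratios:\n%s", report.to_string(index=False))
    return SplitSpec(
        partition=partition.astype(str),
        cluster_labels=cl,
        test_clusters=test_clusters,
        class_ratio_report=report,
    )


def split_to_frame(split: SplitSpec, smiles: list[str]) -> pd.DataFrame:
    """SplitSpec as a persistable table (one row per compound)."""
    return pd.DataFrame({
        "canonical_smiles": smiles,
        "partition": split.partition,
        "cluster_id": split.cluster_labels,
    })
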