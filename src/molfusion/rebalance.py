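"""Imbalanced-data strategies.

Three ways to balance the positive:negative ratio of the training and
validation partitions (the test partition is never touched):

* SMOTE — synthetic minority oversampling by interpolation between a
  minority point and one of its k nearest minority neighbors.
* Unbiased decoy selection — property-matched but structurally dissimilar
  presumed-inactives picked from a candidate pool, then diversified by
  MaxMin selection on fingerprint Tanimoto distance.
* SMILES enumeration — alternative atom-ordering SMILES strings for
  minority molecules, used as sequence-level augmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator

logger = logging.getLogger(__name__)

_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

#: DUD-E-style property-matching windows
DEFAULT_PROPERTY_WINDOWS = {
    "mw": 25.0,          # Da
    "logp": 1.0,
    "hbd": 1,
    "hba": 2,
    "rotb": 2,
    "charge": 0,         # exact match
}
DEFAULT_MAX_TANIMOTO = 0.30

PROPERTY_FUNCS = {
    "mw": Descriptors.MolWt,
    "logp": Descriptors.MolLogP,
    "hbd": Descriptors.NumHDonors,
    "hba": Descriptors.NumHAcceptors,
    "rotb": Descriptors.NumRotatableBonds,
    "charge": Chem.GetFormalCharge,
}


@dataclass
class DecoyCriteria:
    """Filter panel for unbiased decoy selection."""

    property_windows: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTY_WINDOWS))
    max_tanimoto: float = DEFAULT_MAX_TANIMOTO
    n_requested: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.max_tanimoto < 1.0:
            raise ValueError("max_tanimoto must be in (0, 1)")
        if any(w < 0 for w in self.property_windows.values()):
            raise ValueError("property windows must be non-negative")


@dataclass(frozen=True)
class AugmentationRecord:
    """Provenance of one synthetic/augmented item."""

    origin: str                 # 'smote' | 'decoy' | 'enumeration'
    parent_ids: tuple[int, ...]
    payload: object             # feature vector or SMILES string


def smote(
    minority_rows: np.ndarray,
    n_new: int,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, list[AugmentationRecord]]:
    """Synthetic minority oversampling by neighbor interpolation.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of the k nearest minority neighbors (Euclidean) of a
    randomly chosen minority point ``x_i``.
    """
    X = np.asarray(minority_rows, dtype=np.float64)
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(
            f"minority size {n} too small for k={k_neighbors}; "
            f"use k <= {n - 1}")
    if n_new < 1:
        raise ValueError("n_new must be >= 1")
    # full pairwise distances; minority classes here are small enough
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    nbr = nn_idx[base, pick]
    synth = X[base] + u[:, None] * (X[nbr] - X[base])
    records = [
        AugmentationRecord("smote", (int(b), int(m)), synth[i])
        for i, (b, m) in enumerate(zip(base, nbr))
    ]
    return synth, records


def enumerate_smiles(
    canonical_smiles: str,
    n_variants: int,
    seed: int = 0,
    max_tries_factor: int = 20,
) -> list[str]:
    """Alternative SMILES for one molecule by random atom renumbering.

    Every variant canonicalizes back to the input; variants are distinct
    strings (the canonical form itself may appear). Molecules with few
    distinct forms can return fewer than ``n_variants``.
    """
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {canonical_smiles!r}")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    n_atoms = mol.GetNumAtoms()
    seen: list[str] = []
    for _ in range(max_tries_factor * n_variants):
        if len(seen) >= n_variants:
            break
        order = rng.permutation(n_atoms).tolist()
        shuffled = Chem.RenumberAtoms(mol, order)
        smi = Chem.MolToSmiles(shuffled, canonical=False)
        if smi not in seen:
            seen.append(smi)
    if len(seen) < n_variants:
        logger.info("enumeration: only %d distinct forms for %s",
                    len(seen), canonical_smiles)
    return seen


def _fingerprints(smiles: list[str]):
    fps = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES: {smi!r}")
        fps.append(_MORGAN_GEN.GetFingerprint(mol))
    return fps


def _properties(smiles: list[str]) -> pd.DataFrame:
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES: {smi!r}")
        rows.append({name: fn(mol) for name, fn in PROPERTY_FUNCS.items()})
    return pd.DataFrame(rows)


def maxmin_select(
    distance: np.ndarray, n_pick: int
) -> list[int]:
    """Deterministic MaxMin diversity selection on a distance matrix.

    Seeded with the most distant pair, then greedily adds the candidate
    maximizing its minimum distance to the already-selected set (ties by
    lowest index).
    """
    n = distance.shape[0]
    if n_pick >= n:
        return list(range(n))
    if n_pick <= 0:
        return []
    i, j = np.unravel_index(np.argmax(distance), distance.shape)
    selected = [int(min(i, j))] if n_pick == 1 else [int(min(i, j)), int(max(i, j))]
    while len(selected) < n_pick:
        remaining = [x for x in range(n) if x not in selected]
        min_d = distance[np.ix_(remaining, selected)].min(axis=1)
        selected.append(remaining[int(np.argmax(min_d))])
    return selected[:n_pick]


def select_decoys(
    active_smiles: list[str],
    pool_smiles: list[str],
    criteria: DecoyCriteria,
    seed: int = 0,
) -> tuple[list[str], list[AugmentationRecord], pd.DataFrame]:
    """Unbiased decoy selection funnel.

    1. *Property matching*: each of a candidate's panel properties must lie
       within its window of at least one active.
    2. *Dissimilarity*: max ECFP4 Tanimoto to every active below threshold.
    3. *Diversity*: MaxMin selection on Tanimoto distance among survivors
       down to the requested count.

    Returns the selected decoy SMILES, provenance records and a funnel
    table of survivor counts per stage.
    """
    if not pool_smiles:
        raise ValueError("empty decoy pool")
    act_props = _properties(active_smiles)
    pool_props = _properties(pool_smiles)
    windows = criteria.property_windows

    keep1 = []
    for ci in range(len(pool_smiles)):
        cand = pool_props.iloc[ci]
        ok = np.ones(len(act_props), dtype=bool)
        for prop, win in windows.items():
            ok &= (act_props[prop] - cand[prop]).abs().to_numpy() <= win
        if ok.any():
            keep1.append(ci)

    act_fps = _fingerprints(active_smiles)
    pool_fps = _fingerprints([pool_smiles[i] for i in keep1])
    keep2 = []
    for local, ci in enumerate(keep1):
        sims = DataStructs.BulkTanimotoSimilarity(pool_fps[local], act_fps)
        if max(sims, default=0.0) < criteria.max_tanimoto:
            keep2.append(ci)

    surv_fps = _fingerprints([pool_smiles[i] for i in keep2])
    n_pick = min(criteria.n_requested, len(keep2))
    if n_pick < criteria.n_requested:
        logger.warning("only %d decoys survive filters (requested %d)",
                       len(keep2), criteria.n_requested)
    if n_pick > 0:
        m = len(keep2)
        dist = np.zeros((m, m))
        for a in range(m):
            sims = DataStructs.BulkTanimotoSimilarity(surv_fps[a], surv_fps)
            dist[a] = 1.0 - np.asarray(sims)
        picked_local = maxmin_select(dist, n_pick)
    else:
        picked_local = []
    picked = [keep2[i] for i in picked_local]

    funnel = pd.DataFrame({
        "stage": ["pool", "property_matched", "dissimilar", "selected"],
        "n": [len(pool_smiles), len(keep1), len(keep2), len(picked)],
    })
    decoys = [pool_smiles[i] for i in picked]
    records = [AugmentationRecord("decoy", (i,), pool_smiles[i]) for i in picked]
    return decoys, records, funnel


def check_decoys(
    decoy_smiles: list[str],
    active_smiles: list[str],
    criteria: DecoyCriteria,
) -> bool:
    """Re-verify that every decoy satisfies the selection criteria."""
    if not decoy_smiles:
        return True
    act_props = _properties(active_smiles)
    dec_props = _properties(decoy_smiles)
    act_fps = _fingerprints(active_smiles)
    dec_fps = _fingerprints(decoy_smiles)
    for i in range(len(decoy_smiles)):
        ok = np.ones(len(act_props), dtype=bool)
        for prop, win in criteria.property_windows.items():
            ok &= (act_props[prop] - dec_props.iloc[i][prop]).abs().to_numpy() <= win
        if not ok.any():
            return False
        if max(DataStructs.BulkTanimotoSimilarity(dec_fps[i], act_fps)) >= criteria.max_tanimoto:
            return False
    return True


def balance_training_sets(
    partition: np.ndarray,
    labels: np.ndarray,
    strategy: str,
    features: np.ndarray | None = None,
    smiles: list[str] | None = None,
    decoy_pool: list[str] | None = None,
    criteria: DecoyCriteria | None = None,
    k_neighbors: int = 5,
    seed: int = 0,
) -> dict:
    """Augment train+validation to a 1:1 class ratio; test is untouched.

    Returns a dict with the augmented arrays: for ``smote`` and ``decoys``
    keys ``features``/``labels``/``partition``; for ``enumeration`` keys
    ``smiles``/``labels``/``partition``. New items are appended after the
    originals (train rows only), so all original indices — including every
    test row — are byte-identical.
    """
    partition = np.asarray(partition)
    labels = np.asarray(labels)
    tv_mask = partition != "test"
    tv_labels = labels[tv_mask]
    n_pos, n_neg = int(tv_labels.sum()), int((tv_labels == 0).sum())
    minority = 0 if n_neg < n_pos else 1
    deficit = abs(n_pos - n_neg)
    if deficit == 0:
        logger.info("train/validation already balanced; no-op")
        if strategy == "enumeration":
            return {"smiles": list(smiles), "labels": labels, "partition": partition,
                    "records": []}
        return {"features": features, "labels": labels, "partition": partition,
                "records": []}

    tv_min_idx = np.flatnonzero(tv_mask & (labels == minority))
    if strategy == "smote":
        if features is None:
            raise ValueError("SMOTE needs a numeric feature matrix")
        synth, records = smote(features[tv_min_idx], deficit,
                               k_neighbors=k_neighbors, seed=seed)
        return {
            "features": np.vstack([features, synth]),
            "labels": np.concatenate([labels, np.full(deficit, minority)]),
            "partition": np.concatenate([partition, np.full(deficit, "train")]),
            "records": records,
        }
    if strategy == "enumeration":
        if smiles is None:
            raise ValueError("enumeration needs SMILES strings, not a numeric matrix")
        rng = np.random.default_rng(seed)
        new_smiles: list[str] = []
        seen: set[str] = set()
        records = []
        parents = rng.permutation(tv_min_idx)
        per_parent = int(np.ceil(deficit / len(parents)))
        # several rounds: molecules with few distinct forms may under-deliver
        for round_factor in (1, 4, 16):
            for p in parents:
                if len(new_smiles) >= deficit:
                    break
                variants = enumerate_smiles(smiles[p], per_parent * round_factor,
                                            seed=int(rng.integers(2**31)))
                for v in variants:
                    if len(new_smiles) >= deficit:
                        break
                    if v in seen:
                        continue
                    seen.add(v)
                    new_smiles.append(v)
                    records.append(AugmentationRecord("enumeration", (int(p),), v))
            if len(new_smiles) >= deficit:
                break
        n_added = len(new_smiles)
        return {
            "smiles": list(smiles) + new_smiles,
            "labels": np.concatenate([labels, np.full(n_added, minority)]),
            "partition": np.concatenate([partition, np.full(n_added, "train")]),
            "records": records,
        }
    if strategy == "decoys":
        if smiles is None or decoy_pool is None:
            raise ValueError("decoy selection needs active SMILES and a pool")
        if minority != 0:
            raise ValueError(
                "decoy selection adds negatives, but the minority class here "
                "is positive")
        crit = criteria or DecoyCriteria()
        crit = DecoyCriteria(crit.property_windows, crit.max_tanimoto, deficit)
        actives = [smiles[i] for i in np.flatnonzero(tv_mask & (labels == 1))]
        decoys, records, funnel = select_decoys(actives, decoy_pool, crit, seed=seed)
        n_added = len(decoys)
        out = {
            "smiles": (list(smiles) + decoys) if smiles is not None else None,
            "labels": np.concatenate([labels, np.zeros(n_added, dtype=labels.dtype)]),
            "partition": np.concatenate([partition, np.full(n_added, "train")]),
            "records": records,
            "funnel": funnel,
        }
        return out
    raise ValueError(f"unknown strategy {strategy!r}")
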