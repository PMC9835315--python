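"""Molecular featurization and preprocessing.

Three numeric modalities — a pinned 208-descriptor physicochemical panel,
166-bit MACCS keys and 2048-bit ECFP4 (Morgan radius-2) fingerprints — plus
a token encoding of SMILES strings for the sequence model.

Numeric preprocessing follows a leakage-free fit/transform discipline:
zero-variance filtering, standardization (zero mean, unit population SD) and
PCA projection to 128 components are all fitted on designated fit rows only
and applied unchanged elsewhere. Processed 128-dim blocks are fused by
horizontal concatenation into the eight feature combinations.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

#: Pinned physicochemical descriptor panel (208 names). The toolkit's full
#: list grows across releases; the panel excludes post-pin additions so the
#: descriptor space stays fixed for any model trained with this package.
_EXCLUDED_DESCRIPTORS = {"AvgIpc", "SPS"}
DESCRIPTOR_PANEL: tuple[str, ...] = tuple(
    name for name, _ in Descriptors._descList if name not in _EXCLUDED_DESCRIPTORS
)
_DESCRIPTOR_FUNCS = {name: fn for name, fn in Descriptors._descList}

MACCS_BITS = 166
ECFP4_BITS = 2048
DEFAULT_PCA_DIM = 128
MAX_SMILES_LEN = 195

#: combo id -> ordered modalities, following the eight-feature catalogue
#: (4 is the SMILES sequence and has no numeric matrix).
FUSION_COMBOS: dict[int, tuple[str, ...]] = {
    1: ("descriptors",),
    2: ("ECFP4",),
    3: ("MACCS",),
    4: ("smiles",),
    5: ("descriptors", "ECFP4"),
    6: ("descriptors", "MACCS"),
    7: ("MACCS", "ECFP4"),
    8: ("descriptors", "ECFP4", "MACCS"),
}

# standard SMILES tokenization: bracket atoms, two-letter elements and
# two-character ring-bond tokens are single symbols
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|@@|%\d{2}|[BCNOPSFIbcnops]|[0-9]|\(|\)|=|#|-|\+|/|\\|\.|@|:|~|\*|\$)"
)


@dataclass
class FeatureBlock:
    """One modality's numeric matrix (compounds x dimensions)."""

    modality: str
    matrix: np.ndarray
    feature_names: tuple[str, ...]
    raw_dim: int

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix width must match feature_names")


@dataclass
class PreprocessState:
    """Frozen fit statistics for one modality's preprocessing chain."""

    kept_feature_indices: np.ndarray
    scaler: StandardScaler | None
    pca: PCA | None
    post_scaler: StandardScaler | None
    impute_values: np.ndarray | None = None
    kept_components: np.ndarray | None = None
    target_dim: int = DEFAULT_PCA_DIM


@dataclass
class FusedFeature:
    """Concatenation of processed 128-dim blocks for one combo id."""

    combo_id: int
    matrix: np.ndarray
    block_boundaries: tuple[int, ...]
    modalities: tuple[str, ...]


@dataclass
class TokenizedSmiles:
    """Integer-encoded SMILES with trailing zero padding (pad id 0)."""

    vocabulary: dict[str, int]
    sequences: np.ndarray
    lengths: np.ndarray
    max_len: int = MAX_SMILES_LEN


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def compute_descriptors(smiles: Sequence[str]) -> FeatureBlock:
    """Pinned 208-descriptor panel, one row per compound.

    Descriptors that fail for a molecule are stored as NaN; downstream
    preprocessing imputes them with fit-row column medians.
    """
    mat = np.empty((len(smiles), len(DESCRIPTOR_PANEL)), dtype=np.float64)
    for i, smi in enumerate(smiles):
        # reparse the canonical form so atom order (and hence descriptor
        # floating-point accumulation order) is notation-independent
        mol = _mol_from_smiles(Chem.MolToSmiles(_mol_from_smiles(smi)))
        for j, name in enumerate(DESCRIPTOR_PANEL):
            try:
                mat[i, j] = _DESCRIPTOR_FUNCS[name](mol)
            except Exception:  # a panel member failing on an exotic molecule
                mat[i, j] = np.nan
    n_bad = int(np.isnan(mat).sum())
    if n_bad:
        logger.info("descriptors: %d non-finite entries flagged for imputation", n_bad)
    return FeatureBlock("descriptors", mat, DESCRIPTOR_PANEL, len(DESCRIPTOR_PANEL))


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=ECFP4_BITS)


def compute_fingerprint(smiles: Sequence[str], kind: str) -> FeatureBlock:
    """Binary fingerprint matrix: MACCS (166 bits) or ECFP4 (2048 bits)."""
    if kind == "MACCS":
        width = MACCS_BITS
        rows = []
        for smi in smiles:
            bv = MACCSkeys.GenMACCSKeys(_mol_from_smiles(smi))
            arr = np.zeros(bv.GetNumBits(), dtype=np.float64)
            for b in bv.GetOnBits():
                arr[b] = 1.0
            rows.append(arr[1:])  # bit 0 of the toolkit's key set is unused
        names = tuple(f"MACCS_{i}" for i in range(1, width + 1))
    elif kind == "ECFP4":
        width = ECFP4_BITS
        rows = []
        for smi in smiles:
            bv = _MORGAN_GEN.GetFingerprint(_mol_from_smiles(smi))
            arr = np.zeros(width, dtype=np.float64)
            for b in bv.GetOnBits():
                arr[b] = 1.0
            rows.append(arr)
        names = tuple(f"ECFP4_{i}" for i in range(width))
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    mat = np.vstack(rows) if rows else np.empty((0, width))
    return FeatureBlock(kind, mat, names, width)


def drop_zero_variance(
    matrix: np.ndarray, fit_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove columns that are all zero on the fit rows.

    Returns the reduced matrix (all rows) and the kept column indices, which
    must be reapplied unchanged to any future data.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    fit = matrix[fit_rows]
    with np.errstate(invalid="ignore"):
        keep = ~np.all(np.nan_to_num(fit, nan=0.0) == 0.0, axis=0)
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError("all columns are zero on the fit rows")
    return matrix[:, kept], kept


def fit_apply_standardizer(
    matrix: np.ndarray, fit_rows: np.ndarray
) -> tuple[np.ndarray, StandardScaler]:
    """Standardize columns to mean 0 / population SD 1, fit on fit rows only."""
    fit = matrix[fit_rows]
    if fit.shape[0] < 2:
        raise ValueError("need at least 2 fit rows to standardize")
    sd = fit.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s) at fit time: {zero[:5].tolist()}")
    scaler = StandardScaler().fit(fit)
    return scaler.transform(matrix), scaler


def pca_reduce(
    matrix: np.ndarray,
    fit_rows: np.ndarray,
    target_dim: int = DEFAULT_PCA_DIM,
    seed: int = 0,
) -> tuple[np.ndarray, PCA]:
    """Project onto the top ``target_dim`` principal components (fit rows only)."""
    if matrix.shape[1] < target_dim:
        raise ValueError(
            f"input dim {matrix.shape[1]} < target dim {target_dim}")
    if len(fit_rows) <= target_dim:
        raise ValueError("need more fit rows than target dimensions")
    pca = PCA(n_components=target_dim, svd_solver="full", random_state=seed)
    pca.fit(matrix[fit_rows])
    return pca.transform(matrix), pca


def impute_nonfinite(
    matrix: np.ndarray, fit_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replace non-finite entries with fit-row column medians."""
    out = matrix.copy()
    fit = out[fit_rows]
    med = np.nanmedian(np.where(np.isfinite(fit), fit, np.nan), axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = np.take(med, np.nonzero(bad)[1])
    return out, med


def preprocess_block(
    block: FeatureBlock,
    fit_rows: np.ndarray,
    target_dim: int = DEFAULT_PCA_DIM,
    seed: int = 0,
) -> tuple[np.ndarray, PreprocessState]:
    """Full numeric chain: impute -> drop zero-variance -> standardize ->
    PCA -> standardize, everything fitted on ``fit_rows`` only.

    Descriptors are standardized before PCA (their scales differ by orders
    of magnitude); fingerprint bits go into PCA directly. Both end with a
    post-projection standardization so every modality enters the models on
    a common scale.
    """
    mat, med = impute_nonfinite(block.matrix, fit_rows)
    mat, kept = drop_zero_variance(mat, fit_rows)
    scaler = None
    if block.modality == "descriptors":
        # constant (non-zero) descriptors carry no information and would
        # break standardization
        varying = np.flatnonzero(mat[fit_rows].std(axis=0) > 0)
        mat, kept = mat[:, varying], kept[varying]
        mat, scaler = fit_apply_standardizer(mat, fit_rows)
    feasible = min(mat.shape[1], len(fit_rows) - 1)
    if feasible < target_dim:
        logger.warning("%s: clamping PCA target from %d to %d "
                       "(informative dims / fit rows limit)",
                       block.modality, target_dim, feasible)
        target_dim = feasible
    mat, pca = pca_reduce(mat, fit_rows, target_dim=target_dim, seed=seed)
    # components beyond the data's numerical rank carry zero variance
    kept_components = np.flatnonzero(pca.explained_variance_ > 1e-12)
    if len(kept_components) < mat.shape[1]:
        logger.warning("%s: dropping %d rank-deficient PCA components",
                       block.modality, mat.shape[1] - len(kept_components))
        mat = mat[:, kept_components]
    mat, post_scaler = fit_apply_standardizer(mat, fit_rows)
    state = PreprocessState(
        kept_feature_indices=kept, scaler=scaler, pca=pca,
        post_scaler=post_scaler, impute_values=med,
        kept_components=kept_components, target_dim=target_dim,
    )
    return mat, state


def apply_preprocess(block: FeatureBlock, state: PreprocessState) -> np.ndarray:
    """Apply a frozen :class:`PreprocessState` to new compounds."""
    mat = block.matrix.copy()
    bad = ~np.isfinite(mat)
    if bad.any():
        mat[bad] = np.take(state.impute_values, np.nonzero(bad)[1])
    mat = mat[:, state.kept_feature_indices]
    if state.scaler is not None:
        mat = state.scaler.transform(mat)
    mat = state.pca.transform(mat)
    if state.kept_components is not None:
        mat = mat[:, state.kept_components]
    return state.post_scaler.transform(mat)


def fuse(blocks: dict[str, np.ndarray], combo_id: int) -> FusedFeature:
    """Concatenate processed blocks horizontally for one combo id.

    ``blocks`` maps modality name -> processed (n x 128) matrix. Block order
    within a combo follows the combo's declared modality order.
    """
    if combo_id not in FUSION_COMBOS:
        raise ValueError(f"unknown combo id {combo_id}")
    modalities = FUSION_COMBOS[combo_id]
    if modalities == ("smiles",):
        raise ValueError("combo 4 is the SMILES sequence; it has no numeric matrix")
    missing = [m for m in modalities if m not in blocks]
    if missing:
        raise ValueError(f"missing blocks for combo {combo_id}: {missing}")
    parts = [blocks[m] for m in modalities]
    widths = [p.shape[1] for p in parts]
    boundaries = tuple(np.cumsum([0] + widths).tolist())
    return FusedFeature(
        combo_id=combo_id,
        matrix=np.hstack(parts),
        block_boundaries=boundaries,
        modalities=modalities,
    )


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into chemical symbols.

    Multi-character symbols (two-letter elements, bracket atoms, ``@@``,
    ``%nn`` ring bonds) are single tokens.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        leftover = re.sub(_TOKEN_RE, "", smiles)
        raise ValueError(f"untokenizable characters {leftover!r} in {smiles!r}")
    return tokens


def build_vocab(smiles: Iterable[str]) -> dict[str, int]:
    """Deterministic symbol vocabulary over a corpus; id 0 is the pad."""
    symbols: set[str] = set()
    n = 0
    for smi in smiles:
        symbols.update(tokenize(smi))
        n += 1
    if n == 0:
        raise ValueError("empty corpus")
    return {sym: i + 1 for i, sym in enumerate(sorted(symbols))}


def encode_smiles(
    smiles: Sequence[str],
    vocabulary: dict[str, int],
    max_len: int = MAX_SMILES_LEN,
) -> TokenizedSmiles:
    """Encode SMILES as fixed-length integer rows, zero-padded at the tail."""
    seqs = np.zeros((len(smiles), max_len), dtype=np.int64)
    lengths = np.zeros(len(smiles), dtype=np.int64)
    for i, smi in enumerate(smiles):
        tokens = tokenize(smi)
        if len(tokens) > max_len:
            raise ValueError(
                f"SMILES token length {len(tokens)} exceeds max_len {max_len}")
        unknown = [t for t in tokens if t not in vocabulary]
        if unknown:
            raise ValueError(f"symbols not in vocabulary: {sorted(set(unknown))}")
        seqs[i, : len(tokens)] = [vocabulary[t] for t in tokens]
        lengths[i] = len(tokens)
    return TokenizedSmiles(dict(vocabulary), seqs, lengths, max_len)


def decode_tokens(row: np.ndarray, vocabulary: dict[str, int]) -> list[str]:
    """Inverse of :func:`encode_smiles` for one row (pads dropped)."""
    inv = {i: s for s, i in vocabulary.items()}
    return [inv[t] for t in row if t != 0]


def save_vocab(vocabulary: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(vocabulary, indent=0, sort_keys=True))


def load_vocab(path: str | Path) -> dict[str, int]:
    return {k: int(v) for k, v in json.loads(Path(path).read_text()).items()}
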