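"""Synthetic molecule libraries with a planted structure-activity rule.

Compounds are assembled from 13 hand-written scaffold templates (distinct
ring systems) with three substitution slots filled from vetted substituent
lists, guaranteeing chemically valid SMILES by construction. Potency is
planted on the log10(uM) scale:

    log10 potency = mu(pharmacophore) + a(scaffold) + b(R1) + c(R2) + d(R3)
                    + Normal(0, noise_sd)

where the pharmacophore is a sulfonamide motif carried by slot-1
substituents with probability ``p_pharm``. Defaults are calibrated so that
activity cutoffs of 0.5 / 1 / 10 uM yield positive:negative ratios of
about 1:1, 3:2 and 4:1 — a balanced, slightly imbalanced and severely
imbalanced regime — while the scaffold families provide the cluster
structure a hold-out split needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_records import LabeledCompound, aggregate_duplicates, assign_labels

logger = logging.getLogger(__name__)

PHARMACOPHORE_SMARTS = "S(=O)(=O)N"

#: scaffold cores; {R1}..{R3} are branch slots on ring atoms
SCAFFOLDS: tuple[str, ...] = (
    "O=C(Nc1ccc({R1})cc1)c1ccc({R2})c({R3})c1",
    "c1cc({R1})ccc1Oc1ccc({R2})c({R3})c1",
    "c1cc({R1})ccc1-c1nc2cc({R2})c({R3})cc2[nH]1",
    "O=C1N(Cc2ccc({R1})cc2)C(=O)c2cc({R2})c({R3})cc21",
    "c1cc({R1})ccc1CN1CCN(c2ccc({R2})c({R3})c2)CC1",
    "c1cc({R1})ccc1-c1ccc2nc({R2})c({R3})nc2c1",
    "c1cc({R1})ccc1NC(=O)c1ccc({R2})c({R3})n1",
    "c1cc({R1})ccc1-c1sc({R2})c({R3})c1",
    "c1cc({R1})ccc1-c1nc({R2})nc({R3})c1N1CCOCC1",
    "O=C(Nc1ccc({R1})cc1)NCc1ccc({R2})c({R3})c1",
    "c1cc({R1})ccc1-c1cc({R2})nn1Cc1ccc({R3})cc1",
    "c1cc({R1})ccc1-c1cc2cc({R2})c({R3})cc2o1",
    "O=C(N1CCC(c2ccc({R1})cc2)CC1)c1cc({R2})c({R3})cc1",
)

#: slot-1 substituents carrying the sulfonamide pharmacophore
PHARM_SUBS: tuple[str, ...] = (
    "S(=O)(=O)N", "S(=O)(=O)NC", "S(=O)(=O)N(C)C", "S(=O)(=O)NCC",
    "NS(=O)(=O)C", "CNS(=O)(=O)C", "S(=O)(=O)NCCO", "CS(=O)(=O)N",
)
#: slot-1 substituents without it
PLAIN_SUBS: tuple[str, ...] = ("C", "OC", "F", "C(C)C")
#: slot-2/3 substituents (activity-neutral on average)
NEUTRAL_SUBS: tuple[str, ...] = (
    "C", "CC", "CCC", "OC", "OCC", "F", "Cl", "Br",
    "C(F)(F)F", "N", "N(C)C", "C#N",
)


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the study conditions."""

    n_compounds: int = 4500
    n_scaffold_families: int = 13
    p_pharm: float = 0.8
    mu_active: float = -0.57    # mean log10 uM with pharmacophore
    mu_inactive: float = 2.3    # mean log10 uM without
    noise_sd: float = 0.25
    contrib_scale: float = 1.0  # scales scaffold/substituent contributions
    family_weight_decay: float = 0.85  # geometric family abundance (skewed chemotypes)
    n_neutral_subs: int = 12    # substituent alphabet size for slots 2-3
    seed: int = 0
    target_ratios: dict = field(default_factory=lambda: {
        0.5: 0.50, 1.0: 0.60, 10.0: 0.80})

    def __post_init__(self) -> None:
        if not 4 <= self.n_scaffold_families <= len(SCAFFOLDS):
            raise ValueError(
                f"n_scaffold_families must be in [4, {len(SCAFFOLDS)}]")


def _contribs(n: int, half_width: float) -> np.ndarray:
    return np.linspace(-half_width, half_width, n)


def generate_library(spec: SyntheticSpec) -> pd.DataFrame:
    """Sample a compound library under the planted potency rule.

    Returns one row per generated record: smiles, canonical_smiles,
    family_id, pharmacophore flag, noiseless and noisy log10 potency and
    activity_um. Raises if any template yields an invalid SMILES.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds = SCAFFOLDS[: spec.n_scaffold_families]
    neutral = NEUTRAL_SUBS[: spec.n_neutral_subs]
    a = _contribs(len(scaffolds), 0.3) * spec.contrib_scale
    b_pharm = _contribs(len(PHARM_SUBS), 0.95) * spec.contrib_scale
    b_plain = _contribs(len(PLAIN_SUBS), 0.6) * spec.contrib_scale
    cd = _contribs(len(neutral), 0.7) * spec.contrib_scale

    weights = spec.family_weight_decay ** np.arange(len(scaffolds))
    weights /= weights.sum()
    a = a - float(weights @ a)  # zero mean under the sampling weights
    fam = rng.choice(len(scaffolds), size=spec.n_compounds, p=weights)
    has_pharm = rng.random(spec.n_compounds) < spec.p_pharm
    r1_pharm = rng.integers(0, len(PHARM_SUBS), size=spec.n_compounds)
    r1_plain = rng.integers(0, len(PLAIN_SUBS), size=spec.n_compounds)
    r2 = rng.integers(0, len(neutral), size=spec.n_compounds)
    r3 = rng.integers(0, len(neutral), size=spec.n_compounds)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)

    rows = []
    for i in range(spec.n_compounds):
        if has_pharm[i]:
            r1_smi, r1_c = PHARM_SUBS[r1_pharm[i]], b_pharm[r1_pharm[i]]
            mu = spec.mu_active
        else:
            r1_smi, r1_c = PLAIN_SUBS[r1_plain[i]], b_plain[r1_plain[i]]
            mu = spec.mu_inactive
        smi = scaffolds[fam[i]].format(
            R1=r1_smi, R2=neutral[r2[i]], R3=neutral[r3[i]])
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise RuntimeError(f"generator bug: invalid SMILES {smi!r}")
        can = Chem.MolToSmiles(mol)
        if len(can) > 195:
            raise RuntimeError(f"generator bug: SMILES longer than 195: {can!r}")
        noiseless = mu + a[fam[i]] + r1_c + cd[r2[i]] + cd[r3[i]]
        log_potency = noiseless + noise[i]
        rows.append({
            "smiles": smi,
            "canonical_smiles": can,
            "family_id": int(fam[i]),
            "pharmacophore": bool(has_pharm[i]),
            "log10_potency_noiseless": float(noiseless),
            "log10_potency": float(log_potency),
            "activity_um": float(10.0 ** log_potency),
        })
    return pd.DataFrame(rows)


PRESETS = {
    "balanced": 0.5,   # ~1:1
    "slight": 1.0,     # ~3:2
    "severe": 10.0,    # ~4:1
}


def make_benchmark(
    spec: SyntheticSpec,
    preset: str = "balanced",
) -> tuple[list[LabeledCompound], dict]:
    """Curated benchmark at one of the canned cutoff regimes.

    Duplicate structures generated by independent draws are aggregated
    exactly as real curation would do (median potency). The ground-truth
    manifest records the planted rule per unique compound for recovery
    tests: scaffold family, pharmacophore flag and noiseless potency.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {list(PRESETS)}")
    cutoff = PRESETS[preset]
    lib = generate_library(spec)
    entries = list(zip(lib["canonical_smiles"], lib["activity_um"]))
    unique = aggregate_duplicates(entries)
    compounds = assign_labels(unique, cutoff)
    first = lib.drop_duplicates("canonical_smiles").set_index("canonical_smiles")
    manifest = {
        "preset": preset,
        "cutoff_um": cutoff,
        "pharmacophore_smarts": PHARMACOPHORE_SMARTS,
        "n_generated": int(len(lib)),
        "n_unique": len(compounds),
        "family_id": {c.canonical_smiles: int(first.loc[c.canonical_smiles, "family_id"])
                      for c in compounds},
        "pharmacophore": {c.canonical_smiles: bool(first.loc[c.canonical_smiles,
                                                             "pharmacophore"])
                          for c in compounds},
        "log10_potency_noiseless": {
            c.canonical_smiles: float(first.loc[c.canonical_smiles,
                                                "log10_potency_noiseless"])
            for c in compounds},
    }
    frac = np.mean([c.label for c in compounds])
    logger.info("benchmark %s: %d unique compounds, positive fraction %.3f",
                preset, len(compounds), frac)
    return compounds, manifest


def permute_labels(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Null dataset: labels randomly permuted, features untouched."""
    rng = np.random.default_rng(seed)
    return rng.permutation(np.asarray(labels))
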