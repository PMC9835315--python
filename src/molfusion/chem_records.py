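"""Curation of small-molecule activity records.

Reads tabular (CSV/TSV) or SDF activity data, converts potencies to a common
micromolar scale, canonicalizes SMILES, aggregates duplicate structures and
assigns binary activity labels at a potency cutoff.

Potency measures (Ki, Kd, IC50) are pooled without assay-type correction;
a compound is *active* (label 1) when its potency is strictly below the
cutoff, otherwise inactive (label 0).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

ALLOWED_ASSAYS = ("Ki", "Kd", "IC50")
ALLOWED_UNITS = ("nM", "uM", "mM")
STANDARD_CUTOFFS_UM = (0.5, 1.0, 10.0)

#: scale factors to micromolar
_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "mM": 1e3}
#: accepted spellings, normalised before lookup
_UNIT_ALIASES = {
    "nm": "nM",
    "um": "uM",
    "µm": "uM",
    "μm": "uM",
    "mm": "mM",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class ActivityRecord:
    """A single raw potency measurement for one molecule."""

    smiles_raw: str
    assay_type: str
    value: float
    unit: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.smiles_raw:
            raise ValueError("smiles_raw must be non-empty")
        if self.value <= 0 or not np.isfinite(self.value):
            raise ValueError(f"activity value must be positive, got {self.value}")
        if self.unit not in ALLOWED_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; allowed: {ALLOWED_UNITS}")


@dataclass(frozen=True)
class LabeledCompound:
    """A curated unique compound with potency in uM and a binary label."""

    canonical_smiles: str
    activity_um: float
    label: int
    cutoff_um: float
    n_merged: int = 1

    def __post_init__(self) -> None:
        if self.activity_um <= 0:
            raise ValueError("activity_um must be positive")
        expected = int(self.activity_um < self.cutoff_um)
        if self.label != expected:
            raise ValueError(
                f"label {self.label} inconsistent with activity "
                f"{self.activity_um} uM at cutoff {self.cutoff_um} uM"
            )


@dataclass
class RejectionReport:
    """Bookkeeping for rows dropped during parsing/curation."""

    n_read: int = 0
    n_kept: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row_index: int, reason: str) -> None:
        self.rejected.append((row_index, reason))
        logger.warning("row %d rejected: %s", row_index, reason)


def normalize_unit(unit: str) -> str:
    """Map unit spellings (case, micro sign) onto the canonical tags."""
    u = unit.strip()
    if u in ALLOWED_UNITS:
        return u
    return _UNIT_ALIASES.get(u.lower(), u)


def convert_to_micromolar(value: float, unit: str) -> float:
    """Express a potency given in nM/uM/mM in micromolar."""
    u = normalize_unit(unit)
    if u not in _UNIT_TO_UM:
        raise ValueError(f"unknown unit {unit!r}; allowed: {ALLOWED_UNITS}")
    return value * _UNIT_TO_UM[u]


def canonicalize(smiles_raw: str) -> str:
    """Return the toolkit-canonical SMILES for a molecule.

    Raises :class:`SmilesParseError` on chemically invalid input.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles_raw!r}")
    return Chem.MolToSmiles(mol)


def parse_activity_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[ActivityRecord], RejectionReport]:
    """Read activity records from a delimited text file.

    Parameters
    ----------
    path
        CSV/TSV file with one measurement per row.
    column_map
        Maps record fields (``smiles``, ``assay_type``, ``value``, ``unit``,
        optionally ``source_id``) to column names in the file. Defaults to
        identity names.
    delimiter
        Field delimiter; inferred from the extension when omitted
        (``.tsv`` -> tab, else comma).

    Rows with an unparseable value or a unit outside {nM, uM, mM} are
    skipped and recorded in the returned :class:`RejectionReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cmap = {"smiles": "smiles", "assay_type": "assay_type",
            "value": "value", "unit": "unit", "source_id": "source_id"}
    if column_map:
        cmap.update(column_map)

    report = RejectionReport()
    records: list[ActivityRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            logger.warning("empty activity table: %s", path)
            return records, report
        required = [cmap["smiles"], cmap["value"], cmap["unit"]]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"no mappable columns; missing {missing} in {path}")
        for i, row in enumerate(reader):
            report.n_read += 1
            smiles = (row.get(cmap["smiles"]) or "").strip()
            if not smiles:
                report.reject(i, "empty SMILES")
                continue
            try:
                value = float(row[cmap["value"]])
            except (TypeError, ValueError):
                report.reject(i, f"unparseable value {row.get(cmap['value'])!r}")
                continue
            unit = normalize_unit((row.get(cmap["unit"]) or "").strip())
            if unit not in ALLOWED_UNITS:
                report.reject(i, f"unknown unit {row.get(cmap['unit'])!r}")
                continue
            if value <= 0:
                report.reject(i, f"non-positive value {value}")
                continue
            assay = (row.get(cmap["assay_type"]) or "IC50").strip() or "IC50"
            records.append(ActivityRecord(
                smiles_raw=smiles, assay_type=assay, value=value, unit=unit,
                source_id=(row.get(cmap.get("source_id", "source_id")) or "").strip(),
            ))
            report.n_kept += 1
    if report.n_read == 0:
        logger.warning("activity table %s contained no data rows", path)
    return records, report


def parse_activity_sdf(
    path: str | Path,
    value_prop: str = "value",
    unit_prop: str = "unit",
    assay_prop: str = "assay_type",
) -> tuple[list[ActivityRecord], RejectionReport]:
    """Read activity records from an SDF with activity data as properties."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = RejectionReport()
    records: list[ActivityRecord] = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        report.n_read += 1
        if mol is None:
            report.reject(i, "unreadable molecule block")
            continue
        if not mol.HasProp(value_prop) or not mol.HasProp(unit_prop):
            report.reject(i, f"missing {value_prop}/{unit_prop} properties")
            continue
        try:
            value = float(mol.GetProp(value_prop))
        except ValueError:
            report.reject(i, f"unparseable value {mol.GetProp(value_prop)!r}")
            continue
        unit = normalize_unit(mol.GetProp(unit_prop))
        if unit not in ALLOWED_UNITS or value <= 0:
            report.reject(i, f"bad unit/value ({unit}, {value})")
            continue
        assay = mol.GetProp(assay_prop) if mol.HasProp(assay_prop) else "IC50"
        records.append(ActivityRecord(
            smiles_raw=Chem.MolToSmiles(mol), assay_type=assay,
            value=value, unit=unit, source_id=f"sdf:{i}",
        ))
        report.n_kept += 1
    return records, report


def aggregate_duplicates(
    entries: Iterable[tuple[str, float]],
) -> list[tuple[str, float, int]]:
    """Merge entries sharing a canonical SMILES into unique compounds.

    The aggregated potency is the median of the member potencies (robust to
    outlying measurements); ``n_merged`` records how many source entries
    were pooled. Input SMILES must already be canonical. Output order is
    first-seen order.
    """
    groups: dict[str, list[float]] = {}
    order: list[str] = []
    for smiles, activity in entries:
        if smiles not in groups:
            groups[smiles] = []
            order.append(smiles)
        groups[smiles].append(activity)
    return [(s, float(np.median(groups[s])), len(groups[s])) for s in order]


def assign_labels(
    compounds: Iterable[tuple[str, float, int]],
    cutoff_um: float,
) -> list[LabeledCompound]:
    """Label unique compounds at a potency cutoff (strict ``<`` = active).

    ``compounds`` are (canonical_smiles, activity_um, n_merged) triples as
    produced by :func:`aggregate_duplicates`.
    """
    if cutoff_um not in STANDARD_CUTOFFS_UM:
        logger.warning("non-standard cutoff %.3g uM (standard: %s)",
                       cutoff_um, STANDARD_CUTOFFS_UM)
    out = [
        LabeledCompound(
            canonical_smiles=s,
            activity_um=a,
            label=int(a < cutoff_um),
            cutoff_um=cutoff_um,
            n_merged=n,
        )
        for s, a, n in compounds
    ]
    n_pos = sum(c.label for c in out)
    logger.info("labels at %.3g uM: %d active / %d inactive",
                cutoff_um, n_pos, len(out) - n_pos)
    return out


def curate(
    records: Sequence[ActivityRecord],
    cutoff_um: float,
) -> tuple[list[LabeledCompound], RejectionReport]:
    """Full curation: convert units, canonicalize, aggregate, label.

    Records whose SMILES fail canonicalization are dropped with a report
    entry rather than aborting the run.
    """
    report = RejectionReport(n_read=len(records))
    entries: list[tuple[str, float]] = []
    for i, rec in enumerate(records):
        try:
            smiles = canonicalize(rec.smiles_raw)
        except SmilesParseError as exc:
            report.reject(i, str(exc))
            continue
        entries.append((smiles, convert_to_micromolar(rec.value, rec.unit)))
        report.n_kept += 1
    compounds = assign_labels(aggregate_duplicates(entries), cutoff_um)
    return compounds, report


def to_frame(compounds: Sequence[LabeledCompound]) -> pd.DataFrame:
    """Curated compounds as a DataFrame in the package's CSV schema."""
    return pd.DataFrame(
        {
            "canonical_smiles": [c.canonical_smiles for c in compounds],
            "activity_um": [c.activity_um for c in compounds],
            "label": [c.label for c in compounds],
            "cutoff_um": [c.cutoff_um for c in compounds],
            "n_merged": [c.n_merged for c in compounds],
        }
    )


def write_curated_csv(compounds: Sequence[LabeledCompound], path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly
    to_frame(compounds).to_csv(path, index=False, float_format="%.17g")


def read_curated_csv(path: str | Path) -> list[LabeledCompound]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        LabeledCompound(
            canonical_smiles=row.canonical_smiles,
            activity_um=float(row.activity_um),
            label=int(row.label),
            cutoff_um=float(row.cutoff_um),
            n_merged=int(row.n_merged),
        )
        for row in df.itertuples()
    ]
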