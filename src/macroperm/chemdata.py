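"""Permeability record curation: parsing, deduplication, swing-range labeling.

Permeability is carried as ``neg_log_papp`` = -log10(P_app) with P_app in cm/s.
A compound with P_app = 1e-6 cm/s has neg_log_papp = 6.0, the unified decision
threshold used throughout. The *swing range* is an exclusion interval around
that threshold: measurements falling inside it are too close to the boundary to
be trusted given inter-laboratory spread, and are dropped before classification
training. The half-open interval [center - halfwidth, center + halfwidth) is
excluded.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

__all__ = [
    "Assay",
    "Label",
    "AbsorptionBin",
    "RingCategory",
    "MoleculeRecord",
    "LabeledRecord",
    "CurationReport",
    "canonicalize_and_key",
    "dedup_by_inchikey",
    "swing_label",
    "label_records",
    "caco2_three_bin",
    "ring_size_category",
    "largest_ring_size",
    "pair_deviation_stats",
    "read_dataset",
    "write_dataset",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class Assay(str, enum.Enum):
    CACO2 = "CACO2"
    MDCK = "MDCK"
    RRCK = "RRCK"
    PAMPA = "PAMPA"
    SYNTHETIC = "SYNTHETIC"


class Label(enum.IntEnum):
    IMPERMEABLE = 0
    PERMEABLE = 1
    EXCLUDED = -1


class AbsorptionBin(str, enum.Enum):
    POOR = "POOR"
    MODERATE = "MODERATE"
    WELL = "WELL"


class RingCategory(str, enum.Enum):
    NON_MACROCYCLE = "NON_MACROCYCLE"
    SMALL = "SMALL"      # 12-15 ring atoms
    MEDIUM = "MEDIUM"    # 16-18 ring atoms
    LARGE = "LARGE"      # >18 ring atoms


@dataclass(frozen=True)
class MoleculeRecord:
    """One assay measurement of one compound."""

    smiles: str
    inchikey: str
    assay: Assay
    neg_log_papp: float
    conditions: dict | None = None
    source_id: str = ""
    largest_ring_size: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.neg_log_papp):
            raise ValueError(f"neg_log_papp must be finite, got {self.neg_log_papp!r}")
        if not _INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey: {self.inchikey!r}")
        if self.largest_ring_size < 0:
            raise ValueError("largest_ring_size must be >= 0")


@dataclass(frozen=True)
class LabeledRecord:
    record: MoleculeRecord
    label: Label
    swing_center: float
    swing_halfwidth: float


@dataclass
class CurationReport:
    n_input: int = 0
    n_deduplicated: int = 0
    n_excluded_swing: int = 0
    n_positive: int = 0
    n_negative: int = 0

    @property
    def class_balance(self) -> float:
        kept = self.n_positive + self.n_negative
        return self.n_positive / kept if kept else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_deduplicated": self.n_deduplicated,
            "n_excluded_swing": self.n_excluded_swing,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "class_balance": self.class_balance,
        }


def canonicalize_and_key(smiles: str) -> tuple[str, str]:
    """Canonical SMILES and standard InChIKey for a structure.

    Raises ``ValueError`` naming the offending string if the SMILES does not
    parse. Canonicalization is idempotent: feeding the returned SMILES back
    returns it unchanged.
    """
    if not smiles:
        raise ValueError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol), Chem.MolToInchiKey(mol)


def largest_ring_size(smiles: str) -> int:
    """Size of the largest SSSR ring (0 for acyclic molecules)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def dedup_by_inchikey(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Drop duplicate measurements of the same structure within each assay.

    Records are grouped by (inchikey, assay); the first record per group after
    a stable sort on source_id is retained. Cross-assay duplicates are kept:
    different assays are distinct supervision signals.
    """
    report = CurationReport(n_input=len(records))
    ordered = sorted(
        enumerate(records), key=lambda t: (t[1].inchikey, t[1].assay.value, t[1].source_id, t[0])
    )
    seen: set[tuple[str, str]] = set()
    kept_idx: list[int] = []
    for idx, rec in ordered:
        key = (rec.inchikey, rec.assay.value)
        if key not in seen:
            seen.add(key)
            kept_idx.append(idx)
    kept_idx.sort()  # preserve input order
    kept = [records[i] for i in kept_idx]
    report.n_deduplicated = len(kept)
    return kept, report


def swing_label(
    neg_log_papp: float,
    center: float = 6.0,
    halfwidth: float = 0.5,
    label_direction: str = "low_is_permeable",
) -> Label:
    """Swing-range label: EXCLUDED inside [center-hw, center+hw), else binary.

    Under the default direction a *low* neg_log_papp (high P_app) is PERMEABLE,
    consistent with permeable-as-positive at the 1e-6 cm/s threshold. Pass
    ``label_direction="high_is_permeable"`` for the inverted convention.
    """
    if not math.isfinite(neg_log_papp):
        raise ValueError("neg_log_papp must be finite")
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if label_direction not in ("low_is_permeable", "high_is_permeable"):
        raise ValueError(f"unknown label_direction {label_direction!r}")
    if center - halfwidth <= neg_log_papp < center + halfwidth:
        return Label.EXCLUDED
    low_side = neg_log_papp < center
    if label_direction == "low_is_permeable":
        return Label.PERMEABLE if low_side else Label.IMPERMEABLE
    return Label.IMPERMEABLE if low_side else Label.PERMEABLE


def label_records(
    records: Sequence[MoleculeRecord],
    center: float = 6.0,
    halfwidth: float = 0.5,
    label_direction: str = "low_is_permeable",
    aggregate: str | None = None,
) -> tuple[list[LabeledRecord], CurationReport]:
    """Deduplicate then swing-label a record set; returns labeled records + report.

    ``aggregate="mean"`` averages repeated measurements of the same
    (inchikey, assay) pair in -log P space before labeling instead of
    dedup-first.
    """
    report = CurationReport(n_input=len(records))
    if aggregate == "mean":
        groups: dict[tuple[str, str], list[MoleculeRecord]] = {}
        order: list[tuple[str, str]] = []
        for rec in records:
            key = (rec.inchikey, rec.assay.value)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(rec)
        deduped = [
            replace(groups[k][0], neg_log_papp=sum(r.neg_log_papp for r in groups[k]) / len(groups[k]))
            for k in order
        ]
    elif aggregate is None:
        deduped, _ = dedup_by_inchikey(records)
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    report.n_deduplicated = len(deduped)

    labeled: list[LabeledRecord] = []
    for rec in deduped:
        lab = swing_label(rec.neg_log_papp, center, halfwidth, label_direction)
        labeled.append(LabeledRecord(rec, lab, center, halfwidth))
        if lab is Label.EXCLUDED:
            report.n_excluded_swing += 1
        elif lab is Label.PERMEABLE:
            report.n_positive += 1
        else:
            report.n_negative += 1
    return labeled, report


def caco2_three_bin(papp: float) -> AbsorptionBin:
    """Caco-2 absorption bin from P_app in cm/s.

    P_app < 1e-6: poorly absorbed (0-20%); 1e-6..1e-5: moderate (20-70%);
    > 1e-5: well absorbed (70-100%).
    """
    if not (papp > 0) or not math.isfinite(papp):
        raise ValueError(f"P_app must be positive and finite, got {papp!r}")
    if papp < 1e-6:
        return AbsorptionBin.POOR
    if papp <= 1e-5:
        return AbsorptionBin.MODERATE
    return AbsorptionBin.WELL


def ring_size_category(size: int) -> RingCategory:
    """Macrocycle ring-size stratum: 12-15 small, 16-18 medium, >18 large."""
    if size < 0:
        raise ValueError("ring size must be >= 0")
    if size < 12:
        return RingCategory.NON_MACROCYCLE
    if size <= 15:
        return RingCategory.SMALL
    if size <= 18:
        return RingCategory.MEDIUM
    return RingCategory.LARGE


def pair_deviation_stats(
    pairs: Sequence[tuple[float, float]],
    threshold: float = 6.0,
    delta: float = 0.5,
) -> dict[str, float]:
    """Inter-laboratory deviation statistics over repeated-measurement pairs.

    ``frac_within_delta``: fraction of pairs whose absolute difference does
    not exceed delta (boundary inclusive, with a 1e-12 float guard so a
    deviation of exactly delta counts as within).
    ``frac_conflicting``: fraction whose two values fall on opposite sides of
    the classification threshold (one < threshold, the other >= threshold).
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    n = len(pairs)
    within = sum(1 for a, b in pairs if abs(a - b) <= delta + 1e-12)
    conflicting = sum(1 for a, b in pairs if (a < threshold) != (b < threshold))
    return {"frac_within_delta": within / n, "frac_conflicting": conflicting / n}


_REQUIRED_COLUMNS = ("smiles", "assay", "neg_log_papp")
_ALL_COLUMNS = ("smiles", "inchikey", "assay", "neg_log_papp", "ph", "temperature", "source_id", "largest_ring_size")


def read_dataset(path, fmt: str = "csv") -> list[MoleculeRecord]:
    """Read permeability records from CSV/TSV with header columns
    smiles, assay, neg_log_papp [, inchikey, ph, temperature, source_id]."""
    sep = "\t" if fmt.lower() in ("tsv", "tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"source_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    records: list[MoleculeRecord] = []
    for i, row in df.iterrows():
        try:
            value = float(row["neg_log_papp"])
            smiles = str(row["smiles"])
            if "inchikey" in df.columns and isinstance(row.get("inchikey"), str):
                can, key = str(row["smiles"]), str(row["inchikey"])
            else:
                can, key = canonicalize_and_key(smiles)
            conditions = {}
            for c in ("ph", "temperature"):
                if c in df.columns and pd.notna(row[c]):
                    conditions[c] = float(row[c])
            if "largest_ring_size" in df.columns and pd.notna(row.get("largest_ring_size")):
                ring = int(row["largest_ring_size"])
            else:
                ring = largest_ring_size(can)
            records.append(
                MoleculeRecord(
                    smiles=can,
                    inchikey=key,
                    assay=Assay(str(row["assay"])),
                    neg_log_papp=value,
                    conditions=conditions or None,
                    source_id=str(row["source_id"]) if "source_id" in df.columns and pd.notna(row.get("source_id")) else "",
                    largest_ring_size=ring,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def write_dataset(records: Iterable[MoleculeRecord], path, fmt: str = "csv") -> None:
    """Write records as CSV/TSV; round-trips bit-exactly through read_dataset."""
    sep = "\t" if fmt.lower() in ("tsv", "tab") else ","
    rows = []
    for rec in records:
        cond = rec.conditions or {}
        rows.append(
            {
                "smiles": rec.smiles,
                "inchikey": rec.inchikey,
                "assay": rec.assay.value,
                "neg_log_papp": repr(rec.neg_log_papp),
                "ph": cond.get("ph", ""),
                "temperature": cond.get("temperature", ""),
                "source_id": rec.source_id,
                "largest_ring_size": rec.largest_ring_size,
            }
        )
    pd.DataFrame(rows, columns=_ALL_COLUMNS).to_csv(path, sep=sep, index=False)


def write_labeled_dataset(labeled: Iterable[LabeledRecord], path, fmt: str = "csv") -> None:
    """Labeled records as CSV/TSV (record columns + label/swing columns)."""
    sep = "\t" if fmt.lower() in ("tsv", "tab") else ","
    rows = []
    for lr in labeled:
        rec = lr.record
        cond = rec.conditions or {}
        rows.append(
            {
                "smiles": rec.smiles,
                "inchikey": rec.inchikey,
                "assay": rec.assay.value,
                "neg_log_papp": repr(rec.neg_log_papp),
                "ph": cond.get("ph", ""),
                "temperature": cond.get("temperature", ""),
                "source_id": rec.source_id,
                "largest_ring_size": rec.largest_ring_size,
                "label": int(lr.label),
                "swing_center": repr(lr.swing_center),
                "swing_halfwidth": repr(lr.swing_halfwidth),
            }
        )
    cols = list(_ALL_COLUMNS) + ["label", "swing_center", "swing_halfwidth"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def read_labeled_dataset(path, fmt: str = "csv") -> list[LabeledRecord]:
    sep = "\t" if fmt.lower() in ("tsv", "tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"source_id": str})
    for col in ("label", "swing_center", "swing_halfwidth"):
        if col not in df.columns:
            raise ValueError(f"missing required column(s): {col}")
    records = read_dataset(path, fmt)
    return [
        LabeledRecord(
            rec,
            Label(int(df.iloc[i]["label"])),
            float(df.iloc[i]["swing_center"]),
            float(df.iloc[i]["swing_halfwidth"]),
        )
        for i, rec in enumerate(records)
    ]
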