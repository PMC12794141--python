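"""Seeded generator of macrocycle-like molecules with a known latent
permeability function.

Molecules are cyclic (head-to-tail amide closure) or linear peptide-like
chains of amino-acid-style building blocks with configurable side chains
(none, methyl, hydroxymethyl, carboxymethyl, benzyl) and optional backbone
N-methylation.  The latent -log10(P_app) is linear in interpretable
descriptors - hydrogen-bond-donor count (the dominant driver), molecular
weight, hydrophobic-atom fraction and the macrocycle flag - so every
downstream test has a closed-form ground truth.  Observed records add an
assay-specific offset plus Gaussian noise; per-(molecule, assay) RNG streams
are derived from the master seed by stable hashing, so adding molecules never
perturbs existing draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski

from .chemdata import (
    Assay,
    Label,
    LabeledRecord,
    MoleculeRecord,
    canonicalize_and_key,
    label_records,
    largest_ring_size,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SIDE_CHAINS",
    "generate_library",
    "latent_neg_log_papp",
    "simulate_assays",
    "make_benchmark",
    "label_flip_rate",
]

# side-chain fragments attached to the alpha carbon
SIDE_CHAINS = ("", "C", "CO", "CC(=O)O", "Cc1ccccc1")


@dataclass
class SyntheticSpec:
    building_blocks: tuple[str, ...] = SIDE_CHAINS
    ring_size_range: tuple[int, int] = (4, 8)   # residues per cycle -> 12-24 ring atoms
    n_large: int = 2000
    n_task: int = 200
    beta: dict = field(
        default_factory=lambda: {
            "intercept": 3.85,
            "hbd": 0.35,        # dominant driver: each donor costs ~0.35 log units
            "mw_per_100": 0.15,
            "hydrophobic_frac": -2.0,
            "macrocycle": 0.2,
        }
    )
    assay_offsets: dict = field(
        default_factory=lambda: {"CACO2": 0.0, "MDCK": 0.1, "RRCK": 0.1, "PAMPA": 0.2}
    )
    noise_sd: float = 0.4
    cyclic_fraction: float = 0.7
    n_methyl_prob: float = 0.35
    task_swing_halfwidth: float = 0.5
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_large <= 0 or self.n_task <= 0:
            raise ValueError("n_large and n_task must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for frag in self.building_blocks:
            if frag and Chem.MolFromSmiles(frag) is None:
                raise ValueError(f"building block does not parse: {frag!r}")


@dataclass
class GroundTruth:
    mu: dict[str, float]              # inchikey -> latent -log P
    true_label: dict[str, int]        # binary at center 6.0, low side permeable
    driver_channel: str = "hbd"


@dataclass
class _Molecule:
    smiles: str
    inchikey: str
    is_macrocycle: bool
    ring_size: int
    hbd: int
    mw: float
    hydrophobic_frac: float


def _residue_unit(side: str, n_methyl: bool, last_in_ring: bool = False) -> str:
    ca = "C" if not side else f"C({side})"
    if last_in_ring:
        return f"{ca}N1" + ("C" if n_methyl else "")
    return ca + ("N(C)" if n_methyl else "N")


def _cyclic_smiles(residues: list[tuple[str, bool]]) -> str:
    parts = ["O=C1"]
    for i, (side, nme) in enumerate(residues):
        last = i == len(residues) - 1
        parts.append(_residue_unit(side, nme, last_in_ring=last))
        if not last:
            parts.append("C(=O)")
    return "".join(parts)


def _linear_smiles(residues: list[tuple[str, bool]]) -> str:
    parts = []
    for side, nme in residues:
        n = "N(C)" if nme else "N"
        ca = "C" if not side else f"C({side})"
        parts.append(f"{n}{ca}C(=O)")
    return "".join(parts) + "O"


def _stable_stream(*tokens) -> np.random.Generator:
    digest = hashlib.sha256("|".join(str(t) for t in tokens).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2**31))


def _metadata(smiles: str) -> _Molecule:
    can, key = canonicalize_and_key(smiles)
    mol = Chem.MolFromSmiles(can)
    heavy = mol.GetNumHeavyAtoms()
    n_carbon = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
    ring = largest_ring_size(can)
    return _Molecule(
        smiles=can,
        inchikey=key,
        is_macrocycle=ring >= 12,
        ring_size=ring,
        hbd=int(Lipinski.NumHDonors(mol)),
        mw=float(Descriptors.MolWt(mol)),
        hydrophobic_frac=n_carbon / heavy if heavy else 0.0,
    )


def generate_library(spec: SyntheticSpec, n: int | None = None) -> list[_Molecule]:
    """Sample n unique molecules (default n_large + n_task), seed-deterministic."""
    n = n if n is not None else spec.n_large + spec.n_task
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ring_size_range
    seen: set[str] = set()
    out: list[_Molecule] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                f"could not assemble {n} unique molecules from the given blocks"
            )
        n_res = int(rng.integers(lo, hi + 1))
        residues = [
            (
                spec.building_blocks[int(rng.integers(0, len(spec.building_blocks)))],
                bool(rng.random() < spec.n_methyl_prob),
            )
            for _ in range(n_res)
        ]
        cyclic = bool(rng.random() < spec.cyclic_fraction)
        smiles = _cyclic_smiles(residues) if cyclic else _linear_smiles(residues)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise RuntimeError(f"assembled SMILES does not parse: {smiles!r}")
        meta = _metadata(smiles)
        if meta.inchikey in seen:
            continue
        seen.add(meta.inchikey)
        out.append(meta)
    return out


def latent_neg_log_papp(molecule: _Molecule, beta: dict) -> float:
    """mu = b0 + b_hbd*HBD + b_mw*(MW/100) + b_hyd*hydfrac + b_ring*is_macro."""
    return (
        beta["intercept"]
        + beta["hbd"] * molecule.hbd
        + beta["mw_per_100"] * (molecule.mw / 100.0)
        + beta["hydrophobic_frac"] * molecule.hydrophobic_frac
        + beta["macrocycle"] * (1.0 if molecule.is_macrocycle else 0.0)
    )


def simulate_assays(
    molecules: Sequence[_Molecule],
    spec: SyntheticSpec,
    assays: Sequence[str] | None = None,
    n_assays_per_molecule: tuple[int, int] = (1, 4),
) -> list[MoleculeRecord]:
    """Observed records: value = mu + assay offset + N(0, noise_sd).

    Each molecule reports in 1-4 assays (seeded per molecule); the noise draw
    for a (molecule, assay) pair comes from its own hashed RNG stream.
    """
    pool = list(assays) if assays is not None else sorted(spec.assay_offsets)
    for a in pool:
        if a not in spec.assay_offsets:
            raise ValueError(f"assay {a!r} missing from assay_offsets")
    records = []
    for m in molecules:
        mu = latent_neg_log_papp(m, spec.beta)
        pick_rng = _stable_stream(spec.seed, m.inchikey, "assays")
        lo = min(n_assays_per_molecule[0], len(pool))
        hi = min(n_assays_per_molecule[1], len(pool))
        n_a = int(pick_rng.integers(lo, hi + 1))
        chosen = sorted(pick_rng.choice(pool, size=n_a, replace=False).tolist())
        for assay in chosen:
            noise_rng = _stable_stream(spec.seed, m.inchikey, assay)
            noise = float(noise_rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
            records.append(
                MoleculeRecord(
                    smiles=m.smiles,
                    inchikey=m.inchikey,
                    assay=Assay(assay),
                    neg_log_papp=mu + spec.assay_offsets[assay] + noise,
                    source_id=f"synthetic:{assay}",
                    largest_ring_size=m.ring_size,
                )
            )
    return records


def make_benchmark(
    spec: SyntheticSpec,
) -> tuple[list[LabeledRecord], list[LabeledRecord], GroundTruth]:
    """(large multi-assay set, task PAMPA set, ground truth).

    The large set pools Caco-2/MDCK/RRCK records labeled at the unified
    threshold (halfwidth 0); the task set holds PAMPA records labeled with the
    configured swing halfwidth.  Molecule pools are disjoint unless
    ``allow_overlap``.  EXCLUDED task records are retained in the returned
    list (callers filter before training).
    """
    library = generate_library(spec)
    rng = np.random.default_rng(spec.seed + 1)
    order = rng.permutation(len(library))
    large_pool = [library[i] for i in order[: spec.n_large]]
    task_pool = (
        [library[i] for i in order[spec.n_large : spec.n_large + spec.n_task]]
        if not spec.allow_overlap
        else [library[i] for i in order[: spec.n_task]]
    )

    large_records = simulate_assays(large_pool, spec, assays=("CACO2", "MDCK", "RRCK"))
    task_records = simulate_assays(
        task_pool, spec, assays=("PAMPA",), n_assays_per_molecule=(1, 1)
    )
    large_labeled, _ = label_records(large_records, center=6.0, halfwidth=0.0)
    task_labeled, _ = label_records(
        task_records, center=6.0, halfwidth=spec.task_swing_halfwidth
    )
    truth = GroundTruth(
        mu={m.inchikey: latent_neg_log_papp(m, spec.beta) for m in library},
        true_label={
            m.inchikey: int(latent_neg_log_papp(m, spec.beta) < 6.0) for m in library
        },
    )
    return large_labeled, task_labeled, truth


def label_flip_rate(labeled: Sequence[LabeledRecord], truth: GroundTruth) -> float:
    """Fraction of retained (non-EXCLUDED) records whose observed label
    disagrees with the noiseless ground-truth label."""
    kept = [lr for lr in labeled if lr.label is not Label.EXCLUDED]
    if not kept:
        raise ValueError("no retained records")
    flips = sum(
        1 for lr in kept if int(lr.label) != truth.true_label[lr.record.inchikey]
    )
    return flips / len(kept)
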