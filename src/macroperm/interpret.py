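"""Feature attribution by channel masking, and conformer-ensemble geometry.

Channel importance: for each node-feature channel, rebuild the evaluation
graphs with that channel zeroed, re-evaluate the model loss, and report the
loss increase relative to the unmasked baseline.  Channels whose masking
hurts most are the features the model leans on.

Geometry: intramolecular hydrogen bonds are detected with the standard
distance/angle criterion (H...A <= 2.5 A and D-H-A angle >= 120 deg);
solvent-accessible surface area uses the Shrake-Rupley construction with a
deterministic golden-spiral point lattice on each probe-expanded sphere.  Both
are implemented on plain coordinate arrays so they run on fixture geometries
without any conformer generator; RDKit conformer embedding sits behind a
narrow helper for real molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemdata import LabeledRecord
from .evalx import bce_loss
from .featurize import LARGE_RING_MIN_SIZE, NodeFeatureSchema, mask_feature_channel

__all__ = [
    "GeometrySpec",
    "Conformer",
    "ConformerSet",
    "ImportanceReport",
    "BONDI_RADII",
    "golden_spiral_points",
    "shrake_rupley_sasa",
    "detect_imhb",
    "kabsch_rmsd",
    "select_conformers",
    "polar_exposure_profile",
    "channel_importance",
    "top_confident",
    "conformers_from_rdkit",
    "read_conformers_sdf",
    "write_conformers_sdf",
]

# Bondi van der Waals radii (Angstrom)
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

PER_DONOR_UNDEFINED = float("nan")  # sentinel when a molecule has no donors


@dataclass
class GeometrySpec:
    hb_dmax: float = 2.5          # A, max H...A distance
    hb_angle_min: float = 120.0   # deg, min D-H-A angle
    probe_radius: float = 1.4     # A, water probe
    n_test_points: int = 960      # golden-spiral lattice points per sphere

    def __post_init__(self) -> None:
        if self.hb_dmax <= 0 or not (0 < self.hb_angle_min <= 180) or self.probe_radius < 0:
            raise ValueError("invalid geometry spec")
        if self.n_test_points < 92:
            raise ValueError("n_test_points must be >= 92")


@dataclass
class Conformer:
    elements: list[str]
    coords: np.ndarray            # (n_atoms, 3) in A
    bonds: list[tuple[int, int]]  # covalent bonds (explicit hydrogens included)
    energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords shape must be (n_atoms, 3)")


@dataclass
class ConformerSet:
    molecule_id: str
    conformers: list[Conformer]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("empty conformer ensemble")
        ref = self.conformers[0].elements
        for c in self.conformers[1:]:
            if c.elements != ref:
                raise ValueError("conformers must share atom count and element order")


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (deterministic Fibonacci lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii(elements: Sequence[str]) -> np.ndarray:
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        if el not in BONDI_RADII:
            raise ValueError(f"no van der Waals radius for element {el!r}")
        out[i] = BONDI_RADII[el]
    return out


def shrake_rupley_sasa(conformer: Conformer, spec: GeometrySpec | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area in A^2.

    SASA_i = 4 pi (R_i + R_probe)^2 * N_accessible_i / N_total_i, where a test
    point on atom i's expanded sphere is accessible iff it lies outside every
    other atom's expanded sphere.
    """
    spec = spec or GeometrySpec()
    radii = _radii(conformer.elements) + spec.probe_radius
    coords = conformer.coords
    n = len(radii)
    unit = golden_spiral_points(spec.n_test_points)
    sasa = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(spec.n_test_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            # quick reject: spheres too far apart to occlude
            if np.linalg.norm(coords[j] - coords[i]) >= radii[i] + radii[j]:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / spec.n_test_points
    return sasa


def _donor_hydrogens(conformer: Conformer) -> list[tuple[int, int]]:
    """(donor_heavy, hydrogen) pairs: H covalently bound to N or O."""
    pairs = []
    for u, v in conformer.bonds:
        for h, d in ((u, v), (v, u)):
            if conformer.elements[h] == "H" and conformer.elements[d] in ("N", "O"):
                pairs.append((d, h))
    return pairs


def detect_imhb(
    conformer: Conformer,
    donors: Sequence[tuple[int, int]] | None = None,
    acceptors: Sequence[int] | None = None,
    spec: GeometrySpec | None = None,
) -> list[tuple[int, int, int]]:
    """Intramolecular hydrogen bonds as (donor, hydrogen, acceptor) triples.

    A triple is reported iff d(H, A) <= hb_dmax and the D-H-A angle (vertex at
    H) >= hb_angle_min, with A != D and A not covalently bonded to H.  Donors
    default to N/O-bound hydrogens; acceptors default to all N/O atoms.
    """
    spec = spec or GeometrySpec()
    if "H" not in conformer.elements:
        raise ValueError(
            "no hydrogen atoms present; protonate the structure (explicit H) first"
        )
    if donors is None:
        donors = _donor_hydrogens(conformer)
    if acceptors is None:
        acceptors = [
            i for i, el in enumerate(conformer.elements) if el in ("N", "O")
        ]
    bonded = {frozenset(b) for b in conformer.bonds}
    coords = conformer.coords
    out = []
    for d, h in donors:
        for a in acceptors:
            if a == d or frozenset((h, a)) in bonded:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[h]))
            if dist > spec.hb_dmax:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            cosang = float(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            )
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle >= spec.hb_angle_min:
                out.append((d, h, a))
    return out


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shape")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = a0 @ rot.T - b0
    return float(np.sqrt((diff**2).sum() / len(a)))


def select_conformers(
    candidates: Sequence[Conformer],
    k: int,
    rmsd_min: float = 0.5,
    molecule_id: str = "mol",
) -> ConformerSet:
    """Greedy diverse low-energy ensemble selection.

    Candidates are visited in ascending energy; one is skipped if its
    heavy-atom RMSD (after optimal superposition) to any already-selected
    conformer is below ``rmsd_min``.  Selection stops at k; fewer survivors
    are allowed (logged).
    """
    if not candidates:
        raise ValueError("no candidate conformers")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i].energy if candidates[i].energy is not None else 0.0, i),
    )
    heavy = [
        np.asarray([j for j, el in enumerate(candidates[0].elements) if el != "H"])
    ][0]
    selected: list[Conformer] = []
    for i in order:
        cand = candidates[i]
        coords = cand.coords[heavy] if len(heavy) else cand.coords
        if rmsd_min > 0 and any(
            kabsch_rmsd(coords, (s.coords[heavy] if len(heavy) else s.coords)) < rmsd_min
            for s in selected
        ):
            continue
        selected.append(cand)
        if len(selected) == k:
            break
    if len(selected) < k:
        warnings.warn(f"only {len(selected)} of {k} requested conformers survive rmsd_min")
    return ConformerSet(molecule_id, selected)


def polar_exposure_profile(
    ensemble: ConformerSet, spec: GeometrySpec | None = None
) -> dict[str, float]:
    """HBD/HBA solvent exposure and IMHB statistics averaged over conformers.

    Donor exposure is the SASA of N/O-bound hydrogens summed per conformer;
    acceptor exposure sums N/O heavy-atom SASA.  ``per_donor_sasa`` is
    total/donor-count (NaN sentinel when the molecule has no donors).  A donor
    heavy atom counts as ring-embedded iff it sits in a ring of >= 12 atoms;
    ring membership is approximated from the covalent graph cycle structure.
    """
    spec = spec or GeometrySpec()
    import networkx as nx

    first = ensemble.conformers[0]
    donors = _donor_hydrogens(first)
    acceptors = [i for i, el in enumerate(first.elements) if el in ("N", "O")]
    donor_heavies = sorted({d for d, _ in donors})

    g = nx.Graph(first.bonds)
    g.add_nodes_from(range(len(first.elements)))
    large_ring_atoms: set[int] = set()
    for cycle in nx.cycle_basis(g):
        if len(cycle) >= LARGE_RING_MIN_SIZE:
            large_ring_atoms.update(cycle)
    sidechain_hbd = [d for d in donor_heavies if d not in large_ring_atoms]

    tot_hbd, tot_hba, n_imhb = [], [], []
    for conf in ensemble.conformers:
        sasa = shrake_rupley_sasa(conf, spec)
        tot_hbd.append(float(sum(sasa[h] for _, h in donors)))
        tot_hba.append(float(sum(sasa[a] for a in acceptors)))
        n_imhb.append(len(detect_imhb(conf, donors, acceptors, spec)))
    k = len(ensemble.conformers)
    total_hbd = float(np.mean(tot_hbd))
    total_hba = float(np.mean(tot_hba))
    return {
        "total_hbd_sasa": total_hbd,
        "per_donor_sasa": total_hbd / len(donor_heavies) if donor_heavies else PER_DONOR_UNDEFINED,
        "total_hba_sasa": total_hba,
        "per_acceptor_sasa": total_hba / len(acceptors) if acceptors else PER_DONOR_UNDEFINED,
        "sidechain_hbd_count": float(len(sidechain_hbd)),
        "imhb_count": float(np.mean(n_imhb)),
        "n_conformers": float(k),
    }


@dataclass
class ImportanceReport:
    baseline_loss: float
    delta_loss: dict[str, float]          # channel -> loss(masked) - baseline
    delta_loss_sd: dict[str, float] = field(default_factory=dict)

    @property
    def ranking(self) -> list[str]:
        return sorted(self.delta_loss, key=lambda c: -self.delta_loss[c])


def channel_importance(
    model,
    eval_records: Sequence[LabeledRecord],
    schema: NodeFeatureSchema | None = None,
) -> ImportanceReport:
    """Delta-BCE per masked node-feature channel on a fixed evaluation set.

    The unmasked baseline is computed once; for each channel the evaluation
    graphs are rebuilt with that channel zeroed and the model re-evaluated.
    The record count never changes under masking.
    """
    schema = schema or model.cache.schema
    y = np.asarray([int(lr.label) for lr in eval_records], dtype=float)
    ds = model._dataset(eval_records)
    idx = np.arange(len(eval_records))

    def _loss_with_graphs(graphs) -> float:
        from .autodiff import no_grad

        saved = ds.graphs
        ds.graphs = graphs
        try:
            with no_grad():
                z = model.core.forward(*ds.slice(idx)).data[:, 0]
        finally:
            ds.graphs = saved
        p = np.where(z >= 0, 1 / (1 + np.exp(-z)), np.exp(z) / (1 + np.exp(z)))
        return bce_loss(y, p)

    baseline = _loss_with_graphs(ds.graphs)
    deltas: dict[str, float] = {}
    for channel in schema.channel_names:
        masked = [mask_feature_channel(g, channel, schema) for g in ds.graphs]
        deltas[channel] = _loss_with_graphs(masked) - baseline
    return ImportanceReport(baseline_loss=baseline, delta_loss=deltas)


def top_confident(
    probabilities: Sequence[float], labels: Sequence[int], n: int
) -> tuple[list[int], list[int]]:
    """Indices of the n most confident positives and negatives.

    Positives (label 1) are ranked by probability descending, negatives
    (label 0) ascending; ties keep stable record order.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = [int(i) for i in np.flatnonzero(y == 1)]
    neg = [int(i) for i in np.flatnonzero(y == 0)]
    if n > len(pos) or n > len(neg):
        raise ValueError(f"n={n} exceeds class sizes ({len(pos)} pos, {len(neg)} neg)")
    top_pos = sorted(pos, key=lambda i: (-p[i], i))[:n]
    top_neg = sorted(neg, key=lambda i: (p[i], i))[:n]
    return top_pos, top_neg


def conformers_from_rdkit(
    smiles: str, n_candidates: int = 20, seed: int = 0
) -> list[Conformer]:
    """Embed 3D conformer candidates with RDKit ETKDG + MMFF (narrow helper)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_candidates, params=params)
    try:
        energies = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=200)
    except Exception:
        energies = [(0, None)] * len(ids)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    out = []
    for cid, (_, energy) in zip(ids, energies):
        coords = mol.GetConformer(cid).GetPositions()
        out.append(Conformer(elements, coords, bonds, energy=energy))
    return out


def write_conformers_sdf(ensemble: ConformerSet, path) -> None:
    """Write an ensemble as a multi-record SDF (one record per conformer)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    first = ensemble.conformers[0]
    mol = Chem.RWMol()
    for el in first.elements:
        mol.AddAtom(Chem.Atom(el))
    for u, v in first.bonds:
        mol.AddBond(int(u), int(v), Chem.BondType.SINGLE)
    base = mol.GetMol()
    writer = Chem.SDWriter(str(path))
    try:
        for i, conf in enumerate(ensemble.conformers):
            m = Chem.Mol(base)
            c = Chem.Conformer(m.GetNumAtoms())
            for j, (x, y, z) in enumerate(conf.coords):
                c.SetAtomPosition(j, Point3D(float(x), float(y), float(z)))
            m.AddConformer(c, assignId=True)
            m.SetProp("_Name", f"{ensemble.molecule_id}_{i}")
            if conf.energy is not None:
                m.SetProp("energy", repr(conf.energy))
            writer.write(m)
    finally:
        writer.close()


def read_conformers_sdf(path, molecule_id: str | None = None) -> ConformerSet:
    """Read a multi-record SDF (explicit hydrogens expected) as an ensemble."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    conformers: list[Conformer] = []
    name = molecule_id
    for m in supplier:
        if m is None:
            continue
        if name is None and m.HasProp("_Name"):
            name = m.GetProp("_Name").rsplit("_", 1)[0]
        energy = float(m.GetProp("energy")) if m.HasProp("energy") else None
        conformers.append(
            Conformer(
                elements=[a.GetSymbol() for a in m.GetAtoms()],
                coords=m.GetConformer().GetPositions(),
                bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in m.GetBonds()],
                energy=energy,
            )
        )
    if not conformers:
        raise ValueError(f"no conformers read from {path}")
    return ConformerSet(name or "mol", conformers)
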