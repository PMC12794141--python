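"""Molecular graph, descriptor and fingerprint featurization.

The node feature schema is channel-structured so that any named channel can be
masked (zeroed) for feature-attribution experiments. Channels cover standard
GNN atom features plus the permeability-relevant flags: hydrogen-bond donor /
acceptor, lone-pair count, and membership in a large ring (>= 12 atoms, the
macrocycle threshold).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

__all__ = [
    "NodeFeatureSchema",
    "MolGraph",
    "FeatureBundle",
    "build_mol_graph",
    "lone_pair_count",
    "compute_descriptors",
    "compute_fingerprints",
    "mask_feature_channel",
    "Standardizer",
    "DESCRIPTOR_NAMES",
    "LARGE_RING_MIN_SIZE",
]

LARGE_RING_MIN_SIZE = 12

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "other")
_DEGREES = (0, 1, 2, 3, 4, 5)
_HYBRID = ("SP", "SP2", "SP3", "other")
_CHIRAL = ("NONE", "CW", "CCW", "other")
_VALENCE_ELECTRONS = {
    "H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
}

_BOND_TYPES = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
_BOND_STEREO = ("NONE", "Z", "E", "other")
EDGE_DIM = len(_BOND_TYPES) + 2 + len(_BOND_STEREO)


@dataclass(frozen=True)
class NodeFeatureSchema:
    """Ordered node feature channels with widths; versioned for checkpoints.

    The exact channel list is this package's reconstruction: element / degree /
    hybridization / chirality one-hots, formal charge, aromaticity, the HBD and
    HBA flags, lone-pair count, large-ring membership and total hydrogen count.
    It is fully configurable so an alternative schema can be swapped in.
    """

    version: str = "macroperm-node-v1"
    channels: tuple[tuple[str, int], ...] = (
        ("element", len(_ELEMENTS)),
        ("degree", len(_DEGREES)),
        ("formal_charge", 1),
        ("aromatic", 1),
        ("hybridization", len(_HYBRID)),
        ("chirality", len(_CHIRAL)),
        ("hbd", 1),
        ("hba", 1),
        ("lone_pairs", 1),
        ("in_large_ring", 1),
        ("total_h", 1),
    )

    @property
    def dim(self) -> int:
        return sum(w for _, w in self.channels)

    def channel_slice(self, name: str) -> slice:
        start = 0
        for ch, w in self.channels:
            if ch == name:
                return slice(start, start + w)
            start += w
        raise KeyError(
            f"unknown channel {name!r}; schema channels: {[c for c, _ in self.channels]}"
        )

    @property
    def channel_names(self) -> list[str]:
        return [c for c, _ in self.channels]

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "channels": list(self.channels)})

    @classmethod
    def from_json(cls, text: str) -> "NodeFeatureSchema":
        d = json.loads(text)
        return cls(version=d["version"], channels=tuple((c, w) for c, w in d["channels"]))


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with directed edges stored both ways."""

    n_nodes: int
    node_features: np.ndarray  # (n_nodes, d_node)
    edge_index: np.ndarray     # (n_edges, 2) int, directed; (u,v) and (v,u) both present
    edge_features: np.ndarray  # (n_edges, d_edge); feature of (u,v) == feature of (v,u)
    schema_version: str = "macroperm-node-v1"

    def copy(self) -> "MolGraph":
        return MolGraph(
            self.n_nodes,
            self.node_features.copy(),
            self.edge_index.copy(),
            self.edge_features.copy(),
            self.schema_version,
        )


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * len(choices)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # "other" slot
    return vec


def lone_pair_count(element: str, formal_charge: int, total_valence: int) -> int:
    """Nonbonding electron pairs: (valence e- − charge − bonding e-) / 2, floor 0.

    ``total_valence`` counts bonding electrons contributed by the atom (sum of
    bond orders including attached hydrogens). Oxygen in water: (6-0-2)/2 = 2;
    nitrogen in ammonia: (5-0-3)/2 = 1; carbon in methane: 0.
    """
    if element not in _VALENCE_ELECTRONS:
        warnings.warn(f"no valence-electron count for element {element!r}; lone pairs set to 0")
        return 0
    n = _VALENCE_ELECTRONS[element] - formal_charge - total_valence
    return max(n // 2, 0)


def _is_hbd(atom: Chem.Atom) -> bool:
    return atom.GetSymbol() in ("N", "O") and atom.GetTotalNumHs() >= 1


def _is_hba(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() not in ("N", "O"):
        return False
    return lone_pair_count(atom.GetSymbol(), atom.GetFormalCharge(), atom.GetTotalValence()) >= 1


def build_mol_graph(smiles: str, schema: NodeFeatureSchema | None = None) -> MolGraph:
    """Build the node/edge feature graph for one molecule (implicit hydrogens).

    ``in_large_ring`` is 1 iff the atom belongs to any SSSR ring of size >=
    12. Elements outside the schema alphabet fall into the "other" one-hot
    slot with a warning.
    """
    schema = schema or NodeFeatureSchema()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")

    large_ring_atoms: set[int] = set()
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) >= LARGE_RING_MIN_SIZE:
            large_ring_atoms.update(ring)

    rows = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _ELEMENTS[:-1]:
            warnings.warn(f"element {sym!r} outside alphabet; using 'other' slot")
        chiral = {
            Chem.ChiralType.CHI_UNSPECIFIED: "NONE",
            Chem.ChiralType.CHI_TETRAHEDRAL_CW: "CW",
            Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "CCW",
        }.get(atom.GetChiralTag(), "other")
        hyb = str(atom.GetHybridization())
        row = (
            _one_hot(sym, _ELEMENTS)
            + _one_hot(atom.GetDegree(), _DEGREES)
            + [float(atom.GetFormalCharge())]
            + [1.0 if atom.GetIsAromatic() else 0.0]
            + _one_hot(hyb if hyb in _HYBRID else "other", _HYBRID)
            + _one_hot(chiral, _CHIRAL)
            + [1.0 if _is_hbd(atom) else 0.0]
            + [1.0 if _is_hba(atom) else 0.0]
            + [float(lone_pair_count(sym, atom.GetFormalCharge(), atom.GetTotalValence()))]
            + [1.0 if atom.GetIdx() in large_ring_atoms else 0.0]
            + [float(atom.GetTotalNumHs())]
        )
        rows.append(row)

    edges = []
    efeats = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        stereo = {
            Chem.BondStereo.STEREONONE: "NONE",
            Chem.BondStereo.STEREOZ: "Z",
            Chem.BondStereo.STEREOE: "E",
        }.get(bond.GetStereo(), "other")
        feat = (
            _one_hot(str(bond.GetBondType()), _BOND_TYPES)
            + [1.0 if bond.GetIsConjugated() else 0.0]
            + [1.0 if bond.IsInRing() else 0.0]
            + _one_hot(stereo, _BOND_STEREO)
        )
        edges.append((u, v))
        efeats.append(feat)
        edges.append((v, u))
        efeats.append(feat)

    node_features = np.asarray(rows, dtype=np.float64).reshape(mol.GetNumAtoms(), schema.dim)
    edge_index = (
        np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges
        else np.zeros((0, 2), dtype=np.int64)
    )
    edge_features = (
        np.asarray(efeats, dtype=np.float64)
        if efeats
        else np.zeros((0, EDGE_DIM), dtype=np.float64)
    )
    return MolGraph(mol.GetNumAtoms(), node_features, edge_index, edge_features, schema.version)


def mask_feature_channel(
    graph: MolGraph, channel_name: str, schema: NodeFeatureSchema | None = None
) -> MolGraph:
    """Return a copy of the graph with the named channel zeroed for all nodes."""
    schema = schema or NodeFeatureSchema()
    sl = schema.channel_slice(channel_name)  # raises KeyError listing schema
    out = graph.copy()
    out.node_features[:, sl] = 0.0
    return out


# Fixed RDKit 2D descriptor panel: compact, fast, and covers the size /
# lipophilicity / polarity axes that drive passive permeability.
DESCRIPTOR_NAMES = (
    "MolWt", "MolLogP", "TPSA", "NumHDonors", "NumHAcceptors",
    "NumRotatableBonds", "RingCount", "FractionCSP3", "HeavyAtomCount",
    "NumAromaticRings", "NHOHCount", "NOCount", "LabuteASA",
    "BalabanJ", "BertzCT", "MolMR", "qed", "MaxPartialCharge",
    "MinPartialCharge", "NumSaturatedRings",
)


def compute_descriptors(smiles: str, family: str = "RDKIT_2D") -> np.ndarray:
    """Fixed-length 2D descriptor vector; non-finite entries imputed to 0."""
    if family.upper() not in ("RDKIT_2D", "RDKIT"):
        raise ValueError(f"descriptor family {family!r} is not available; use 'RDKIT_2D'")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    lookup = dict(Descriptors.descList)
    out = np.empty(len(DESCRIPTOR_NAMES), dtype=np.float64)
    for i, name in enumerate(DESCRIPTOR_NAMES):
        try:
            val = float(lookup[name](mol))
        except Exception:
            val = float("nan")
        out[i] = val
    bad = ~np.isfinite(out)
    if bad.any():
        warnings.warn(
            f"imputed 0 for non-finite descriptor(s) "
            f"{[DESCRIPTOR_NAMES[i] for i in np.flatnonzero(bad)]} on {smiles!r}"
        )
        out[bad] = 0.0
    return out


_MORGAN_GEN = None


def _morgan_generator():
    global _MORGAN_GEN
    if _MORGAN_GEN is None:
        _MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return _MORGAN_GEN


def compute_fingerprints(smiles: str) -> tuple[np.ndarray, np.ndarray]:
    """(ECFP radius-2 2048-bit, MACCS 167-bit) fingerprints as 0/1 arrays."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    ecfp = _morgan_generator().GetFingerprint(mol)
    maccs = MACCSkeys.GenMACCSKeys(mol)
    return (
        np.array(ecfp, dtype=np.float64),
        np.array(maccs, dtype=np.float64),
    )


class Standardizer:
    """Column-wise (x - mean) / sd with statistics frozen on the training set.

    Non-finite entries are excluded from the fit; zero-variance columns get
    sd = 1 so they pass through centered.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        masked = np.where(np.isfinite(X), X, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_ = np.nan_to_num(np.nanmean(masked, axis=0))
            self.sd_ = np.nan_to_num(np.nanstd(masked, axis=0, ddof=0))
        self.sd_[self.sd_ == 0.0] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        X = np.asarray(X, dtype=np.float64)
        out = (np.where(np.isfinite(X), X, 0.0) - self.mean_) / self.sd_
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "sd": self.sd_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        obj = cls()
        obj.mean_ = np.asarray(d["mean"], dtype=np.float64)
        obj.sd_ = np.asarray(d["sd"], dtype=np.float64)
        return obj


@dataclass
class FeatureBundle:
    """All representations of one molecule used by the mixture-of-experts."""

    graph: MolGraph
    descriptors: np.ndarray
    ecfp: np.ndarray
    maccs: np.ndarray
    extra_global: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def from_smiles(
        cls, smiles: str, schema: NodeFeatureSchema | None = None
    ) -> "FeatureBundle":
        ecfp, maccs = compute_fingerprints(smiles)
        return cls(
            graph=build_mol_graph(smiles, schema),
            descriptors=compute_descriptors(smiles),
            ecfp=ecfp,
            maccs=maccs,
        )
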