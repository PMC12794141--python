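"""Leakage-free fold assignment, scaffold similarity, and the high-fidelity
injection protocol.

Cross-validation folds are assigned to *units* (unique SMILES, Murcko
scaffold, or fingerprint cluster), never to individual records, so identical
or scaffold-sharing structures can never straddle a train/validation boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .chemdata import MoleculeRecord
from .featurize import compute_fingerprints

__all__ = [
    "FoldAssignment",
    "ClusterModel",
    "assign_folds",
    "murcko_scaffold",
    "scaffold_tanimoto_matrix",
    "cluster_high_fidelity",
    "injection_protocol",
    "selection_overlap",
    "EMPTY_SCAFFOLD",
]

EMPTY_SCAFFOLD = ""  # sentinel for acyclic molecules


@dataclass
class FoldAssignment:
    unit_of_record: list[str]       # unit key per record, aligned with input
    fold_of_unit: dict[str, int]
    k: int
    mode: str
    seed: int

    @property
    def folds(self) -> np.ndarray:
        return np.asarray([self.fold_of_unit[u] for u in self.unit_of_record], dtype=int)


@dataclass
class ClusterModel:
    n_clusters: int
    centroids: np.ndarray
    labels: np.ndarray
    chosen_by: str                  # ELBOW, SILHOUETTE, or BOTH
    embedding: np.ndarray           # points in the space that was clustered
    inertia_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]


def murcko_scaffold(smiles: str) -> str:
    """Murcko scaffold SMILES (ring systems + linkers); '' for acyclic input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaf)


def _unit_keys(records: Sequence[MoleculeRecord], mode: str, seed: int) -> list[str]:
    if mode == "SMILES":
        return [Chem.MolToSmiles(Chem.MolFromSmiles(r.smiles)) for r in records]
    if mode == "SCAFFOLD":
        return [murcko_scaffold(r.smiles) or f"__acyclic__{r.inchikey}" for r in records]
    if mode == "CLUSTER":
        model = cluster_high_fidelity(records, range(2, min(9, len(records))), seed)
        return [f"cluster_{c}" for c in model.labels]
    if mode == "RANDOM":
        return [f"record_{i}" for i in range(len(records))]
    raise ValueError(f"unknown split mode {mode!r}")


def assign_folds(
    records: Sequence[MoleculeRecord],
    mode: str = "SMILES",
    k: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Assign every record to one of k folds without splitting any unit.

    SMILES/RANDOM units are shuffled and dealt round-robin (fold sizes differ
    by at most one unit); SCAFFOLD/CLUSTER units are greedily bin-packed in
    descending size so record counts stay balanced despite uneven unit sizes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not records:
        raise ValueError("records must be non-empty")
    units = _unit_keys(records, mode, seed)
    distinct = sorted(set(units))
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds the {len(distinct)} distinct {mode} units")
    rng = np.random.default_rng(seed)

    fold_of_unit: dict[str, int] = {}
    if mode in ("SMILES", "RANDOM"):
        order = list(distinct)
        rng.shuffle(order)
        for i, u in enumerate(order):
            fold_of_unit[u] = i % k
    else:
        sizes: dict[str, int] = {}
        for u in units:
            sizes[u] = sizes.get(u, 0) + 1
        order = sorted(distinct, key=lambda u: (-sizes[u], u))
        load = np.zeros(k, dtype=int)
        for u in order:
            f = int(np.argmin(load))
            fold_of_unit[u] = f
            load[f] += sizes[u]
    return FoldAssignment(units, fold_of_unit, k, mode, seed)


def scaffold_tanimoto_matrix(scaffolds: Sequence[str]) -> np.ndarray:
    """Pairwise Tanimoto similarity of scaffold ECFP4 (radius 2, 2048 bits).

    An empty scaffold has similarity 0 against everything and 1 with itself.
    """
    if not scaffolds:
        raise ValueError("need at least one scaffold")
    fps: list[set[int] | None] = []
    for s in scaffolds:
        if s == EMPTY_SCAFFOLD:
            fps.append(None)
            continue
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparsable scaffold SMILES: {s!r}")
        from .featurize import _morgan_generator

        bv = _morgan_generator().GetFingerprint(mol)
        fps.append(set(bv.GetOnBits()))
    n = len(fps)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                sim = 1.0
            elif fps[i] is None or fps[j] is None:
                sim = 0.0
            else:
                inter = len(fps[i] & fps[j])
                union = len(fps[i] | fps[j])
                sim = inter / union if union else 0.0
            out[i, j] = out[j, i] = sim
    return out


def _elbow_k(inertia_by_k: dict[int, float]) -> int:
    """k with the maximum second difference of within-cluster SSE."""
    ks = sorted(inertia_by_k)
    if len(ks) < 3:
        return ks[0]
    best_k, best_curv = ks[1], -np.inf
    for a, b, c in zip(ks, ks[1:], ks[2:]):
        curv = inertia_by_k[a] - 2 * inertia_by_k[b] + inertia_by_k[c]
        if curv > best_curv:
            best_curv, best_k = curv, b
    return best_k


def cluster_high_fidelity(
    records: Sequence[MoleculeRecord],
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
    cluster_space: str = "tsne",
    features: np.ndarray | None = None,
) -> ClusterModel:
    """ECFP fingerprints -> (optionally) 2D t-SNE -> k-means with k chosen by
    silhouette score, cross-checked against the elbow criterion.

    ``cluster_space``: "tsne" (cluster the seeded 2D embedding, perplexity
    capped at (n-1)/3) or "fingerprint" (cluster the raw 2048-bit space).
    Silhouette wins elbow/silhouette conflicts; ties break toward smaller k.
    """
    k_range = sorted(set(int(k) for k in k_range))
    n_points = len(features) if features is not None else len(records)
    if n_points < max(k_range):
        raise ValueError("need at least max(k_range) records")
    X = (
        np.asarray(features, dtype=np.float64)
        if features is not None
        else np.asarray([compute_fingerprints(r.smiles)[0] for r in records])
    )
    if np.all(X == X[0]):
        raise ValueError("all points identical; clustering is degenerate (single cluster)")
    if cluster_space == "tsne":
        perplexity = min(30.0, (len(records) - 1) / 3.0)
        emb = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(X)
    elif cluster_space == "fingerprint":
        emb = X.astype(np.float64)
    else:
        raise ValueError(f"unknown cluster_space {cluster_space!r}")

    inertia, silhouette, fits = {}, {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
        inertia[k] = float(km.inertia_)
        silhouette[k] = float(silhouette_score(emb, km.labels_))
        fits[k] = km
    sil_best = max(silhouette.values())
    k_sil = min(k for k, v in silhouette.items() if v == sil_best)
    k_elbow = _elbow_k(inertia)
    chosen_by = "BOTH" if k_sil == k_elbow else "SILHOUETTE"
    km = fits[k_sil]
    return ClusterModel(
        n_clusters=k_sil,
        centroids=km.cluster_centers_,
        labels=km.labels_.astype(int),
        chosen_by=chosen_by,
        embedding=emb,
        inertia_by_k=inertia,
        silhouette_by_k=silhouette,
    )


def _stratified_pick(
    groups: dict[str, list[int]], n_select: int, rng: np.random.Generator
) -> list[int]:
    """Proportional sampling per group (largest-remainder rounding)."""
    total = sum(len(v) for v in groups.values())
    names = sorted(groups)
    quotas = {g: n_select * len(groups[g]) / total for g in names}
    base = {g: int(np.floor(quotas[g])) for g in names}
    short = n_select - sum(base.values())
    for g in sorted(names, key=lambda g: -(quotas[g] - base[g]))[:short]:
        base[g] += 1
    picked: list[int] = []
    for g in names:
        idx = np.asarray(groups[g])
        take = min(base[g], len(idx))
        picked.extend(rng.choice(idx, size=take, replace=False).tolist())
    return sorted(picked)


def injection_protocol(
    high_fidelity: Sequence[MoleculeRecord],
    large: Sequence[MoleculeRecord],
    fraction: float,
    strategy: str = "RANDOM",
    seed: int = 0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Inject a fraction of the high-fidelity set into the large set.

    Selection is stratified by fingerprint cluster (FINGERPRINT), by Murcko
    scaffold group (SCAFFOLD), or uniform (RANDOM); the augmented large set is
    the union with (inchikey, assay) dedup favouring existing large records.
    Returns (augmented_large, selected).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_select = round(fraction * len(high_fidelity))
    if n_select == 0:
        return list(large), []
    if strategy == "RANDOM":
        picked = sorted(
            rng.choice(len(high_fidelity), size=n_select, replace=False).tolist()
        )
    elif strategy in ("FINGERPRINT", "SCAFFOLD"):
        groups: dict[str, list[int]] = {}
        if strategy == "FINGERPRINT":
            k_hi = min(5, max(2, len(high_fidelity) // 10))
            if len(high_fidelity) > k_hi:
                model = cluster_high_fidelity(high_fidelity, range(2, k_hi + 1), seed)
                keys = [f"c{c}" for c in model.labels]
            else:
                keys = ["c0"] * len(high_fidelity)
        else:
            keys = [murcko_scaffold(r.smiles) or "__acyclic__" for r in high_fidelity]
        for i, key in enumerate(keys):
            groups.setdefault(key, []).append(i)
        picked = _stratified_pick(groups, n_select, rng)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    selected = [high_fidelity[i] for i in picked]
    existing = {(r.inchikey, r.assay.value) for r in large}
    augmented = list(large) + [
        r for r in selected if (r.inchikey, r.assay.value) not in existing
    ]
    return augmented, selected


def selection_overlap(
    selected_a: Sequence[MoleculeRecord], selected_b: Sequence[MoleculeRecord]
) -> float:
    """|A intersect B| / |A| by InChIKey (asymmetric; call twice for both)."""
    if not selected_a:
        raise ValueError("selected_a must be non-empty")
    keys_a = {r.inchikey for r in selected_a}
    keys_b = {r.inchikey for r in selected_b}
    return len(keys_a & keys_b) / len(keys_a)
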