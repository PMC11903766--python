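"""Pharmacophore condition graphs and gating conditions for the SMILES
generator.

At training time a molecule's pharmacophore graph is built from its 2D
feature set with topological (bond-count) shortest-path distances scaled to
Å; at inference the graph comes from a sampled 3D cloud with Euclidean
distances.  The gating condition is a fixed, ordered set of property
channels, each either open (value enforced) or closed (unconstrained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from ..clouds import CATEGORY_INDEX, PharmacophoreCloud
from ..features import extract_pharmacophores_2d

__all__ = [
    "BOND_LENGTH_SCALE",
    "GATE_CHANNELS",
    "PharmGraph",
    "GatingCondition",
    "mol_to_training_pair",
    "pharm_graph_from_cloud",
]

#: Å per bond: converts topological shortest-path distances to the metric
#: scale of the 3D clouds (mean single-bond length).
BOND_LENGTH_SCALE = 1.5

#: Fixed, ordered gating channels.
GATE_CHANNELS = ("MW", "LogP", "QED", "SAS", "RotBonds", "TPSA", "DockScore")

#: Per-channel normalization (offset, scale) so embedded values are O(1).
_CHANNEL_NORM = {
    "MW": (350.0, 150.0),
    "LogP": (2.5, 2.0),
    "QED": (0.5, 0.25),
    "SAS": (3.0, 1.5),
    "RotBonds": (5.0, 3.0),
    "TPSA": (70.0, 40.0),
    "DockScore": (-8.0, 4.0),
}


@dataclass
class PharmGraph:
    """Condition graph c_phar: feature-category nodes with pairwise
    distances (Å)."""

    node_categories: list[int]          # category indices, 1..max_phar nodes
    edge_dist: np.ndarray               # (n, n) symmetric, zero diagonal, Å
    source: str = "graph-topological"   # or "euclidean-3d"

    def __post_init__(self):
        self.edge_dist = np.asarray(self.edge_dist, dtype=np.float64)
        n = len(self.node_categories)
        if self.edge_dist.shape != (n, n):
            raise ValueError("edge_dist shape does not match node count")
        if n < 1:
            raise ValueError("PharmGraph needs at least one node")
        if not np.allclose(self.edge_dist, self.edge_dist.T):
            raise ValueError("edge_dist must be symmetric")
        if np.any(np.abs(np.diag(self.edge_dist)) > 1e-9):
            raise ValueError("edge_dist diagonal must be zero")
        if np.any(self.edge_dist < 0):
            raise ValueError("edge_dist must be nonnegative")

    def __len__(self) -> int:
        return len(self.node_categories)


@dataclass
class GatingCondition:
    """Property gates g(c_feat): open channels carry a target value, closed
    channels carry none."""

    gates: dict = field(default_factory=dict)  # channel -> float (open only)

    def __post_init__(self):
        for ch in self.gates:
            if ch not in GATE_CHANNELS:
                raise ValueError(
                    f"unknown gate channel {ch!r}; valid: {GATE_CHANNELS}")

    def is_open(self, channel: str) -> bool:
        return channel in self.gates

    def value(self, channel: str) -> float:
        return float(self.gates[channel])

    def normalized(self, channel: str) -> float:
        off, scale = _CHANNEL_NORM[channel]
        return (self.value(channel) - off) / scale

    @classmethod
    def closed(cls) -> "GatingCondition":
        return cls({})


def mol_to_training_pair(smiles: str, rng: np.random.Generator,
                         max_phar: int = 8, infill_rate: float = 0.5):
    """Build a (PharmGraph, mapping matrix) training condition from a
    molecule.

    A random subset of 2..max_phar of the molecule's 2D pharmacophore
    features becomes the condition graph (the noise-injection "infilling"
    scheme: the generator must complete molecules from partial hypotheses).
    Edge distances are topological shortest paths between feature anchors in
    bond counts, scaled by 1.5 Å/bond.  The mapping matrix (n_nodes,
    n_heavy_atoms + 1) one-hot-links each pharm node to its anchor atom
    (last column = unmapped).

    With infill_rate = 0 the subset is the full feature set (the first
    max_phar features in detection order) and no randomness is used.
    """
    cache = feature_cache(smiles)
    return pair_from_cache(cache, rng, max_phar=max_phar,
                           infill_rate=infill_rate)


def feature_cache(smiles: str):
    """Precompute (features, topological distance matrix, n_heavy) for a
    molecule — the per-molecule invariants reused across training epochs."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    feats = extract_pharmacophores_2d(mol)
    if len(feats) < 2:
        raise ValueError(
            f"molecule has {len(feats)} pharmacophore feature(s); need >= 2")
    dmat = Chem.GetDistanceMatrix(mol)  # topological, in bonds
    return feats, dmat, mol.GetNumAtoms()


def pair_from_cache(cache, rng: np.random.Generator, max_phar: int = 8,
                    infill_rate: float = 0.5):
    feats, dmat, n_heavy = cache
    n_avail = len(feats)
    if infill_rate > 0:
        n_take = int(rng.integers(2, min(n_avail, max_phar) + 1))
        chosen = sorted(rng.choice(n_avail, size=n_take, replace=False))
    else:
        chosen = list(range(min(n_avail, max_phar)))

    cats, anchors = [], []
    for i in chosen:
        family, atom_ids = feats[i]
        cats.append(CATEGORY_INDEX[family])
        anchors.append(list(atom_ids))
    n = len(chosen)
    edge = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # distance between feature centers: min over member-atom pairs
            d = min(dmat[a, b] for a in anchors[i] for b in anchors[j])
            edge[i, j] = edge[j, i] = d * BOND_LENGTH_SCALE
    mapping = np.zeros((n, n_heavy + 1))
    for i, atom_ids in enumerate(anchors):
        # anchor = first member atom (deterministic)
        mapping[i, atom_ids[0]] = 1.0
    graph = PharmGraph(cats, edge, source="graph-topological")
    return graph, mapping


def pharm_graph_from_cloud(cloud: PharmacophoreCloud,
                           max_phar: int = 8) -> PharmGraph:
    """Condition graph from a 3D cloud: Euclidean pairwise distances.

    Clouds larger than max_phar keep their max_phar highest-support points.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    order = np.argsort([-p.support for p in cloud.points])[:max_phar]
    order = np.sort(order)
    xyz = cloud.positions[order]
    cats = cloud.category_indices[order]
    diff = xyz[:, None, :] - xyz[None, :, :]
    edge = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(edge, 0.0)
    return PharmGraph(list(cats), edge, source="euclidean-3d")
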