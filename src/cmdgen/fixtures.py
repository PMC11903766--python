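"""Synthetic data generators: toy pocket–pharmacophore complexes with known
statistical structure, and a drug-like SMILES corpus built by template
enumeration.  Everything is a pure function of its spec/seed, so the whole
package can be trained and tested at desk scale with no downloads.

The toy pocket emulates the geometry a diffusion model must learn from real
complexes: protein atoms form a spherical shell (radius ~8 Å) with a cap
removed on one side — the pocket "mouth" — and the ligand pharmacophore
cloud sits displaced from the pocket center toward that opening.  The mouth
is what makes the displacement learnable: a rotation-equivariant network can
only infer the offset direction from an anisotropy of the pocket itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .clouds import CATEGORIES, N_CATEGORIES, PharmacophoreCloud, PocketCloud

__all__ = [
    "FixtureSpec",
    "make_complex_fixtures",
    "filter_displaced_pairs",
    "make_smiles_corpus",
    "write_fixture_pdb",
    "write_fixture_sdf",
]

#: Default category mix for fixture clouds: dominated by the four families
#: that drive most protein-ligand recognition.
_DEFAULT_MARGINALS = (0.15, 0.15, 0.05, 0.05, 0.25, 0.25, 0.05, 0.05)


@dataclass
class FixtureSpec:
    """Conditions under which toy pocket-ligand pairs are generated."""

    n_pairs: int = 200
    pocket_points: int = 32
    cloud_points: int = 5
    category_marginals: tuple = _DEFAULT_MARGINALS
    offset: tuple = (3.0, 0.0, 0.0)   # pocket-center -> cloud-centroid, Å
    spatial_sigma: float = 1.0        # Å, spread of cloud points
    pocket_radius: float = 8.0        # Å, shell radius
    mouth_halfwidth: float = 0.35     # cosine half-width of the removed cap
    corrupt_fraction: float = 0.0     # fraction of pairs with displaced clouds
    seed: int = 0

    def __post_init__(self):
        m = np.asarray(self.category_marginals, dtype=np.float64)
        if m.shape != (N_CATEGORIES,) or np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(
                "category_marginals must be 8 nonnegative values summing to 1")
        if self.n_pairs < 1 or self.cloud_points < 1 or self.pocket_points < 1:
            raise ValueError("n_pairs, pocket_points, cloud_points must be >= 1")


_ELEMENTS = ("C", "N", "O", "S")
_ELEMENT_WEIGHTS = (0.65, 0.15, 0.15, 0.05)


def make_complex_fixtures(spec: FixtureSpec) -> list[tuple[PocketCloud, PharmacophoreCloud]]:
    """Generate toy (PocketCloud, PharmacophoreCloud) pairs.

    Pocket points are drawn on a spherical shell around the origin with a cap
    removed in the offset direction; cloud points are i.i.d. Gaussian around
    origin + offset with categories drawn from the spec marginals.  With
    `corrupt_fraction > 0` the stated fraction of pairs has its cloud pushed
    > 2 Å off the nominal centroid (emulating bad complex conformations that
    a quality filter should drop; see :func:`filter_displaced_pairs`).
    """
    rng = np.random.default_rng(spec.seed)
    offset = np.asarray(spec.offset, dtype=np.float64)
    u = offset / np.linalg.norm(offset) if np.linalg.norm(offset) > 0 \
        else np.array([1.0, 0.0, 0.0])
    pairs = []
    n_corrupt = int(round(spec.corrupt_fraction * spec.n_pairs))
    for i in range(spec.n_pairs):
        # shell points, rejecting the cap around the mouth direction
        pts = []
        while len(pts) < spec.pocket_points:
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            if v @ u > 1.0 - spec.mouth_halfwidth:
                continue  # inside the mouth cap
            r = spec.pocket_radius * (1.0 + 0.05 * rng.standard_normal())
            pts.append(r * v)
        elements = rng.choice(_ELEMENTS, size=spec.pocket_points,
                              p=_ELEMENT_WEIGHTS)
        pocket = PocketCloud(
            positions=np.asarray(pts), features=list(elements),
            mode="full_atom", center=np.zeros(3), radius=spec.pocket_radius,
            alphabet=list(_ELEMENTS),
        )
        centroid = offset.copy()
        if i < n_corrupt:
            # displaced cloud: centroid pushed 2.5-4 Å off the nominal spot
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            centroid = centroid + direction * rng.uniform(2.5, 4.0)
        xyz = centroid + spec.spatial_sigma * rng.standard_normal(
            (spec.cloud_points, 3))
        cats = rng.choice(N_CATEGORIES, size=spec.cloud_points,
                          p=np.asarray(spec.category_marginals))
        cloud = PharmacophoreCloud.from_arrays(xyz, cats,
                                               provenance="ligand-derived")
        pairs.append((pocket, cloud))
    return pairs


def filter_displaced_pairs(pairs, offset, max_deviation: float = 2.0):
    """Quality screen: drop pairs whose cloud centroid deviates more than
    `max_deviation` Å (default 2) from the nominal offset relative to the
    pocket's stated center."""
    offset = np.asarray(offset, dtype=np.float64)
    kept = []
    for pocket, cloud in pairs:
        if np.linalg.norm(cloud.centroid() - pocket.center - offset) \
                <= max_deviation:
            kept.append((pocket, cloud))
    return kept


# -- SMILES corpus ------------------------------------------------------------

# scaffold x linker x substituent templates; {} slots are filled left to right
_SCAFFOLDS = (
    "c1ccc({A})cc1",              # benzene
    "c1ccc({A})nc1",              # pyridine
    "c1cc({A})ccc1O",             # phenol
    "c1cc({A})ccc1N",             # aniline
    "c1cc({A})ccc1C(N)=O",        # benzamide
    "c1cc({A})ccc1S(N)(=O)=O",    # benzenesulfonamide
    "c1cc({A})ccc1C(=O)O",        # benzoic acid
    "c1ccc2[nH]c({A})cc2c1",      # indole
)
_LINKERS = (
    "C(=O)N{B}", "CC(=O)N{B}", "NC(=O){B}", "C(=O)O{B}", "OC{B}",
    "NC{B}", "C{B}", "CC{B}", "CCC{B}", "N(C)C(=O){B}", "CNC(=O){B}",
    "OCC{B}", "SCC{B}", "C(=O)NC{B}",
)
_CAPS = (
    # ring digits 8/9 avoid clashing with open scaffold ring closures
    "C", "CC", "CCC", "C(C)C", "CCO", "CCN", "CCN(C)C", "C8CCCCC8",
    "C8CCNCC8", "CCc8ccccc8", "Cc8ccccc8", "CCOCC",
    "c8ccccc8", "c8ccncc8", "CC(C)O", "CCCN", "C8CCOC8", "CCNC",
    "CC(=O)N", "CCS",
)


def make_smiles_corpus(n: int, seed: int = 0) -> list[str]:
    """Enumerate up to `n` valid, unique, feature-rich drug-like SMILES from
    scaffold x linker x cap templates (MW kept under 800 by construction).
    Deterministic: the enumeration order is a seeded permutation of the
    template grid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    combos = [(s, l, c) for s in _SCAFFOLDS for l in _LINKERS for c in _CAPS]
    cap = len(combos)
    if n > cap:
        raise ValueError(f"corpus cap is {cap} molecules ({n} requested)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    out: list[str] = []
    seen: set[str] = set()
    for idx in order:
        scaffold, linker, capg = combos[idx]
        smi = scaffold.format(A=linker.format(B=capg))
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
        if len(out) == n:
            return out
    raise ValueError(f"could only enumerate {len(out)} unique molecules")


# -- flat-file fixtures -------------------------------------------------------

_POCKET_RES = {"C": "ALA", "N": "ALA", "O": "ALA", "S": "CYS"}


def write_fixture_pdb(pocket: PocketCloud, path) -> None:
    """Write a pocket cloud as a minimal standards-conformant PDB (one
    pseudo-residue per point so both extraction modes can re-read it)."""
    lines = []
    for i, (pos, feat) in enumerate(zip(pocket.positions, pocket.features), 1):
        element = feat if pocket.mode == "full_atom" else "C"
        name = "CA" if pocket.mode == "calpha" else element
        res = _POCKET_RES.get(element, "ALA") if pocket.mode == "full_atom" \
            else (feat if len(feat) == 3 else "ALA")
        lines.append(
            f"ATOM  {i:5d} {name:^4s} {res:3s} A{i:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture_sdf(mol: Chem.Mol, path) -> None:
    """Write a molecule (with conformers if present) as SDF."""
    writer = Chem.SDWriter(str(path))
    try:
        if mol.GetNumConformers() == 0:
            mol = Chem.Mol(mol)
            AllChem.Compute2DCoords(mol)
        writer.write(mol)
    finally:
        writer.close()
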