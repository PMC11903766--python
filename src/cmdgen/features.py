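"""Pharmacophore extraction from 3D ligands and pocket-cloud extraction
from protein structures.

Ligand features come from the RDKit chemical-feature factory (BaseFeatures
definitions).  Each detected feature instance becomes one cloud point at the
unweighted centroid of its member atoms; RDKit families outside the seven
named classes map to ``Other``.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import ChemicalFeatures

from .clouds import FeatureCategory, PharmacophoreCloud, PharmacophorePoint, PocketCloud

__all__ = [
    "extract_ligand_pharmacophores",
    "extract_pharmacophores_2d",
    "extract_pocket_cloud",
    "load_ligand",
]

_FAMILY_MAP = {
    "Aromatic": "Aromatic",
    "Hydrophobe": "Hydrophobic",
    "PosIonizable": "PosIonizable",
    "NegIonizable": "NegIonizable",
    "Acceptor": "Acceptor",
    "Donor": "Donor",
    "LumpedHydrophobe": "LumpedHydrophobe",
}

_factory = None


def _feature_factory():
    global _factory
    if _factory is None:
        fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        _factory = ChemicalFeatures.BuildFeatureFactory(fdef)
    return _factory


def load_ligand(path) -> Chem.Mol:
    """Load the first molecule from an SDF/MOL file, sanitized, with H kept
    implicit."""
    path = str(path)
    if path.endswith(".mol"):
        mol = Chem.MolFromMolFile(path, removeHs=True)
    else:
        supplier = Chem.SDMolSupplier(path, removeHs=True)
        mol = next(iter(supplier), None)
    if mol is None:
        raise ValueError(f"could not parse a molecule from {path}")
    return mol


def _detect_features(mol: Chem.Mol) -> list[tuple[str, tuple[int, ...]]]:
    feats = _feature_factory().GetFeaturesForMol(mol)
    out = []
    for f in feats:
        family = _FAMILY_MAP.get(f.GetFamily(), "Other")
        out.append((family, tuple(f.GetAtomIds())))
    return out


def extract_ligand_pharmacophores(mol: Chem.Mol) -> PharmacophoreCloud:
    """Reduce a 3D ligand to its pharmacophore point cloud.

    Each detected feature becomes one point at the centroid of its member
    atoms.  Deterministic for a fixed conformer.
    """
    if mol is None:
        raise ValueError("cannot extract pharmacophores from an unparsed molecule")
    if mol.GetNumConformers() < 1:
        raise ValueError("molecule has no 3D conformer")
    conf = mol.GetConformer()
    coords = conf.GetPositions()
    points = []
    for family, atom_ids in _detect_features(mol):
        pos = coords[list(atom_ids)].mean(axis=0)
        points.append(
            PharmacophorePoint(pos, FeatureCategory(family), support=len(atom_ids))
        )
    if not points:
        raise ValueError("no pharmacophore features detected (empty cloud)")
    return PharmacophoreCloud(points, provenance="ligand-derived")


def extract_pharmacophores_2d(mol: Chem.Mol) -> list[tuple[str, tuple[int, ...]]]:
    """Topological (conformer-free) feature detection: list of
    (category, member atom ids).  Used by the SMILES-generator training path
    where only graph distances are needed."""
    if mol is None:
        raise ValueError("cannot extract pharmacophores from an unparsed molecule")
    return _detect_features(mol)


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def extract_pocket_cloud(structure, center, radius: float = 10.0,
                         mode: str = "full_atom") -> PocketCloud:
    """Extract a pocket point cloud around `center` from a protein structure.

    Parameters
    ----------
    structure : gemmi.Structure or path to a PDB file.
    center : (3,) Å.
    radius : selection radius in Å; a residue is retained if any heavy atom
        (full_atom) / its Cα (calpha) lies within radius of center.
    mode : "full_atom" (heavy atoms, element features) or "calpha"
        (one Cα point per residue, residue-name features).
    """
    if isinstance(structure, (str, Path)):
        structure = gemmi.read_structure(str(structure))
    center = np.asarray(center, dtype=np.float64).reshape(3)
    model = structure[0]
    positions: list[np.ndarray] = []
    feats: list[str] = []
    for chain in model:
        for residue in chain:
            if residue.name in _WATER_NAMES:
                continue
            if mode == "calpha":
                ca = residue.find_atom("CA", "*")
                if ca is None:
                    continue
                pos = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
                if np.linalg.norm(pos - center) <= radius:
                    positions.append(pos)
                    feats.append(residue.name)
            else:
                for atom in residue:
                    if atom.element.name == "H" or atom.element.name == "D":
                        continue
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if np.linalg.norm(pos - center) <= radius:
                        positions.append(pos)
                        feats.append(atom.element.name)
    if not positions:
        raise ValueError(
            f"no pocket points within {radius:.2f} Å of "
            f"({center[0]:.2f}, {center[1]:.2f}, {center[2]:.2f})"
        )
    return PocketCloud(
        positions=np.stack(positions), features=feats, mode=mode,
        center=center, radius=float(radius),
    )
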