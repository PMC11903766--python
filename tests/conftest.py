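"""Shared fixtures: tiny synthetic inputs generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from cmdgen.clouds import PharmacophoreCloud
from cmdgen.fixtures import FixtureSpec, make_complex_fixtures, make_smiles_corpus


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def embedded_mol(smiles: str, seed: int = 7) -> Chem.Mol:
    """Molecule with one minimized 3D conformer (hydrogens removed)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    AllChem.MMFFOptimizeMolecule(mol)
    return Chem.RemoveHs(mol)


def random_cloud(rng: np.random.Generator, n: int = 5,
                 scale: float = 5.0) -> PharmacophoreCloud:
    return PharmacophoreCloud.from_arrays(
        rng.standard_normal((n, 3)) * scale,
        rng.integers(0, 8, size=n),
    )


@pytest.fixture(scope="session")
def toy_pairs():
    """16 toy pocket/cloud complexes (shared, read-only)."""
    return make_complex_fixtures(FixtureSpec(n_pairs=16, seed=11))


@pytest.fixture(scope="session")
def small_corpus():
    return make_smiles_corpus(120, seed=5)


@pytest.fixture(scope="session")
def benzene_3d():
    return embedded_mol("c1ccccc1")


@pytest.fixture(scope="session")
def phenol_3d():
    return embedded_mol("Oc1ccccc1")
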