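"""Conformer embedding and pharmacophore-alignment posing."""

from itertools import permutations

import numpy as np
import pytest
from rdkit import Chem

from cmdgen.align import align_to_cloud, apply_pose, embed_conformers, pose_rmsd
from cmdgen.clouds import PharmacophoreCloud, PharmacophorePoint, FeatureCategory
from cmdgen.clustering import kabsch
from cmdgen.features import extract_ligand_pharmacophores


def test_ethane_bond_length_physical():
    mol = embed_conformers("CC", n_conf=1, seed=1)
    xyz = mol.GetConformer().GetPositions()
    assert 1.45 <= np.linalg.norm(xyz[0] - xyz[1]) <= 1.60


def test_requested_conformer_count():
    mol = embed_conformers("CCO", n_conf=5, seed=2)
    assert mol.GetNumConformers() == 5


def test_embedding_is_seed_deterministic():
    a = embed_conformers("CC(=O)Nc1ccc(O)cc1", n_conf=3, seed=5)
    b = embed_conformers("CC(=O)Nc1ccc(O)cc1", n_conf=3, seed=5)
    for ca, cb in zip(a.GetConformers(), b.GetConformers()):
        assert np.abs(ca.GetPositions() - cb.GetPositions()).max() < 1e-6


def test_invalid_smiles_rejected():
    with pytest.raises(ValueError, match="invalid"):
        embed_conformers("xx((", 1, 0)


@pytest.fixture(scope="module")
def posed_molecule():
    mol = embed_conformers("CC(=O)Nc1ccc(O)cc1", n_conf=1, seed=3)
    cloud = extract_ligand_pharmacophores(mol)
    return mol, cloud


def test_self_alignment_identity(posed_molecule):
    mol, cloud = posed_molecule
    poses = align_to_cloud(mol, cloud, tolerance=0, fit_cutoff=1.5)
    assert poses
    top = poses[0]
    assert top.fit_rmsd < 1e-6
    assert top.n_unmatched == 0
    assert np.abs(top.transform.rotation - np.eye(3)).max() < 1e-5
    assert np.abs(top.transform.translation).max() < 1e-5


def test_extra_point_needs_tolerance(posed_molecule):
    mol, cloud = posed_molecule
    extra = PharmacophorePoint(cloud.positions.mean(axis=0) + [10, 0, 0],
                               FeatureCategory("Donor"))
    bigger = PharmacophoreCloud(cloud.points + [extra], cloud.provenance)
    strict = align_to_cloud(mol, bigger, tolerance=0, fit_cutoff=1.5)
    assert strict == []
    relaxed = align_to_cloud(mol, bigger, tolerance=1, fit_cutoff=1.5)
    assert relaxed
    assert relaxed[0].fit_rmsd < 1e-6
    assert relaxed[0].n_unmatched == 1


def test_tolerance_monotonicity(posed_molecule):
    mol, cloud = posed_molecule
    counts = [len(align_to_cloud(mol, cloud, tolerance=t, fit_cutoff=2.0))
              for t in (0, 1, 2)]
    assert counts[0] <= counts[1] <= counts[2]


def test_accepted_poses_match_bruteforce_enumeration():
    """<= 4-point cloud vs a small molecule: the branch-and-bound search
    finds exactly the assignments an exhaustive permutation scan accepts."""
    rng = np.random.default_rng(4)
    mol = embed_conformers("NCCO", n_conf=2, seed=6)
    tolerance, cutoff = 1, 1.0
    cloud_xyz = rng.uniform(-3, 3, (4, 3))
    feats0 = extract_ligand_pharmacophores(
        Chem.Mol(mol, confId=mol.GetConformers()[0].GetId()))
    cats_pool = feats0.categories + ["Aromatic"]
    cloud = PharmacophoreCloud.from_arrays(
        cloud_xyz, [cats_pool[i % len(cats_pool)] for i in range(4)])

    got = align_to_cloud(mol, cloud, tolerance, cutoff)
    got_keys = {(p.conformer_id, tuple(sorted(p.matched_pairs))) for p in got}

    expected_keys = set()
    cloud_cats = cloud.category_indices
    for conf in mol.GetConformers():
        sub = Chem.Mol(mol, confId=conf.GetId())
        fc = extract_ligand_pharmacophores(sub)
        fxyz, fcats = fc.positions, fc.category_indices
        n_mol = len(fcats)
        idxs = list(range(n_mol)) + [None] * 4
        for perm in set(permutations(idxs, 4)):
            chosen = [p for p in perm if p is not None]
            if len(chosen) != len(set(chosen)):
                continue
            unmatched = 4 - len(chosen)
            if unmatched > tolerance or not chosen:
                continue
            if any(perm[i] is not None and fcats[perm[i]] != cloud_cats[i]
                   for i in range(4)):
                continue
            pairs = [(i, perm[i]) for i in range(4) if perm[i] is not None]
            a = np.array([fxyz[m] for _, m in pairs])
            b = np.array([cloud.positions[i] for i, _ in pairs])
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tf = kabsch(a, b) if len(pairs) > 1 else None
            rmsd = tf.rmsd if tf else 0.0
            if rmsd <= cutoff:
                expected_keys.add((conf.GetId(), tuple(sorted(pairs))))
    assert got_keys == expected_keys


def test_pose_rescoring_reproduces_fit_rmsd(posed_molecule):
    mol, cloud = posed_molecule
    poses = align_to_cloud(mol, cloud, tolerance=1, fit_cutoff=1.5)
    for p in poses[:5]:
        sub = Chem.Mol(mol, confId=p.conformer_id)
        fc = extract_ligand_pharmacophores(sub)
        a = np.array([fc.positions[m] for _, m in p.matched_pairs])
        b = np.array([cloud.positions[i] for i, _ in p.matched_pairs])
        moved = p.transform.apply(a)
        rmsd = np.sqrt(((moved - b) ** 2).sum() / len(a))
        assert rmsd == pytest.approx(p.fit_rmsd, abs=1e-9)


def test_multiple_poses_possible(posed_molecule):
    """The overlay can return more than one acceptable pose for a single
    molecule."""
    mol, cloud = posed_molecule
    poses = align_to_cloud(mol, cloud, tolerance=2, fit_cutoff=2.0)
    assert len(poses) > 1


# -- pose RMSD ----------------------------------------------------------------

def test_identical_poses_zero_rmsd():
    mol = embed_conformers("CCO", 1, seed=7)
    assert pose_rmsd(mol, mol) == pytest.approx(0.0, abs=1e-12)


def test_benzene_60_degree_rotation_is_symmetry_equivalent():
    mol = embed_conformers("c1ccccc1", 1, seed=8)
    rot = Chem.Mol(mol)
    conf = rot.GetConformer()
    xyz = conf.GetPositions()
    center = xyz.mean(axis=0)
    # rotate 60 degrees about the ring normal
    centered = xyz - center
    u, _, _ = np.linalg.svd(centered.T @ centered)
    normal = u[:, 2]
    from scipy.spatial.transform import Rotation
    r = Rotation.from_rotvec(normal * np.pi / 3).as_matrix()
    for i, p in enumerate(centered @ r.T + center):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
    assert pose_rmsd(mol, rot) < 0.05


def test_random_perturbation_matches_direct_formula():
    rng = np.random.default_rng(9)
    mol = embed_conformers("NCCO", 1, seed=10)  # no symmetry
    pert = Chem.Mol(mol)
    conf = pert.GetConformer()
    xyz = conf.GetPositions()
    noise = rng.normal(0, 0.1, xyz.shape)  # small: keeps identity mapping best
    for i, p in enumerate(xyz + noise):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
    expected = np.sqrt((noise**2).sum() / len(xyz))
    assert pose_rmsd(mol, pert) == pytest.approx(expected, abs=1e-9)


def test_topology_mismatch_rejected():
    a = embed_conformers("CCO", 1, 0)
    b = embed_conformers("CCN", 1, 0)
    with pytest.raises(ValueError, match="topology"):
        pose_rmsd(a, b)


def test_apply_pose_moves_conformer(posed_molecule):
    mol, cloud = posed_molecule
    shifted_cloud = cloud.translated(np.array([5.0, 0.0, 0.0]))
    poses = align_to_cloud(mol, shifted_cloud, tolerance=0, fit_cutoff=1.5)
    assert poses
    posed = apply_pose(mol, poses[0])
    delta = posed.GetConformer().GetPositions() - \
        mol.GetConformer().GetPositions()
    assert np.allclose(delta, [5.0, 0.0, 0.0], atol=1e-6)
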