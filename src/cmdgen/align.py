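"""Binding-pose generation by rigid pharmacophore alignment.

Generated molecules are embedded as 3D conformers (distance geometry +
force-field minimization), their pharmacophore features extracted, and each
conformer rigidly posed onto a sampled pharmacophore cloud: an exact search
over injective, category-consistent assignments of cloud points to molecular
features (allowing up to `tolerance` cloud points to go unmatched) followed
by a Kabsch fit on the matched centroids.  Conformers stay rigid — the
overlay does not refit torsions — so one molecule can yield several
plausible poses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .clouds import PharmacophoreCloud
from .clustering import RigidTransform, kabsch
from .features import extract_ligand_pharmacophores

__all__ = ["PoseResult", "embed_conformers", "align_to_cloud", "pose_rmsd"]

#: assignment-search size guard: clouds above this size would make the exact
#: enumeration explode
_MAX_CLOUD_FOR_SEARCH = 12


@dataclass
class PoseResult:
    """One accepted pose of one conformer on a pharmacophore cloud."""

    conformer_id: int
    transform: RigidTransform
    matched_pairs: list[tuple[int, int]]   # (cloud point idx, mol feature idx)
    n_unmatched: int                       # cloud points without a partner
    fit_rmsd: float                        # Å over matched pharmacophore pairs


def embed_conformers(smiles: str, n_conf: int = 10, seed: int = 0) -> Chem.Mol:
    """Distance-geometry embedding (ETKDGv3) + MMFF minimization.

    Returns a molecule with exactly n_conf conformers (explicit hydrogens
    removed afterwards).  Deterministic given seed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_conf, params=params)
    if len(conf_ids) < n_conf:
        raise ValueError(
            f"conformer embedding failed for {smiles!r} "
            f"({len(conf_ids)}/{n_conf} embedded)")
    AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
    return Chem.RemoveHs(molh)


def align_to_cloud(mol: Chem.Mol, cloud: PharmacophoreCloud,
                   tolerance: int = 1, fit_cutoff: float = 1.5
                   ) -> list[PoseResult]:
    """Pose every conformer of `mol` onto `cloud`.

    For each conformer, all injective category-consistent assignments of
    cloud points to the conformer's pharmacophore features are enumerated,
    allowing up to `tolerance` cloud points to stay unmatched (surplus
    molecule features are free).  Each assignment with >= 3 matched pairs
    (or all cloud points when the cloud is smaller) is scored by a Kabsch
    fit; poses with fit_rmsd <= fit_cutoff are returned sorted by
    (n_unmatched, fit_rmsd).  An empty list means no acceptable pose.
    """
    if len(cloud) == 0:
        raise ValueError("empty pharmacophore cloud")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if len(cloud) > _MAX_CLOUD_FOR_SEARCH:
        raise ValueError(
            f"cloud has {len(cloud)} points; the exact assignment search is "
            f"capped at {_MAX_CLOUD_FOR_SEARCH} — cluster the cloud or raise "
            "the cap")
    n_cloud = len(cloud)
    cloud_xyz = cloud.positions
    cloud_cats = cloud.category_indices
    poses: list[PoseResult] = []
    for conf in mol.GetConformers():
        sub = Chem.Mol(mol, confId=conf.GetId())
        try:
            feat_cloud = extract_ligand_pharmacophores(sub)
        except ValueError:
            continue
        feat_xyz = feat_cloud.positions
        feat_cats = feat_cloud.category_indices
        candidates = [
            [m for m in range(len(feat_cats)) if feat_cats[m] == cloud_cats[i]]
            for i in range(n_cloud)
        ]
        seen_assignments = set()

        def search(i, used, pairs, unmatched):
            if unmatched > tolerance:
                return
            if i == n_cloud:
                if pairs:
                    key = tuple(sorted(pairs))
                    if key not in seen_assignments:
                        seen_assignments.add(key)
                        _score_assignment(pairs, unmatched)
                return
            for m in candidates[i]:
                if m not in used:
                    search(i + 1, used | {m}, pairs + [(i, m)], unmatched)
            search(i + 1, used, pairs, unmatched + 1)

        def _score_assignment(pairs, unmatched):
            a = np.array([feat_xyz[m] for _, m in pairs])
            b = np.array([cloud_xyz[i] for i, _ in pairs])
            if len(pairs) == 1:
                # pure translation
                t = b[0] - a[0]
                tf = RigidTransform(np.eye(3), t, 0.0)
            else:
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tf = kabsch(a, b)
            if tf.rmsd <= fit_cutoff:
                poses.append(PoseResult(
                    conformer_id=conf.GetId(), transform=tf,
                    matched_pairs=[(i, m) for i, m in pairs],
                    n_unmatched=unmatched, fit_rmsd=tf.rmsd))

        search(0, frozenset(), [], 0)
    poses.sort(key=lambda p: (p.n_unmatched, p.fit_rmsd))
    return poses


def apply_pose(mol: Chem.Mol, pose: PoseResult) -> Chem.Mol:
    """Return a single-conformer copy of `mol` with the pose transform
    applied to the heavy-atom coordinates."""
    out = Chem.Mol(mol, confId=pose.conformer_id)
    conf = out.GetConformer()
    xyz = conf.GetPositions()
    new = pose.transform.apply(xyz)
    for i, p in enumerate(new):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
    return out


def pose_rmsd(mol_a: Chem.Mol, mol_b: Chem.Mol,
              max_automorphisms: int = 10_000) -> float:
    """In-place heavy-atom RMSD between two poses of the same molecule,
    minimized over graph automorphisms (no re-fitting)."""
    if Chem.MolToSmiles(Chem.RemoveHs(mol_a)) != Chem.MolToSmiles(
            Chem.RemoveHs(mol_b)):
        raise ValueError("pose_rmsd requires identical molecular topology")
    a = Chem.RemoveHs(mol_a)
    b = Chem.RemoveHs(mol_b)
    xa = a.GetConformer().GetPositions()
    xb = b.GetConformer().GetPositions()
    matches = a.GetSubstructMatches(b, uniquify=False,
                                    maxMatches=max_automorphisms)
    if not matches:
        raise ValueError("molecules do not share a substructure mapping")
    best = np.inf
    for perm in matches:
        d = xa[list(perm)] - xb
        best = min(best, float(np.sqrt((d**2).sum() / len(xb))))
    return best
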