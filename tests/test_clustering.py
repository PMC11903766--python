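"""Consensus clustering, Kabsch registration, selective differencing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cmdgen.clouds import CATEGORIES, PharmacophoreCloud
from cmdgen.clustering import (
    cluster_clouds,
    consensus_category,
    kabsch,
    register_clouds,
    selective_features,
)
from tests.conftest import random_cloud, random_rotation


def _cloud(xyz, cats):
    return PharmacophoreCloud.from_arrays(np.asarray(xyz, float), cats)


# -- consensus clustering -----------------------------------------------------

def test_two_unanimous_blobs():
    rng = np.random.default_rng(0)
    blob1 = rng.normal([0, 0, 0], 0.3, (12, 3))
    blob2 = rng.normal([20, 0, 0], 0.3, (12, 3))
    cloud = _cloud(np.vstack([blob1, blob2]),
                   ["Acceptor"] * 12 + ["Donor"] * 12)
    model, consensus = cluster_clouds([cloud], k=2, seed=0)
    cats = dict(zip(
        np.round(consensus.positions[:, 0], 0), consensus.categories))
    assert set(consensus.categories) == {"Acceptor", "Donor"}
    by_x = sorted(zip(consensus.positions[:, 0], consensus.categories))
    assert by_x[0][1] == "Acceptor" and by_x[1][1] == "Donor"
    assert abs(by_x[0][0]) < 0.5 and abs(by_x[1][0] - 20) < 0.5
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_majority_vote_with_minority():
    """Cluster with counts {Aromatic: 3, Donor: 1} -> Aromatic (brute-force
    evaluation of the consensus rule with indicator P(f|sample))."""
    labels = np.array([0, 0, 0, 5])  # 3x Aromatic, 1x Donor
    global_freq = np.bincount(labels, minlength=8) / 4
    # independent oracle: enumerate all 8 categories, count indicator sums
    sums = [(labels == f).sum() for f in range(8)]
    oracle = int(np.argmax(sums))
    assert consensus_category(labels, global_freq) == oracle == 0


def test_consensus_matches_exhaustive_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(1, 12))
        labels = rng.integers(0, 8, size=n)
        gf = rng.dirichlet(np.ones(8))
        got = consensus_category(labels, gf)
        # oracle: maximize (count, global freq, -index) explicitly
        best = max(range(8),
                   key=lambda f: ((labels == f).sum(), gf[f], -f))
        assert got == best


def test_tie_broken_by_global_frequency():
    labels = np.array([0, 5])  # 1 Aromatic, 1 Donor
    gf = np.zeros(8)
    gf[5] = 0.9
    gf[0] = 0.1
    assert consensus_category(labels, gf) == 5


def test_auto_k_selects_three_blobs():
    rng = np.random.default_rng(1)
    centers = np.array([[0, 0, 0], [15, 0, 0], [0, 15, 0]], float)
    xyz = np.vstack([rng.normal(c, 0.3, (10, 3)) for c in centers])
    cloud = _cloud(xyz, ["Donor"] * 30)
    model, consensus = cluster_clouds([cloud], k="auto", seed=0)
    assert model.k == 3
    assert len(consensus) == 3


def test_k_larger_than_points_rejected():
    cloud = random_cloud(np.random.default_rng(0), n=4)
    with pytest.raises(ValueError, match="k="):
        cluster_clouds([cloud], k=9, seed=0)


def test_consensus_supports_sum_to_pooled_points():
    rng = np.random.default_rng(2)
    clouds = [random_cloud(rng, n=6) for _ in range(4)]
    model, consensus = cluster_clouds(clouds, k=3, seed=0)
    assert sum(p.support for p in consensus.points) == 24
    assert len(model.assignments) == 24


# -- Kabsch ------------------------------------------------------------------

def test_kabsch_identity_on_self():
    rng = np.random.default_rng(3)
    a = rng.standard_normal((8, 3)) * 5
    tf = kabsch(a, a)
    assert np.abs(tf.rotation - np.eye(3)).max() < 1e-9
    assert np.abs(tf.translation).max() < 1e-9
    assert tf.rmsd < 1e-9


def test_kabsch_recovers_random_rigid_motion():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = rng.standard_normal((10, 3)) * 4
        r = random_rotation(rng)
        v = rng.standard_normal(3) * 10
        tf = kabsch(a, a @ r.T + v)
        assert np.abs(tf.rotation - r).max() < 1e-6
        assert tf.rmsd < 1e-6
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(tf.rotation @ tf.rotation.T - np.eye(3)).max() < 1e-9


def test_kabsch_agrees_with_scipy_oracle():
    """Noisy pairs: RMSD matches scipy's independent SVD-based solver."""
    rng = np.random.default_rng(5)
    a = rng.standard_normal((10, 3)) * 3
    r = random_rotation(rng)
    b = a @ r.T + np.array([1.0, 2.0, 3.0]) + rng.normal(0, 0.2, (10, 3))
    tf = kabsch(a, b)
    rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
    scipy_rmsd = rssd / np.sqrt(len(a))
    assert tf.rmsd == pytest.approx(scipy_rmsd, abs=1e-9)
    assert np.abs(tf.rotation - rot.as_matrix()).max() < 1e-9


def test_kabsch_warns_on_collinear_points():
    a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
    with pytest.warns(UserWarning, match="degenerate"):
        tf = kabsch(a, a)
    assert tf.rmsd < 1e-9


def test_registration_rmsd_invariant_under_common_motion():
    rng = np.random.default_rng(6)
    a = random_cloud(rng, n=10)
    b = random_cloud(rng, n=12)
    base = register_clouds(a, b, "nearest-neighbor").rmsd
    r = random_rotation(rng)
    v = rng.standard_normal(3) * 7
    a2 = a.transformed(r, v)
    b2 = b.transformed(r, v)
    moved = register_clouds(a2, b2, "nearest-neighbor").rmsd
    assert abs(base - moved) < 1e-9


def test_registration_paired_mode_size_check():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError, match="equal"):
        register_clouds(random_cloud(rng, 4), random_cloud(rng, 5), "paired")


def test_icp_recovers_moderate_rigid_motion():
    rng = np.random.default_rng(8)
    a = random_cloud(rng, n=15, scale=6.0)
    r = Rotation.from_euler("z", 15, degrees=True).as_matrix()
    b = a.transformed(r, np.array([1.0, -0.5, 0.5]))
    tf = register_clouds(a, b, "nearest-neighbor")
    assert tf.rmsd < 1e-6


# -- selective differencing ---------------------------------------------------

def test_identical_clouds_give_empty_selective_cloud():
    rng = np.random.default_rng(9)
    cloud = random_cloud(rng, n=10)
    for delta in (0.5, 1.0, 2.0, 3.0):
        with pytest.warns(UserWarning, match="indistinguishable"):
            sel = selective_features(cloud, cloud, None, delta=delta,
                                     dbscan_min=1)
        assert len(sel) == 0


def test_planted_extra_point_survives():
    rng = np.random.default_rng(10)
    base = random_cloud(rng, n=8)
    extra = np.array([[50.0, 50.0, 50.0]])
    target = PharmacophoreCloud.from_arrays(
        np.vstack([base.positions, extra]),
        base.categories + ["Hydrophobic"])
    sel = selective_features(target, base, None, delta=2.0, dbscan_min=1)
    assert len(sel) == 1
    assert sel.categories == ["Hydrophobic"]
    assert np.linalg.norm(sel.positions[0] - extra[0]) < 1e-9


def test_selective_monotone_in_delta():
    rng = np.random.default_rng(11)
    target = random_cloud(rng, n=30, scale=8.0)
    homolog = random_cloud(rng, n=30, scale=8.0)
    counts = []
    for delta in (0.5, 1.0, 2.0, 4.0, 8.0):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = selective_features(target, homolog, None, delta=delta,
                                     dbscan_min=1)
        counts.append(sum(p.support for p in sel.points))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_two_survivor_groups_match_majority_oracle():
    """20 survivors in two tight groups cluster into two consensus points
    whose categories equal the per-group majority (brute-force count)."""
    rng = np.random.default_rng(12)
    g1 = rng.normal([30, 0, 0], 0.3, (10, 3))
    g2 = rng.normal([0, 30, 0], 0.3, (10, 3))
    cats1 = ["Donor"] * 7 + ["Acceptor"] * 3
    cats2 = ["Aromatic"] * 6 + ["Hydrophobic"] * 4
    target = PharmacophoreCloud.from_arrays(np.vstack([g1, g2]), cats1 + cats2)
    homolog = PharmacophoreCloud.from_arrays(np.zeros((1, 3)), ["Other"])
    sel = selective_features(target, homolog, None, delta=2.0,
                             dbscan_eps=1.5, dbscan_min=3)
    assert len(sel) == 2
    got = dict(zip(np.round(sel.positions[:, 0]), sel.categories))
    by_x = sorted(zip(sel.positions[:, 0], sel.categories))
    assert by_x[0][1] == "Aromatic"   # the group near x=0
    assert by_x[1][1] == "Donor"      # the group near x=30
    assert sorted(p.support for p in sel.points) == [10, 10]


def test_dual_target_composition_shared_features(toy_pairs):
    """Register-then-cluster on two copies of a cloud: shared features show
    up as high-support consensus clusters."""
    cloud = toy_pairs[0][1]
    tf = register_clouds(cloud, cloud, "nearest-neighbor")
    model, consensus = cluster_clouds([cloud, cloud], k=len(cloud), seed=0)
    assert sum(p.support for p in consensus.points) == 2 * len(cloud)
    assert max(p.support for p in consensus.points) >= 2
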