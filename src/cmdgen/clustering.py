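"""Space-and-feature consensus clustering of sampled pharmacophore clouds,
rigid point-cloud registration, and selective-feature differencing.

Repeated diffusion samples for one pocket are pooled and clustered with a
Gaussian mixture on 3D coordinates; each cluster is then assigned the most
probable pharmacophoric category,

    category(C_i) = argmax_f  sum_{sample in C_i} P(f | sample),

where P(f | sample) is the indicator of the sample's hard label, so the rule
reduces to a per-cluster majority vote; ties are broken by the global
category frequency P(f) over the pooled cloud (and then by the pinned
category order, so the result is deterministic).

Registration of two clouds uses the Kabsch least-squares rigid superposition,
optionally inside an iterative-closest-point loop when no correspondence is
given.  Selective features of a target pocket versus a homolog are the target
points left without a nearby transformed homolog partner, consolidated by
DBSCAN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN
from sklearn.mixture import GaussianMixture

from .clouds import CATEGORIES, N_CATEGORIES, PharmacophoreCloud

__all__ = [
    "ClusterModel",
    "RigidTransform",
    "cluster_clouds",
    "consensus_category",
    "kabsch",
    "register_clouds",
    "selective_features",
]


@dataclass
class ClusterModel:
    """Fitted Gaussian mixture over pooled cloud coordinates plus the
    per-cluster and global category tables."""

    k: int
    means: np.ndarray                  # (k, 3) Å
    covariances: np.ndarray            # (k, 3, 3)
    weights: np.ndarray                # (k,), sums to 1
    assignments: np.ndarray            # (n_points,) -> component
    cluster_feature_table: np.ndarray  # (k, 8), P(f | sample in C_i), rows sum to 1
    global_feature_table: np.ndarray   # (8,), P(f) over the pooled cloud
    bic: float = float("nan")


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t with the residual RMSD of the fit."""

    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float              # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)


def consensus_category(labels: np.ndarray, global_freq: np.ndarray) -> int:
    """Most probable category for one cluster: majority vote over hard
    labels, ties broken by the global frequency table, then by index order."""
    counts = np.bincount(labels, minlength=N_CATEGORIES).astype(float)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    return int(tied[np.argmax(global_freq[tied])])


def cluster_clouds(clouds, k="auto", seed: int = 0,
                   provenance: str = "clustered"):
    """Consensus-cluster pooled pharmacophore clouds.

    Returns (ClusterModel, consensus cloud) with one consensus point per
    cluster at the component mean, support = cluster size.  With k="auto"
    the component count is selected by BIC over 1..min(8, n_points // 3).
    """
    clouds = list(clouds)
    if not clouds:
        raise ValueError("need at least one cloud")
    xyz = np.concatenate([c.positions for c in clouds])
    labels = np.concatenate([c.category_indices for c in clouds])
    n = len(xyz)
    global_freq = np.bincount(labels, minlength=N_CATEGORIES) / n

    if k == "auto":
        k_max = max(1, min(8, n // 3))
        fits = []
        for kk in range(1, k_max + 1):
            gm = _fit_gmm(xyz, kk, seed)
            fits.append((gm.bic(xyz), kk, gm))
        bic, k_sel, gm = min(fits, key=lambda t: (t[0], t[1]))
    else:
        k_sel = int(k)
        if k_sel < 1 or k_sel > n:
            raise ValueError(f"k={k_sel} invalid for {n} pooled points")
        gm = _fit_gmm(xyz, k_sel, seed)
        bic = gm.bic(xyz)

    assign = gm.predict(xyz)
    table = np.zeros((k_sel, N_CATEGORIES))
    cons_points = []
    for i in range(k_sel):
        members = labels[assign == i]
        if len(members) == 0:
            continue
        counts = np.bincount(members, minlength=N_CATEGORIES).astype(float)
        table[i] = counts / counts.sum()
        cat = consensus_category(members, global_freq)
        cons_points.append((gm.means_[i], cat, len(members)))

    model = ClusterModel(
        k=k_sel, means=gm.means_.copy(), covariances=gm.covariances_.copy(),
        weights=gm.weights_.copy(), assignments=assign,
        cluster_feature_table=table, global_feature_table=global_freq,
        bic=float(bic),
    )
    consensus = PharmacophoreCloud.from_arrays(
        np.array([p[0] for p in cons_points]),
        [p[1] for p in cons_points],
        [p[2] for p in cons_points],
        provenance=provenance,
    )
    return model, consensus


def _fit_gmm(xyz: np.ndarray, k: int, seed: int) -> GaussianMixture:
    # covariance ridge 0.01 Å^2 (0.1 Å std floor): spatial structure below
    # pharmacophore resolution must not be fit as separate components
    gm = GaussianMixture(
        n_components=k, covariance_type="full", tol=1e-4, n_init=5,
        reg_covar=1e-2, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(xyz)
        if not gm.converged_:
            # ridge-regularize harder and retry once
            warnings.warn("GMM did not converge; increasing covariance ridge",
                          stacklevel=2)
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 tol=1e-4, n_init=5, reg_covar=1e-3,
                                 random_state=seed).fit(xyz)
    return gm


# -- Kabsch registration ------------------------------------------------------

def kabsch(a: np.ndarray, b: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping paired points a onto b.

    Classic SVD solution: cross-covariance H = (a - a̅)ᵀ(b - b̅) = U S Vᵀ,
    R = V D Uᵀ with D = diag(1, 1, sign(det(V Uᵀ))) to exclude reflections.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("kabsch needs two equal-shape (N, 3) arrays")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if abs(np.linalg.det(h)) < 1e-12 and np.min(s) < 1e-9 * max(np.max(s), 1.0):
        warnings.warn("degenerate (nearly collinear/planar) point sets in "
                      "Kabsch fit; solution may not be unique", stacklevel=2)
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cb - rot @ ca
    resid = a @ rot.T + trans - b
    rmsd = float(np.sqrt((resid**2).sum() / len(a)))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


def register_clouds(cloud_a: PharmacophoreCloud, cloud_b: PharmacophoreCloud,
                    correspondence: str = "nearest-neighbor",
                    max_iter: int = 100, tol: float = 1e-10) -> RigidTransform:
    """Rigid registration of cloud_a onto cloud_b.

    "paired" assumes point i of a corresponds to point i of b (sizes must
    match).  "nearest-neighbor" runs ICP: alternate nearest-neighbor
    assignment (a -> b) and Kabsch until the RMSD stops improving.
    """
    a, b = cloud_a.positions, cloud_b.positions
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot register empty clouds")
    if correspondence == "paired":
        if len(a) != len(b):
            raise ValueError("paired mode needs equal cloud sizes")
        return kabsch(a, b)
    if correspondence != "nearest-neighbor":
        raise ValueError(f"unknown correspondence mode {correspondence!r}")
    tree = cKDTree(b)
    current = a.copy()
    rot = np.eye(3)
    trans = np.zeros(3)
    prev = np.inf
    for _ in range(max_iter):
        _, idx = tree.query(current)
        step = kabsch(a, b[idx])
        current = step.apply(a)
        rot, trans = step.rotation, step.translation
        if prev - step.rmsd < tol:
            break
        prev = step.rmsd
    d, _ = tree.query(current)
    rmsd = float(np.sqrt((d**2).mean()))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


# -- selective differencing ---------------------------------------------------

def selective_features(target_cloud: PharmacophoreCloud,
                       homolog_cloud: PharmacophoreCloud,
                       transform: RigidTransform | None = None,
                       delta: float = 2.0, dbscan_eps: float = 1.5,
                       dbscan_min: int = 3) -> PharmacophoreCloud:
    """Pharmacophore points unique to the target pocket.

    Keeps target points whose nearest transformed homolog point lies farther
    than `delta` Å, consolidates survivors with DBSCAN (noise points are
    dropped), and labels each retained cluster with its majority category
    (global-frequency tie-break).  `transform` maps the homolog frame onto
    the target frame (identity if omitted).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    hom = homolog_cloud.positions
    if transform is not None:
        hom = transform.apply(hom)
    tgt = target_cloud.positions
    labels = target_cloud.category_indices
    d, _ = cKDTree(hom).query(tgt)
    survivors = d > delta
    if not np.any(survivors):
        warnings.warn(
            f"no target points farther than delta={delta} Å from the homolog "
            "cloud; the targets are indistinguishable at this resolution",
            stacklevel=2)
        return PharmacophoreCloud([], provenance="selective")
    xyz = tgt[survivors]
    cat = labels[survivors]
    db = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min).fit(xyz)
    global_freq = np.bincount(labels, minlength=N_CATEGORIES) / len(labels)
    points, categories, supports = [], [], []
    for ci in sorted(set(db.labels_) - {-1}):
        mask = db.labels_ == ci
        points.append(xyz[mask].mean(axis=0))
        categories.append(consensus_category(cat[mask], global_freq))
        supports.append(int(mask.sum()))
    if not points:
        warnings.warn("all selective survivors were DBSCAN noise",
                      stacklevel=2)
        return PharmacophoreCloud([], provenance="selective")
    return PharmacophoreCloud.from_arrays(
        np.array(points), categories, supports, provenance="selective")
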