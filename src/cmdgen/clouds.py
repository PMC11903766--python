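"""Pharmacophore and pocket point-cloud data model and JSON serialization.

The central currency of the package is the :class:`PharmacophoreCloud`: a
ligand (real or generated) reduced to a handful of labeled 3D points, one per
interaction feature.  Every feature carries one of eight fixed categories;
the label↔index bijection below is pinned and serialized with every artifact
so that one-hot feature matrices are interchangeable across modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CATEGORIES",
    "CATEGORY_INDEX",
    "N_CATEGORIES",
    "FeatureCategory",
    "PharmacophorePoint",
    "PharmacophoreCloud",
    "PocketCloud",
    "read_cloud",
    "write_cloud",
]

#: Pinned category alphabet (order defines the one-hot channel index).
CATEGORIES: tuple[str, ...] = (
    "Aromatic",
    "Hydrophobic",
    "PosIonizable",
    "NegIonizable",
    "Acceptor",
    "Donor",
    "LumpedHydrophobe",
    "Other",
)
CATEGORY_INDEX: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES)}
N_CATEGORIES = len(CATEGORIES)

#: Legacy spellings accepted on input (some pharmacophore vocabularies call
#: the ionizable classes "Localizable"/"Negativable" and the catch-all
#: "Others"); normalized to the pinned labels on read.
CATEGORY_ALIASES: dict[str, str] = {
    "Localizable": "PosIonizable",
    "Negativable": "NegIonizable",
    "Others": "Other",
    "Hydrophobe": "Hydrophobic",
}


@dataclass(frozen=True)
class FeatureCategory:
    """One of the eight pharmacophoric categories."""

    label: str

    def __post_init__(self):
        label = CATEGORY_ALIASES.get(self.label, self.label)
        if label not in CATEGORY_INDEX:
            raise ValueError(
                f"unknown pharmacophore category {self.label!r}; "
                f"valid labels: {', '.join(CATEGORIES)}"
            )
        object.__setattr__(self, "label", label)

    @property
    def index(self) -> int:
        return CATEGORY_INDEX[self.label]

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class PharmacophorePoint:
    """A single labeled feature point (position in Å)."""

    position: np.ndarray
    category: FeatureCategory
    support: int = 1

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError("pharmacophore point coordinates must be finite")
        if self.support < 1:
            raise ValueError("support must be >= 1")
        object.__setattr__(self, "position", pos)
        if isinstance(self.category, str):
            object.__setattr__(self, "category", FeatureCategory(self.category))


@dataclass
class PharmacophoreCloud:
    """An ordered set of pharmacophore points with a provenance tag."""

    points: list[PharmacophorePoint]
    provenance: str = "ligand-derived"

    def __len__(self) -> int:
        return len(self.points)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) float array of point positions in Å."""
        if not self.points:
            return np.zeros((0, 3))
        return np.stack([p.position for p in self.points])

    @property
    def categories(self) -> list[str]:
        return [p.category.label for p in self.points]

    @property
    def category_indices(self) -> np.ndarray:
        return np.array([p.category.index for p in self.points], dtype=np.intp)

    def onehot(self) -> np.ndarray:
        """(N, 8) one-hot feature matrix over the pinned alphabet."""
        h = np.zeros((len(self.points), N_CATEGORIES))
        h[np.arange(len(self.points)), self.category_indices] = 1.0
        return h

    def centroid(self) -> np.ndarray:
        if not self.points:
            raise ValueError("empty cloud has no centroid")
        return self.positions.mean(axis=0)

    @classmethod
    def from_arrays(cls, positions: np.ndarray, categories, supports=None,
                    provenance: str = "ligand-derived") -> "PharmacophoreCloud":
        positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        supports = [1] * len(positions) if supports is None else list(supports)
        pts = []
        for pos, cat, sup in zip(positions, categories, supports):
            if isinstance(cat, (int, np.integer)):
                cat = CATEGORIES[int(cat)]
            pts.append(PharmacophorePoint(pos, FeatureCategory(str(cat)), int(sup)))
        return cls(pts, provenance)

    def translated(self, v: np.ndarray) -> "PharmacophoreCloud":
        v = np.asarray(v, dtype=np.float64).reshape(3)
        return PharmacophoreCloud.from_arrays(
            self.positions + v, self.categories,
            [p.support for p in self.points], self.provenance,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "PharmacophoreCloud":
        pos = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return PharmacophoreCloud.from_arrays(
            pos, self.categories, [p.support for p in self.points], self.provenance
        )


@dataclass
class PocketCloud:
    """Protein-pocket point cloud used as fixed conditioning context.

    In ``full_atom`` mode features are element symbols of heavy atoms; in
    ``calpha`` mode one point per retained residue, featured by residue type.
    """

    positions: np.ndarray
    features: list[str]
    mode: str
    center: np.ndarray
    radius: float
    alphabet: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if self.mode not in ("full_atom", "calpha"):
            raise ValueError(f"mode must be full_atom or calpha, got {self.mode!r}")
        if len(self.features) != len(self.positions):
            raise ValueError("features and positions length mismatch")
        if not self.alphabet:
            self.alphabet = sorted(set(self.features))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def d_p(self) -> int:
        """Feature-alphabet size (one-hot dimension of pocket features)."""
        return len(self.alphabet)

    def onehot(self) -> np.ndarray:
        index = {f: i for i, f in enumerate(self.alphabet)}
        h = np.zeros((len(self), self.d_p))
        for i, f in enumerate(self.features):
            h[i, index[f]] = 1.0
        return h

    def to_json_dict(self) -> dict:
        return {
            "positions": [[round(float(c), 6) for c in p] for p in self.positions],
            "features": list(self.features),
            "mode": self.mode,
            "center": [round(float(c), 6) for c in self.center],
            "radius": float(self.radius),
            "alphabet": list(self.alphabet),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PocketCloud":
        return cls(
            positions=np.asarray(d["positions"], dtype=np.float64),
            features=list(d["features"]),
            mode=d["mode"],
            center=np.asarray(d["center"], dtype=np.float64),
            radius=float(d["radius"]),
            alphabet=list(d.get("alphabet", [])),
        )


# -- JSON round-trip ---------------------------------------------------------

def _cloud_to_dict(cloud: PharmacophoreCloud) -> dict:
    return {
        "points": [
            {
                "xyz": [float(f"{c:.6f}") for c in p.position],
                "category": p.category.label,
                "support": int(p.support),
            }
            for p in cloud.points
        ],
        "provenance": cloud.provenance,
        "categories": list(CATEGORIES),
    }


def write_cloud(cloud, path) -> None:
    """Write a PharmacophoreCloud or PocketCloud as canonical JSON."""
    path = Path(path)
    if isinstance(cloud, PocketCloud):
        payload = {"kind": "pocket", **cloud.to_json_dict()}
    else:
        payload = {"kind": "pharmacophore", **_cloud_to_dict(cloud)}
    path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_cloud(path):
    """Read a cloud JSON file; returns PharmacophoreCloud or PocketCloud."""
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if d.get("kind") == "pocket" or ("mode" in d and "points" not in d):
        return PocketCloud.from_json_dict(d)
    pts = [
        PharmacophorePoint(
            np.asarray(p["xyz"], dtype=np.float64),
            FeatureCategory(p["category"]),
            int(p.get("support", 1)),
        )
        for p in d["points"]
    ]
    return PharmacophoreCloud(pts, d.get("provenance", "ligand-derived"))
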