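"""Evaluation suite: generation metrics (validity / uniqueness / novelty /
available ratio), pharmacophore match score, drug-likeness property panel,
and ligand efficiency.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import QED, Crippen, Descriptors, rdMolDescriptors

from .clouds import CATEGORY_INDEX
from .features import extract_pharmacophores_2d
from .gcpg.pharm_graph import BOND_LENGTH_SCALE, PharmGraph

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (rdkit contrib, Ertl & Schuffenhauer SA score)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "GenerationReport",
    "generation_metrics",
    "match_score",
    "property_panel",
    "ligand_efficiency",
]


@dataclass
class GenerationReport:
    """Aggregate metrics plus a per-molecule table."""

    n_total: int
    n_valid: int
    n_unique: int
    n_novel: int
    validity: float
    uniqueness: float
    novelty: float
    available_ratio: float
    table: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "n_total": self.n_total, "n_valid": self.n_valid,
            "n_unique": self.n_unique, "n_novel": self.n_novel,
            "validity": self.validity, "uniqueness": self.uniqueness,
            "novelty": self.novelty, "available_ratio": self.available_ratio,
        }


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def generation_metrics(generated: list[str],
                       reference_corpus: set[str],
                       with_properties: bool = True) -> GenerationReport:
    """Standard generative-chemistry metrics.

    validity  = n_valid / n_total
    uniqueness = n_unique / n_valid          (over canonical SMILES)
    novelty   = n_novel / n_unique           (not in the reference corpus)
    available_ratio = n_{valid & unique & novel} / n_total

    The reference corpus must already be canonicalized.
    """
    if len(generated) == 0:
        raise ValueError("no generated molecules to evaluate")
    n_total = len(generated)
    rows = []
    seen: set[str] = set()
    n_valid = 0
    for smi in generated:
        can = _canonical(smi)
        valid = can is not None
        n_valid += valid
        first = valid and can not in seen
        if first:
            seen.add(can)
        novel = first and can not in reference_corpus
        rows.append({"smiles": smi, "canonical": can, "valid": valid,
                     "unique": first, "novel": novel})
    n_unique = len(seen)
    n_novel = sum(r["novel"] for r in rows)
    table = pd.DataFrame(rows)
    if with_properties and n_valid:
        props = {k: [] for k in ("MW", "LogP", "QED", "SAS", "RotBonds", "TPSA")}
        for r in rows:
            vals = property_panel(r["canonical"]) if r["valid"] else \
                dict.fromkeys(props, np.nan)
            for k in props:
                props[k].append(vals[k])
        for k, v in props.items():
            table[k] = v
    return GenerationReport(
        n_total=n_total, n_valid=n_valid, n_unique=n_unique, n_novel=n_novel,
        validity=n_valid / n_total,
        uniqueness=(n_unique / n_valid) if n_valid else 0.0,
        novelty=(n_novel / n_unique) if n_unique else 0.0,
        available_ratio=n_novel / n_total,
        table=table,
    )


def property_panel(smiles: str) -> dict:
    """MW, Wildman-Crippen LogP, QED, Ertl SAS (1-10), rotatable bonds,
    Ertl TPSA for one molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"invalid SMILES {smiles!r}")
    return {
        "MW": Descriptors.MolWt(mol),
        "LogP": Crippen.MolLogP(mol),
        "QED": QED.qed(mol),
        "SAS": sascorer.calculateScore(mol),
        "RotBonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "TPSA": rdMolDescriptors.CalcTPSA(mol),
    }


def ligand_efficiency(score: float, smiles: str) -> float:
    """-score / n_heavy_atoms: binding score (kcal/mol, more negative =
    better) normalized per heavy atom, oriented so larger is better."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    n_heavy = mol.GetNumAtoms()
    if n_heavy < 1:
        raise ValueError("molecule has no heavy atoms")
    return -float(score) / n_heavy


def match_score(smiles: str, phar: PharmGraph, tau: float = 1.5) -> float:
    """Fraction of pharmacophore nodes a molecule can satisfy.

    The molecule's 2D features (topological distances x 1.5 Å/bond) are
    assigned injectively to category-matching pharmacophore nodes; a node
    counts as satisfied when every pairwise distance to the other assigned
    nodes agrees within tau Å.  The maximum satisfied count over all
    assignments (exact search) is divided by the node count.
    """
    if len(phar) == 0:
        raise ValueError("empty pharmacophore graph")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    feats = extract_pharmacophores_2d(mol)
    dmat = Chem.GetDistanceMatrix(mol)
    mol_cats = [CATEGORY_INDEX[f[0]] for f in feats]
    anchors = [list(f[1]) for f in feats]

    def mol_dist(i: int, j: int) -> float:
        return BOND_LENGTH_SCALE * min(
            dmat[a, b] for a in anchors[i] for b in anchors[j])

    n = len(phar)
    best = 0
    # candidates per node: molecule features of the same category (or None)
    cands = [[m for m, c in enumerate(mol_cats) if c == phar.node_categories[i]]
             for i in range(n)]

    def search(i: int, used: set, assign: list):
        nonlocal best
        if i == n:
            matched = _count_satisfied(assign, phar, mol_dist, tau)
            best = max(best, matched)
            return
        # upper bound prune: even matching all remaining can't beat best
        if len([a for a in assign if a is not None]) + (n - i) <= best:
            return
        for m in cands[i]:
            if m in used:
                continue
            used.add(m)
            search(i + 1, used, assign + [m])
            used.remove(m)
        search(i + 1, used, assign + [None])

    search(0, set(), [])
    return best / n


def _count_satisfied(assign, phar: PharmGraph, mol_dist, tau: float) -> int:
    n = len(assign)
    ok = 0
    for i in range(n):
        if assign[i] is None:
            continue
        good = True
        for j in range(n):
            if j == i or assign[j] is None:
                continue
            if abs(phar.edge_dist[i, j] - mol_dist(assign[i], assign[j])) > tau:
                good = False
                break
        ok += good
    return ok
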