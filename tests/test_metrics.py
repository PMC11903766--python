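"""Generation metrics, match score, property panel, ligand efficiency."""

from itertools import product

import numpy as np
import pytest

from cmdgen.gcpg.pharm_graph import (
    BOND_LENGTH_SCALE,
    PharmGraph,
    mol_to_training_pair,
)
from cmdgen.metrics import (
    generation_metrics,
    ligand_efficiency,
    match_score,
    property_panel,
)

# -- generation metrics -------------------------------------------------------

# 10 strings: 2 unparseable; among the 8 valid 1 duplicate; among the 7
# unique, 2 sit in the reference corpus
TEN_STRINGS = [
    "garbage(((",        # invalid
    "C1CC",              # invalid (unclosed ring)
    "CCO",               # valid, in reference
    "CCN",               # valid, in reference
    "CCC",               # valid, novel
    "CCC",               # duplicate of the above
    "c1ccccc1",          # valid, novel
    "CCCl",              # valid, novel
    "CC=O",              # valid, novel
    "CCS",               # valid, novel
]
REFERENCE = {"CCO", "CCN", "CCCC"}


def test_hand_counted_fixture():
    r = generation_metrics(TEN_STRINGS, REFERENCE, with_properties=False)
    assert r.n_total == 10 and r.n_valid == 8
    assert r.n_unique == 7 and r.n_novel == 5
    assert r.validity == pytest.approx(0.8)
    assert r.uniqueness == pytest.approx(0.875)
    assert r.novelty == pytest.approx(5 / 7)
    assert r.available_ratio == pytest.approx(0.5)


def test_all_identical_and_novel():
    r = generation_metrics(["CCO"] * 5, {"CCN"}, with_properties=False)
    assert r.n_valid == 5 and r.n_unique == 1
    assert r.uniqueness == pytest.approx(1 / 5)
    assert r.available_ratio == pytest.approx(1 / 5)


def test_generated_subset_of_reference():
    r = generation_metrics(["CCO", "CCN"], {"CCO", "CCN"},
                           with_properties=False)
    assert r.novelty == 0.0
    assert r.available_ratio == 0.0


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        generation_metrics([], set())


def test_report_invariant_chain():
    """n_novel <= n_unique <= n_valid <= n_total and the available-ratio
    identity available = novelty * uniqueness * validity."""
    rng = np.random.default_rng(0)
    pool = ["CCO", "CCN", "CCC", "bad(", "c1ccccc1", "CCO"]
    for _ in range(10):
        sample = [pool[i] for i in rng.integers(0, len(pool), size=8)]
        r = generation_metrics(sample, {"CCO"}, with_properties=False)
        assert r.n_novel <= r.n_unique <= r.n_valid <= r.n_total
        assert r.available_ratio == pytest.approx(
            r.novelty * r.uniqueness * r.validity)
        assert r.available_ratio <= r.validity


def test_metrics_idempotent_under_canonicalization():
    from rdkit import Chem
    strings = ["OCC", "NCC", "C1=CC=CC=C1"]
    canon = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in strings]
    r1 = generation_metrics(strings, set(), with_properties=False)
    r2 = generation_metrics(canon, set(), with_properties=False)
    assert r1.summary() == r2.summary()


# -- property panel -----------------------------------------------------------

def test_benzene_panel():
    p = property_panel("c1ccccc1")
    assert p["MW"] == pytest.approx(78.11, abs=0.01)
    assert p["RotBonds"] == 0
    assert p["TPSA"] == 0.0


def test_ethanol_tpsa_matches_fragment_table():
    # Ertl fragment contribution for an aliphatic hydroxyl
    assert property_panel("CCO")["TPSA"] == pytest.approx(20.23, abs=0.01)


@pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1",
                                    "CN1CCC[C@H]1c1cccnc1"])
def test_qed_and_sas_ranges(smiles):
    p = property_panel(smiles)
    assert 0.0 <= p["QED"] <= 1.0
    assert 1.0 <= p["SAS"] <= 10.0


def test_invalid_smiles_rejected():
    with pytest.raises(ValueError):
        property_panel("notasmiles((")


# -- ligand efficiency --------------------------------------------------------

def test_ligand_efficiency_arithmetic():
    # eicosane: 20 heavy atoms
    assert ligand_efficiency(-10.0, "C" * 20) == pytest.approx(0.5)
    assert ligand_efficiency(0.0, "CCO") == 0.0


def test_ligand_efficiency_monotone_in_size():
    le_small = ligand_efficiency(-8.0, "CCCCCC")
    le_big = ligand_efficiency(-8.0, "C" * 20)
    assert le_big < le_small


# -- match score --------------------------------------------------------------

def _brute_force_match(smiles: str, phar: PharmGraph, tau: float) -> float:
    """Independent oracle: full enumeration over injective category-
    consistent assignments (no pruning), itertools-based."""
    from rdkit import Chem

    from cmdgen.clouds import CATEGORY_INDEX
    from cmdgen.features import extract_pharmacophores_2d

    mol = Chem.MolFromSmiles(smiles)
    feats = extract_pharmacophores_2d(mol)
    dmat = Chem.GetDistanceMatrix(mol)
    cats = [CATEGORY_INDEX[f[0]] for f in feats]
    anchors = [list(f[1]) for f in feats]

    def mdist(i, j):
        return BOND_LENGTH_SCALE * min(
            dmat[a, b] for a in anchors[i] for b in anchors[j])

    n = len(phar)
    options = [[m for m, c in enumerate(cats)
                if c == phar.node_categories[i]] + [None] for i in range(n)]
    best = 0
    for combo in product(*options):
        chosen = [c for c in combo if c is not None]
        if len(chosen) != len(set(chosen)):
            continue
        ok = 0
        for i in range(n):
            if combo[i] is None:
                continue
            good = all(
                abs(phar.edge_dist[i, j] - mdist(combo[i], combo[j])) <= tau
                for j in range(n) if j != i and combo[j] is not None)
            ok += good
        best = max(best, ok)
    return best / n


def test_self_match_is_one(small_corpus):
    rng = np.random.default_rng(1)
    for smi in small_corpus[:5]:
        phar, _ = mol_to_training_pair(smi, rng, infill_rate=0.0)
        assert match_score(smi, phar, tau=0.1) == 1.0


def test_single_aromatic_node_vs_benzene():
    phar = PharmGraph([0], np.zeros((1, 1)))
    assert match_score("c1ccccc1", phar) == 1.0


def test_missing_category_scores_below_one_and_matches_oracle():
    # PosIonizable node that ethanol cannot satisfy
    phar = PharmGraph([5, 2], np.array([[0.0, 3.0], [3.0, 0.0]]))
    s = match_score("CCO", phar, tau=1.5)
    assert s < 1.0
    assert s == pytest.approx(_brute_force_match("CCO", phar, 1.5))


def test_match_score_equals_bruteforce_on_random_pairs(small_corpus):
    rng = np.random.default_rng(2)
    for trial in range(50):
        smi = small_corpus[int(rng.integers(len(small_corpus)))]
        n = int(rng.integers(1, 5))
        cats = rng.integers(0, 8, size=n).tolist()
        pos = rng.uniform(0, 10, size=(n, 3))
        d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        phar = PharmGraph(cats, d)
        assert match_score(smi, phar) == pytest.approx(
            _brute_force_match(smi, phar, 1.5))


def test_match_score_monotone_under_unsatisfiable_nodes(small_corpus):
    """Adding nodes of categories absent from the molecule never raises the
    score."""
    rng = np.random.default_rng(3)
    smi = "CCO"  # has Donor/Acceptor/Hydrophobic but no aromatic ring
    phar, _ = mol_to_training_pair(smi, rng, infill_rate=0.0)
    base = match_score(smi, phar)
    n = len(phar)
    d2 = np.zeros((n + 1, n + 1))
    d2[:n, :n] = phar.edge_dist
    d2[n, :n] = d2[:n, n] = 5.0
    bigger = PharmGraph(phar.node_categories + [0], d2)  # Aromatic added
    assert match_score(smi, bigger) <= base


def test_empty_pharm_graph_rejected():
    with pytest.raises(ValueError):
        PharmGraph(node_categories=[], edge_dist=np.zeros((0, 0)))
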