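# cmdgen

Hierarchical pharmacophore-guided molecular generation for structure-based
drug design.

Generating drug-like 3D molecules directly inside a protein pocket couples
two hard problems — where the interaction hot-spots are, and which
chemistry realizes them.  `cmdgen` decouples them through a coarse-grained
intermediate, the **pharmacophore point cloud**: a ligand reduced to a
handful of labeled 3D points (aromatic ring, H-bond donor/acceptor,
hydrophobe, ionizable group, ...).  The pipeline:

1. **Sample** pharmacophore clouds inside a pocket with a
   pocket-conditioned equivariant denoising-diffusion model.  The
   variance-preserving process `q(z_t|z_0) = N(α_t z_0, σ_t² I)` with
   `α_t² + σ_t² = 1` is reversed with an E(3)-equivariant graph network
   predicting the injected noise, the pocket acting as fixed 3D context.
2. **Cluster** repeated samples with a Gaussian mixture on coordinates;
   each cluster's category is `argmax_f Σ_{sample∈C_i} P(f|sample)`
   (majority vote, global-frequency tie-break) — one consensus
   pharmacophore hypothesis per pocket.
3. **Generate** SMILES with a conditional latent-variable
   encoder–decoder whose condition combines the pharmacophore graph with a
   **gating mechanism**: per-property channels (MW, LogP, QED, SAS,
   rotatable bonds, TPSA, docking score) that are either *open* (value
   enforced) or *closed* (unconstrained).  A fine-tuning channel consumes
   external docking-score tables for activity-gated generation.
4. **Pose** generated molecules by exact category-consistent assignment of
   cloud points to conformer features plus a Kabsch fit, with a tolerance
   for unmatched cloud points.
5. **Differencing** the registered clouds of two related pockets (Kabsch /
   ICP + DBSCAN) yields the features unique to one target — the starting
   point for selective-inhibitor design.

An evaluation suite reports validity / uniqueness / novelty / available
ratio, a pharmacophore match score, the standard property panel and ligand
efficiency.  Synthetic fixture generators (toy pocket–cloud complexes with
known statistics and a template-enumerated drug-like SMILES corpus) make
every stage trainable and testable on one CPU with no downloads.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Extract a pharmacophore cloud from a 3D ligand (paracetamol, embedded with
RDKit):

```python
from rdkit import Chem
from rdkit.Chem import AllChem
from cmdgen.features import extract_ligand_pharmacophores

mol = Chem.AddHs(Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1"))
params = AllChem.ETKDGv3(); params.randomSeed = 7
AllChem.EmbedMolecule(mol, params); AllChem.MMFFOptimizeMolecule(mol)
cloud = extract_ligand_pharmacophores(Chem.RemoveHs(mol))
for pt in cloud.points:
    print(f"{pt.category.label:<16} {pt.position.round(2)}  support={pt.support}")
```

```
Donor            [-1.33  0.21  0.21]  support=1
Donor            [ 4.14  0.07 -0.82]  support=1
Acceptor         [-2.12 -1.91 -0.39]  support=1
Acceptor         [ 4.14  0.07 -0.82]  support=1
Aromatic         [ 1.43  0.12 -0.32]  support=6
LumpedHydrophobe [ 1.43  0.12 -0.32]  support=6
```

Each detected feature becomes one point at the centroid of its member
atoms: the amide N–H and the phenol O–H are donors, the carbonyl and
phenol oxygens acceptors, and the ring contributes an aromatic point and a
lumped hydrophobe at the ring centroid (support = 6 atoms).

Scoring a generated batch against a reference corpus:

```python
from cmdgen.metrics import generation_metrics

rep = generation_metrics(
    ["CCO", "CCO", "c1ccccc1", "CCN", "not_a_molecule"],
    reference_corpus={"CCO"})
print(rep.summary())
```

```
{'n_total': 5, 'n_valid': 4, 'n_unique': 3, 'n_novel': 2,
 'validity': 0.8, 'uniqueness': 0.75, 'novelty': 0.667,
 'available_ratio': 0.4}
```

One string fails to parse (validity 4/5), one is a duplicate (uniqueness
3/4), and of the three unique molecules one sits in the reference corpus
(novelty 2/3); the available ratio 2/5 counts molecules that are valid,
unique *and* novel against everything generated.

The same operations are scriptable end to end from the shell:

```bash
cmdgen fixtures --kind complexes --n 200 --seed 1 --out fx/
cmdgen train-diffusion --pairs fx/ --epochs 200 --hidden 64 --layers 3 \
       --t-steps 150 --cutoff 12 --coord-scale 4 --lr 2e-3 --out model.npz
cmdgen sample --pocket fx/pocket_0000.json --model model.npz \
       --n-points 5 --repeats 5 --seed 1 --out clouds/
cmdgen cluster --clouds clouds/sampled_000.json --clouds clouds/sampled_001.json \
       --k auto --out consensus.json
cmdgen generate --model gcpg.npz --cloud consensus.json --n 100 \
       --gate MW=400 --gate QED=0.6 --seed 1 --out gen.smi
cmdgen pose --smiles gen.smi --cloud consensus.json --tolerance 1 --out poses.sdf
cmdgen evaluate --generated gen.smi --reference corpus.smi \
       --cloud consensus.json --out report.csv
```

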