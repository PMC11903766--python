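# Methods

This note documents the models implemented in `cmdgen`, the assumptions
behind them, the synthetic data they are exercised on, and the numerical
and design choices a maintainer would want to know about.  Everything here
is computed by the test-suite or by `scripts/acceptance.py`; no number is
quoted from elsewhere.

## Overview

`cmdgen` is a coarse-to-fine pipeline for structure-based ligand design.
Instead of generating atoms directly in a protein pocket, it:

1. samples **coarse-grained pharmacophore point clouds** — a handful of
   labeled 3D points (aromatic ring, H-bond donor/acceptor, hydrophobe,
   ionizable group, ...) — inside the pocket with a conditional equivariant
   diffusion model;
2. **consensus-clusters** repeated samples into one pharmacophore
   hypothesis;
3. decodes hypotheses into molecules with a **property-gated conditional
   SMILES generator**;
4. poses generated molecules by **rigid pharmacophore alignment**; and
5. supports selective-inhibitor design by **registering and differencing**
   the clouds of two related pockets.

The pharmacophore abstraction is the interface between the 3D generative
stage and the chemical-language stage: both sides only need to agree on
eight feature categories (Aromatic, Hydrophobic, PosIonizable,
NegIonizable, Acceptor, Donor, LumpedHydrophobe, Other) and on pairwise
distances between feature points.

## Pocket-conditioned diffusion over pharmacophore clouds

### Model

The latent state is `z = (x, h)` with `x ∈ R^{N×3}` (Å) and `h ∈ R^{N×8}` a
continuous relaxation of the one-hot category matrix (scale 1.0, decoded by
argmax at the end of sampling).  The variance-preserving forward process is

    q(z_t | z_0) = N(z_t | α_t z_0, σ_t² I),     α_t² + σ_t² = 1,

and the exact reverse transition for s < t is Gaussian with

    mean = (α_{t|s} σ_s²/σ_t²) z_t + (α_s σ_{t|s}²/σ_t²) z_0,
    var  = σ_{t|s}² σ_s²/σ_t²,

with `α_{t|s} = α_t/α_s` and `σ_{t|s}² = σ_t² − α_{t|s}² σ_s²`.  A noise
predictor `φ_θ(z_t, pocket, t)` yields `ε̂`, the clean-state estimate is
`ẑ_0 = z_t/α_t − (σ_t/α_t) ε̂`, and the chain plugs `ẑ_0` into the exact
transition.  Training minimizes `½‖ε − φ_θ(z_t, pocket, t)‖²` with the
pocket as fixed, noise-free context.

Two schedules are provided: a quadratic ("polynomial") α-decay
`α_t = (1 − (t/T)²)(1 − 2·10⁻⁴) + 10⁻⁴` (default) and a clipped cosine
schedule.  Both satisfy the conservation identity to < 1e-12 at every step.

### Handling translations: why the ligand center of mass is noised

Rotational equivariance is architectural (below).  Translations are handled
by expressing all coordinates in a frame anchored on the pocket centroid.
An alternative sometimes used — projecting the ligand's coordinate noise
onto its zero-center-of-mass subspace — was implemented first and rejected:
with CoM-projected noise the translational coordinate of the cloud is
*noise-free* under the forward process, so the reverse chain can only move
the cloud centroid through the ε-predictor's CoM output, which enters
`ẑ_0` multiplied by σ_t/α_t and therefore amplifies model error by up to
1/α_T ≈ 10⁴.  In practice the sampled centroid either stayed frozen at its
initialization or drifted chaotically.  With the pocket as translational
anchor, the ligand CoM is an ordinary noised coordinate and the posterior
step matches the closed form exactly — which is also what the acceptance
check on the posterior sampler verifies.

### Noise predictor

`φ_θ` is an E(3)-equivariant graph network:

- **Nodes**: ligand cloud points (category one-hot + t/T scalar) and pocket
  points (element/residue one-hot + t/T), embedded by separate input
  projections (which doubles as the ligand/pocket flag).
- **Pocket encoder**: two rounds of feature-only message passing *among
  pocket atoms* (8 Å radius, coordinates fixed).  This stage is independent
  of t, so samplers compute it once per reverse chain.  It matters: a
  single ligand←pocket hop aggregates pocket geometry linearly and can only
  express "weighted centroid of the pocket" directional estimates; local
  pocket-pocket context (e.g. proximity to a cavity-rim) is what lets the
  ligand head point *into* the cavity opening.  Adding it cut the toy
  centroid-recovery error by roughly half.
- **Main stack** (default 5 layers at full scale, 3 at desk scale): edges
  directed into ligand nodes only, rebuilt from the current coordinates
  every denoising step (6 Å cutoff at full scale; 12 Å at desk scale so the
  8 Å toy cavity fits in the receptive field).  Edge messages see the
  invariant scalars |x_i−x_j|², |x_i|², |x_j|², x_i·x_j (the frame origin —
  the pocket centroid — is covariant, so all four are invariant under
  common rotations).  Coordinate updates are linear combinations of the
  difference vectors (x_i−x_j)/(d_ij+1) *and* of the neighbor frame
  positions x_j/(|x_j|+1); the second term lets a layer express
  pocket-anisotropy-aligned fields (such as "toward the mouth") directly.
- **Output heads**: ε̂_coords = (coordinate drift of the stack) + x·g(t)
  with a learned scalar schedule g — the optimal ε contains a z_t-
  proportional component that message passing alone converges to slowly —
  and an invariant feature head for ε̂_feats.

Rotating the pocket and the injected noise stream rotates the sampled cloud
to < 1e-4 Å through the entire reverse chain (checked for untrained and
trained models over 20 random rotations).

### Numerical stabilization of the reverse chain

Early reverse steps divide by α_t ≈ 10⁻⁴; with an imperfect predictor the
clean-state estimate can explode before the chain has gathered signal.
Two clips are applied during sampling only: ẑ_0 coordinates are radially
rescaled into a ball of radius (max pocket extent + 10 Å) around the pocket
centroid — a rotation-equivariant operation — and ẑ_0 features are clipped
to [−4, 4].  Internally the chain runs on coordinates divided by
`coord_scale` (4 Å at desk scale) so pocket-scale geometry has roughly unit
variance, matching the N(0, I) terminal distribution.

### Desk-scale training protocol

(`cmdgen.protocols`): 200 synthetic complexes, hidden 64 × 3 layers,
T = 150, Adam at 2e-3 with linear decay to 10%, batch 16, 200 epochs
(about 8 minutes on one CPU), timesteps drawn with density ∝ √(t/T) —
placing the cloud relative to the pocket is learned at high noise, which a
uniform draw under-weights.  Sampling 200 clouds takes about one minute.

## Synthetic fixtures

`make_complex_fixtures` emulates the geometry the diffusion model must
learn from real pocket-ligand pairs, at desk scale:

- **Pocket**: 32 pseudo-atoms on a spherical shell of radius 8 ± 0.4 Å
  with a cap removed around one direction — the cavity "mouth" (cosine
  half-width 0.35, i.e. a ±49° opening, the scale of a real ligand-entry
  channel).  The mouth is essential, not cosmetic: an isotropic shell
  carries no directional information, and a rotation-equivariant model
  provably cannot recover a centroid offset from it.
- **Ligand cloud**: 5 points, i.i.d. Gaussian (σ = 1 Å) around
  pocket-center + offset (3 Å, along the mouth), categories i.i.d. from a
  fixed 8-vector dominated by Acceptor/Donor (0.25 each).
- An optional corrupt fraction displaces cloud centroids by 2.5–4 Å,
  emulating the bad complex conformations that a ≥ 2 Å quality screen
  (`filter_displaced_pairs`) should remove.

What passing the recovery check shows: the sampler reproduces the category
marginals (TV ≤ 0.15) and places clouds at the right position relative to
an *anisotropic* pocket (mean centroid within 1 Å of the 3 Å offset over
200 samples).  What it does not show: chemistry-specific feature
co-occurrence, realistic pocket surfaces, or transferability across
receptors — real pockets are far more informative than a 32-point shell,
but also far more varied.

The SMILES corpus (`make_smiles_corpus`) enumerates scaffold × linker × cap
templates (benzamides, anilines, sulfonamides, piperazines, indoles, ...),
giving up to ~2200 valid, unique, canonical molecules with MW ≈ 120–420
(well under the 800 Da preprocessing cap) and ≥ 2 pharmacophore features
in ≥ 95% of cases.  Its deliberately wide MW spread is what gives the
gate-shift experiments a detectable effect size.

## Consensus clustering (space + feature)

Pooled cloud points are clustered by a full-covariance Gaussian mixture on
coordinates (5 restarts, tol 1e-4, covariance ridge 0.01 Å²; the ridge
matters — without a ~0.1 Å std floor, BIC happily pays for components that
collapse onto single points, and model selection overshoots k).  With
k = "auto", BIC is scanned over 1..min(8, n/3).  Each cluster's category is

    argmax_f Σ_{sample ∈ C_i} P(f | sample),

where P(f|sample) is the indicator of the sample's hard label (diffusion
outputs argmax labels), i.e. a per-cluster majority vote; ties are broken
by the pooled global frequency P(f), then by category order, making the
rule deterministic.  The acceptance check verifies the rule against
exhaustive enumeration over all eight categories.

## Registration and selective differencing

`kabsch` implements the closed-form SVD superposition (proper rotations
only, reflection guarded by the determinant sign; near-degenerate point
sets warn but still return the least-squares solution).  Unpaired clouds
are registered by iterated closest-point: assign nearest neighbors, solve,
repeat until the RMSD stops improving (tol 1e-10, cap 100 iterations).

Selective features of a target pocket versus a homolog: target points
whose nearest transformed homolog point is farther than δ (default 2 Å —
the scale of a residue-level clash; a convex-hull "outside the shape" test
was rejected because hulls mislabel interior cavities), consolidated by
DBSCAN (eps 1.5 Å, min_samples 3; noise points dropped), each cluster
labeled by the same majority rule.  `selective(A, A)` is empty for any
δ > 0 and survivor counts are monotone nonincreasing in δ.

## Property-gated SMILES generation

A latent-variable encoder-decoder over SMILES tokens, conditioned on
`c_com = (c_phar, g(c_feat))`:

- **c_phar**: a pharmacophore graph — category nodes with pairwise
  distances.  At training time graphs are built from the molecule's own 2D
  features with topological shortest-path distances × 1.5 Å/bond (mean
  single-bond length); multi-atom features use the minimum over member-atom
  pairs.  At inference the graph comes from a sampled 3D cloud with
  Euclidean distances.  This train/inference distance-domain mismatch is a
  deliberate, documented caveat of the approach; the 1.5 Å/bond scale keeps
  the two domains numerically aligned.  The graph encoder is two rounds of
  distance-biased attention (RBF-embedded distances → additive attention
  bias).
- **g(c_feat)**: seven ordered property channels (MW, LogP, QED, SAS,
  RotBonds, TPSA, DockScore).  An open channel embeds its normalized value;
  a closed channel contributes a learned null vector — the stored value
  cannot leak because a closed gate has no value slot at all.  Channel
  embeddings are concatenated and fused into a gating vector added to the
  decoder input at every position.
- **Latent**: Gaussian posterior `P(z | c_com, x)` against an N(0, I)
  prior, closed-form KL with a linear warm-up over the first 10% of steps.
  On the 500-molecule toy corpus the KL settles near zero — the condition
  plus autoregression explains the data, so generation quality does not
  depend on a posterior/prior mismatch.
- **Decoder**: pre-norm causal self-attention blocks with cross-attention
  into the pharmacophore node memory; a token head and a mapping head.
  The mapping loss is the cross-entropy of predicting, for every atom
  token, which pharmacophore node it realizes (or none), against the known
  feature→anchor-atom assignment; the three loss terms (KL, LM, mapping)
  are weighted 1:1:1.
- **Noise injection ("infilling")**: each epoch, each molecule's condition
  graph is a fresh random subset of 2..8 of its features, and each property
  gate is independently open (with its true value) or closed with
  probability ½ — so the model learns conditional and unconditional
  behavior for every channel.

Training at desk scale: 500 molecules, hidden 64, 2 blocks, latent 8,
batch 32, 150 epochs, cyclic cosine annealing (restart every 4 epochs).
The learning rate is 1e-3 rather than the 3e-4 used at full scale: with a
tiny model and corpus the smaller rate does not reach syntactic competence
within the desk budget (validity stalls below 20%), while 1e-3 reaches
~60–75% validity and a strongly significant molecular-weight gate response.
Default sampling temperature 0.8; maximum decode length 128 tokens (80 at
desk scale).

Fine-tuning on activity surrogates (`finetune_with_scores`) continues
training with only the DockScore gate, from a user-supplied
(smiles, score) table — docking itself is external to this package.  The
two generation protocols are exposed as conventions, not code paths:
drug-likeness-gated generation uses the five property gates at user values
(pre-filter ranges MW 325–425, LogP 1–4, QED 0.4–0.8, SAS 1–5,
RotBonds 4–6 are shipped as config defaults); score-gated generation
fine-tunes on scores and then fixes DockScore at a target value.

## Pharmacophore alignment (posing)

Conformers come from RDKit distance-geometry embedding (ETKDGv3, seeded)
with MMFF minimization.  For each rigid conformer, all injective,
category-consistent assignments of cloud points to conformer features are
enumerated exactly (branch-and-bound; clouds are capped at 12 points), with
up to `tolerance` cloud points left unmatched — surplus *molecule* features
are free, mirroring pharmacophore-screening convention.  Each assignment is
scored by a Kabsch fit on the matched feature centroids; poses with RMSD ≤
`fit_cutoff` (default 1.5 Å per matched pair) are returned sorted by
(unmatched count, RMSD).  One molecule can therefore yield several poses.
Pose-to-pose RMSD is computed in place (no refit) and minimized over graph
automorphisms (capped at 10⁴ mappings).

## Evaluation metrics

For a generated batch against a canonicalized reference corpus:
validity = valid/total; uniqueness = unique/valid; novelty = novel/unique
(computed over unique valid canonical SMILES, so novelty ≤ 1 by
construction); available ratio = (valid ∧ unique ∧ novel)/total — which
makes `available = validity × uniqueness × novelty` an exact identity.
Zero-atom parses count as invalid.  The property panel uses the published
definitions: Wildman–Crippen logP, Ertl–Schuffenhauer synthetic
accessibility (1–10), QED, Ertl TPSA, rotatable-bond count.  Ligand
efficiency is −score/heavy-atom count (positive is better).  The match
score of a molecule against a pharmacophore graph is the maximum, over
injective category-consistent assignments, of the fraction of graph nodes
whose assigned pairwise distances agree within τ (default 1.5 Å, one bond
unit), computed by exact search and verified against full enumeration.

## Known limitations

- The desk-scale pocket is a 32-point shell; direction inference from it
  is intrinsically noisy (even an oracle margin estimator of the mouth
  direction attains mean cosine ≈ 0.93), so sampled-centroid accuracy at
  this scale should not be read as a docking-accuracy claim.
- The SMILES generator's latent collapses on the toy corpus; on a corpus
  of millions the KL term would be active and the latent meaningful.
- Pose generation does not refit torsions and does not score poses against
  the receptor; docking/rescoring tables are consumed, never produced.
- The eight-category alphabet treats "Other" as a real catch-all class;
  with the default RDKit feature definitions it is rarely populated.
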