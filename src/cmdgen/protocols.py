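"""Desk-scale study protocols: the fixed conditions under which the package
trains and evaluates its models on synthetic fixtures.

These are the problem sizes and model settings used by the test-suite and by
the reproduction script; docs/methods.md discusses why each was chosen.  The
synthetic-data conditions (pair counts, noise levels, category marginals,
centroid offset) are fixed here once; model hyperparameters are the desk
equivalents of the full-scale settings.
"""

from __future__ import annotations

import numpy as np

from .clouds import CATEGORIES
from .diffusion import (
    DenoiserConfig,
    build_schedule,
    sample_pharmacophores_batch,
    train_denoiser,
)
from .fixtures import FixtureSpec, make_complex_fixtures, make_smiles_corpus
from .gcpg import GcpgConfig, train_gcpg

__all__ = [
    "diffusion_fixture_spec",
    "toy_denoiser_config",
    "train_toy_diffusion",
    "sample_toy_clouds",
    "toy_gcpg_config",
    "train_toy_gcpg",
    "TOY_CORPUS_SIZE",
]

#: number of molecules in the desk-scale generator corpus
TOY_CORPUS_SIZE = 500


def diffusion_fixture_spec(seed: int = 3) -> FixtureSpec:
    """200 pocket-cloud pairs: spherical-shell pockets (radius 8 Å) with a
    mouth opening, clouds of 5 points at a 3 Å centroid offset with 1 Å
    spatial spread and a fixed category mix."""
    return FixtureSpec(
        n_pairs=200, pocket_points=32, cloud_points=5,
        offset=(3.0, 0.0, 0.0), spatial_sigma=1.0, pocket_radius=8.0,
        seed=seed,
    )


def toy_denoiser_config(seed: int = 1, epochs: int = 200) -> DenoiserConfig:
    """Desk-scale noise-predictor settings.

    Cutoff 12 Å (the 8 Å toy cavity must fit inside the receptive field),
    coordinate normalization 4 Å, T = 150 reverse steps, hidden 64 x 3
    layers trained with Adam at 2e-3.
    """
    return DenoiserConfig(
        hidden_dim=64, n_layers=3, epochs=epochs, lr=2e-3, batch_size=16,
        seed=seed, T=150, cutoff=12.0, coord_scale=4.0,
    )


def train_toy_diffusion(seed: int = 1, epochs: int = 200):
    """Train the toy denoiser on the fixture pairs.  Returns
    (model, schedule, pairs, trace, spec).  The fixture conditions are
    fixed; `seed` drives model initialization and the training noise."""
    spec = diffusion_fixture_spec()
    pairs = make_complex_fixtures(spec)
    config = toy_denoiser_config(seed=seed, epochs=epochs)
    model, trace = train_denoiser(pairs, config)
    schedule = build_schedule(config.T, config.schedule_kind)
    return model, schedule, pairs, trace, spec


def sample_toy_clouds(model, schedule, pairs, n_samples: int, seed: int,
                      n_points: int = 5):
    pockets = [pairs[i % len(pairs)][0] for i in range(n_samples)]
    rng = np.random.default_rng(seed)
    return sample_pharmacophores_batch(
        pockets, [n_points] * n_samples, model, schedule, rng)


def toy_gcpg_config(seed: int = 0, epochs: int = 150) -> GcpgConfig:
    """Desk-scale generator: hidden 64, 2 transformer blocks, latent 8.

    The learning rate is raised to 1e-3 (vs the full-scale 3e-4): with a
    500-molecule corpus and a small model, convergence within the desk
    budget needs the larger step size.  Default sampling temperature 0.8.
    """
    return GcpgConfig(
        hidden_dim=64, n_blocks=2, latent_dim=8, epochs=epochs, lr=1e-3,
        batch_size=32, seed=seed, max_len=80, temperature=0.8,
    )


def train_toy_gcpg(seed: int = 0, epochs: int = 150,
                   corpus_size: int = TOY_CORPUS_SIZE):
    corpus = make_smiles_corpus(corpus_size, seed=7)
    config = toy_gcpg_config(seed=seed, epochs=epochs)
    model, trace = train_gcpg(corpus, config)
    return model, trace, corpus
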