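"""EGNN denoiser: equivariance, determinism, training/inference-path
consistency, sampling contracts."""

import numpy as np
import pytest

from cmdgen.clouds import CATEGORIES
from cmdgen.diffusion import (
    DenoiserConfig,
    EGNNDenoiser,
    RngNoise,
    build_schedule,
    load_checkpoint,
    sample_pharmacophores,
    sample_pharmacophores_batch,
    save_checkpoint,
    train_denoiser,
)
from cmdgen.nn import Tensor
from tests.conftest import random_rotation

TOY = DenoiserConfig(hidden_dim=24, n_layers=2, epochs=2, lr=1e-3, seed=3,
                     T=40, cutoff=12.0, coord_scale=4.0)


def _make_model(seed=0, config=TOY):
    return EGNNDenoiser(["C", "N", "O", "S"], config,
                        np.random.default_rng(seed))


def _rand_inputs(rng, n_lig=5, n_pkt=12):
    lig = rng.standard_normal((n_lig, 3))
    feats = rng.standard_normal((n_lig, 8))
    pkt = rng.standard_normal((n_pkt, 3)) * 2
    pkt -= pkt.mean(axis=0)
    oh = np.zeros((n_pkt, 4))
    oh[np.arange(n_pkt), rng.integers(0, 4, n_pkt)] = 1.0
    return lig, feats, pkt, oh


def test_forward_rotation_equivariance_untrained():
    """Coordinate head rotates with the input; feature head is invariant."""
    rng = np.random.default_rng(1)
    model = _make_model()
    lig, feats, pkt, oh = _rand_inputs(rng)
    ec, ef = model.forward(lig, feats, pkt, oh, 0.5)
    for _ in range(5):
        r = random_rotation(rng)
        ec_r, ef_r = model.forward(lig @ r.T, feats, pkt @ r.T, oh, 0.5)
        assert np.abs(ec_r - ec @ r.T).max() < 1e-9
        assert np.abs(ef_r - ef).max() < 1e-9


def test_training_and_inference_paths_agree():
    """The autodiff forward and the plain-numpy forward share parameters and
    must produce identical outputs."""
    rng = np.random.default_rng(2)
    model = _make_model()
    lig, feats, pkt, oh = _rand_inputs(rng)
    ec_np, ef_np = model.forward(lig, feats, pkt, oh, 0.3)
    ec_t, ef_t = model.forward(Tensor(lig), Tensor(feats), pkt, oh, 0.3)
    assert np.abs(ec_t.data - ec_np).max() < 1e-12
    assert np.abs(ef_t.data - ef_np).max() < 1e-12


def test_training_decreases_loss(toy_pairs):
    config = DenoiserConfig(hidden_dim=24, n_layers=2, epochs=8, lr=2e-3,
                            seed=1, T=40, cutoff=12.0, coord_scale=4.0)
    model, trace = train_denoiser(toy_pairs, config)
    assert len(trace) == 8
    assert trace[-1] < trace[0]
    assert model.trained


def test_training_is_seed_deterministic(toy_pairs):
    config = DenoiserConfig(hidden_dim=16, n_layers=2, epochs=3, lr=2e-3,
                            seed=7, T=40, cutoff=12.0, coord_scale=4.0)
    _, t1 = train_denoiser(toy_pairs[:8], config)
    _, t2 = train_denoiser(toy_pairs[:8], config)
    assert abs(t1[-1] - t2[-1]) < 1e-6


def test_zero_epochs_returns_initialized_model(toy_pairs):
    config = DenoiserConfig(hidden_dim=16, n_layers=2, epochs=0, seed=7,
                            T=40, cutoff=12.0, coord_scale=4.0)
    model, trace = train_denoiser(toy_pairs, config)
    fresh = EGNNDenoiser(model.pocket_alphabet, config,
                         np.random.default_rng(config.seed))
    assert trace == []
    assert not model.trained
    for a, b in zip(model.parameters(), fresh.parameters()):
        assert np.array_equal(a.data, b.data)


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        train_denoiser([], TOY)


def test_sampled_cloud_has_requested_points(toy_pairs):
    model, _ = train_denoiser(toy_pairs[:4],
                              DenoiserConfig(hidden_dim=16, n_layers=2,
                                             epochs=1, seed=0, T=20,
                                             cutoff=12.0, coord_scale=4.0))
    sch = build_schedule(20)
    cloud = sample_pharmacophores(toy_pairs[0][0], 7, model, sch,
                                  np.random.default_rng(0))
    assert len(cloud) == 7
    assert cloud.provenance == "diffusion-sampled"
    assert all(c in CATEGORIES for c in cloud.categories)


def test_sampling_invalid_n_points(toy_pairs):
    model, _ = train_denoiser(toy_pairs[:4],
                              DenoiserConfig(hidden_dim=16, n_layers=2,
                                             epochs=1, seed=0, T=20,
                                             cutoff=12.0, coord_scale=4.0))
    sch = build_schedule(20)
    with pytest.raises(ValueError, match="n_points"):
        sample_pharmacophores(toy_pairs[0][0], 0, model, sch,
                              np.random.default_rng(0))


def test_sampling_repeatable_given_seed(toy_pairs):
    model, _ = train_denoiser(toy_pairs[:4],
                              DenoiserConfig(hidden_dim=16, n_layers=2,
                                             epochs=1, seed=0, T=20,
                                             cutoff=12.0, coord_scale=4.0))
    sch = build_schedule(20)
    c1 = sample_pharmacophores(toy_pairs[0][0], 5, model, sch,
                               np.random.default_rng(11))
    c2 = sample_pharmacophores(toy_pairs[0][0], 5, model, sch,
                               np.random.default_rng(11))
    assert np.array_equal(c1.positions, c2.positions)
    assert c1.categories == c2.categories


def test_n_points_drawn_from_size_histogram(toy_pairs):
    model, _ = train_denoiser(toy_pairs[:6],
                              DenoiserConfig(hidden_dim=16, n_layers=2,
                                             epochs=1, seed=0, T=20,
                                             cutoff=12.0, coord_scale=4.0))
    sch = build_schedule(20)
    sizes = {len(c) for _, c in toy_pairs[:6]}
    cloud = sample_pharmacophores(toy_pairs[0][0], None, model, sch,
                                  np.random.default_rng(1))
    assert len(cloud) in sizes


class RotatedNoise:
    """Noise source that rotates every coordinate draw of a base stream."""

    def __init__(self, seed: int, rotation: np.ndarray):
        self.rng = np.random.default_rng(seed)
        self.r = rotation

    def coords(self, shape):
        return self.rng.standard_normal(shape) @ self.r.T

    def feats(self, shape):
        return self.rng.standard_normal(shape)


class PlainNoise:
    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def coords(self, shape):
        return self.rng.standard_normal(shape)

    def feats(self, shape):
        return self.rng.standard_normal(shape)


@pytest.mark.parametrize("trained", [False, True])
def test_sampling_chain_equivariance(toy_pairs, trained):
    """Rotating the pocket and the injected noise stream rotates the sampled
    cloud (checked through the full reverse chain)."""
    config = DenoiserConfig(hidden_dim=16, n_layers=2, epochs=2 if trained
                            else 0, lr=2e-3, seed=5, T=30, cutoff=12.0,
                            coord_scale=4.0)
    model, _ = train_denoiser(toy_pairs[:6], config)
    model.trained = True
    sch = build_schedule(30)
    pocket, _ = toy_pairs[0]
    rng = np.random.default_rng(0)
    base = sample_pharmacophores_batch(
        [pocket], [5], model, sch, np.random.default_rng(99),
        noise_source=PlainNoise(123))[0]
    from cmdgen.clouds import PocketCloud
    for trial in range(3):
        r = random_rotation(rng)
        rot_pocket = PocketCloud(
            positions=pocket.positions @ r.T, features=pocket.features,
            mode=pocket.mode, center=pocket.center @ r.T,
            radius=pocket.radius, alphabet=pocket.alphabet)
        rotated = sample_pharmacophores_batch(
            [rot_pocket], [5], model, sch, np.random.default_rng(99),
            noise_source=RotatedNoise(123, r))[0]
        assert np.abs(rotated.positions - base.positions @ r.T).max() < 1e-4
        assert rotated.categories == base.categories


def test_checkpoint_round_trip(tmp_path, toy_pairs):
    config = DenoiserConfig(hidden_dim=16, n_layers=2, epochs=1, seed=0,
                            T=20, cutoff=12.0, coord_scale=4.0)
    model, _ = train_denoiser(toy_pairs[:4], config)
    sch = build_schedule(20, config.schedule_kind)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, sch, path)
    back, sch2 = load_checkpoint(path)
    assert back.pocket_alphabet == model.pocket_alphabet
    assert back.size_histogram == model.size_histogram
    assert sch2.T == sch.T
    rng = np.random.default_rng(3)
    lig, feats = rng.standard_normal((4, 3)), rng.standard_normal((4, 8))
    pkt = rng.standard_normal((8, 3))
    oh = model.pocket_onehot(["C"] * 8)
    a = model.forward(lig, feats, pkt, oh, 0.4)
    b = back.forward(lig, feats, pkt, oh, 0.4)
    assert np.abs(a[0] - b[0]).max() < 1e-12
    assert np.abs(a[1] - b[1]).max() < 1e-12
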