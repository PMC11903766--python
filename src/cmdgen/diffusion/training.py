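"""Training and sampling for the pocket-conditioned pharmacophore diffusion
model.

Training minimizes the simplified denoising objective

    L1 = 1/2 || eps - phi_theta(z_t, pocket, t) ||^2

over uniformly drawn timesteps, with the pocket cloud as noise-free context.
Sampling runs the reverse chain from z_T ~ N(0, I) down to z_0, decoding
categories by argmax over the eight feature channels at the end.  All
coordinates are expressed in a frame centered on the pocket centroid, and
injected coordinate noise is projected to the ligand cloud's
zero-center-of-mass subspace.
"""

from __future__ import annotations

import numpy as np

from ..clouds import CATEGORIES, PharmacophoreCloud, PocketCloud
from ..nn import Adam, Tensor, clip_grad_norm
from .egnn import DenoiserConfig, EGNNDenoiser, radius_graph
from .schedule import (
    DiffusionState,
    NoiseSchedule,
    build_schedule,
    forward_noise,
    posterior_coefficients,
)

__all__ = [
    "train_denoiser",
    "sample_pharmacophores",
    "sample_pharmacophores_batch",
    "RngNoise",
    "save_checkpoint",
    "load_checkpoint",
]


class RngNoise:
    """Default standard-normal noise source; equivariance checks substitute a
    wrapper that rotates the coordinate draws."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def coords(self, shape) -> np.ndarray:
        return self.rng.standard_normal(shape)

    def feats(self, shape) -> np.ndarray:
        return self.rng.standard_normal(shape)


def _pocket_frame(pocket: PocketCloud) -> np.ndarray:
    """Translational anchor: the pocket centroid."""
    return pocket.positions.mean(axis=0)


def train_denoiser(pairs, config: DenoiserConfig | None = None,
                   schedule: NoiseSchedule | None = None):
    """Fit the EGNN noise predictor on (PocketCloud, PharmacophoreCloud)
    pairs.  Returns (model, loss_trace) with one loss value per epoch.
    Deterministic for a fixed config.seed."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    config = config or DenoiserConfig()
    schedule = schedule or build_schedule(config.T, config.schedule_kind)
    rng = np.random.default_rng(config.seed)
    alphabet = sorted({f for pocket, _ in pairs for f in pocket.features})
    model = EGNNDenoiser(alphabet, config, rng)
    for _, cloud in pairs:
        n = len(cloud)
        model.size_histogram[n] = model.size_histogram.get(n, 0) + 1

    # precompute frames and one-hots; coordinates are divided by coord_scale
    # so the chain operates near unit variance
    cs = config.coord_scale
    prepared = []
    for pocket, cloud in pairs:
        frame = _pocket_frame(pocket)
        prepared.append(
            ((pocket.positions - frame) / cs, model.pocket_onehot(pocket.features),
             (cloud.positions - frame) / cs, cloud.onehot())
        )

    opt = Adam(model.parameters(), lr=config.lr)
    trace: list[float] = []
    n_train = len(prepared)
    for epoch in range(config.epochs):
        # linear decay to 10% of the base rate over the run
        frac = epoch / max(config.epochs - 1, 1)
        lr = config.lr * (1.0 - 0.9 * frac)
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, config.batch_size):
            batch = [prepared[i] for i in order[start:start + config.batch_size]]
            loss = _batch_loss(model, batch, schedule, rng)
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(model.parameters(), config.grad_clip)
            opt.step(lr=lr)
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    model.trained = config.epochs > 0
    return model, trace


def _batch_loss(model: EGNNDenoiser, batch, schedule: NoiseSchedule,
                rng: np.random.Generator) -> Tensor:
    """Block-diagonal batched L1 loss: all ligand nodes first, then all
    pocket nodes, edges built per complex."""
    lig_coords, lig_feats, t_fracs_lig = [], [], []
    pkt_coords, pkt_onehots, t_fracs_pkt = [], [], []
    targets_c, targets_f = [], []
    sizes = []
    for pkt_xyz, pkt_oh, cloud_xyz, cloud_oh in batch:
        # timesteps biased toward the high-noise end (density ~ t^(1/2)):
        # placing the cloud relative to the pocket is learned at high t,
        # where the uniform draw under-represents the training signal
        t = int(np.ceil(schedule.T * rng.random() ** (2.0 / 3.0)))
        eps_c = rng.standard_normal(cloud_xyz.shape)
        eps_f = rng.standard_normal(cloud_oh.shape)
        z = forward_noise(DiffusionState(cloud_xyz, cloud_oh),
                          t, DiffusionState(eps_c, eps_f), schedule)
        lig_coords.append(z.coords)
        lig_feats.append(z.feats)
        targets_c.append(eps_c)
        targets_f.append(eps_f)
        pkt_coords.append(pkt_xyz)
        pkt_onehots.append(pkt_oh)
        tf = t / schedule.T
        t_fracs_lig.append(np.full(len(cloud_xyz), tf))
        t_fracs_pkt.append(np.full(len(pkt_xyz), tf))
        sizes.append((len(cloud_xyz), len(pkt_xyz)))

    lig_xyz = np.concatenate(lig_coords)
    pkt_xyz = np.concatenate(pkt_coords)
    n_lig_total = len(lig_xyz)
    # per-complex radius graphs with block offsets
    edge_blocks = []
    lig_off, pkt_off = 0, n_lig_total
    for (nl, npk), lx, px in zip(sizes, lig_coords, pkt_coords):
        local = radius_graph(
            np.concatenate([lx, px]),
            model.config.cutoff / model.config.coord_scale, n_receive=nl)
        if len(local):
            remap = np.where(local < nl, local + lig_off, local - nl + pkt_off)
            edge_blocks.append(remap)
        lig_off += nl
        pkt_off += npk
    edges = (np.concatenate(edge_blocks) if edge_blocks
             else np.zeros((0, 2), dtype=np.intp))
    pkt_edges = _pocket_edge_blocks(
        pkt_coords, model.config.pocket_cutoff / model.config.coord_scale)
    pkt_oh_all = np.concatenate(pkt_onehots)
    pkt_hidden = model.encode_pocket(pkt_xyz, pkt_oh_all, training=True,
                                     edges=pkt_edges)

    eps_c_hat, eps_f_hat = model.forward(
        Tensor(lig_xyz), Tensor(np.concatenate(lig_feats)),
        pkt_xyz, pkt_oh_all,
        np.concatenate(t_fracs_lig + t_fracs_pkt), edges=edges,
        pkt_hidden=pkt_hidden,
    )
    target_c = np.concatenate(targets_c)
    target_f = np.concatenate(targets_f)
    n_entries = target_c.size + target_f.size
    sq = ((eps_c_hat - target_c) ** 2).sum() + ((eps_f_hat - target_f) ** 2).sum()
    return sq * (0.5 / n_entries)


def sample_pharmacophores(pocket: PocketCloud, n_points: int | None,
                          model: EGNNDenoiser, schedule: NoiseSchedule,
                          rng: np.random.Generator,
                          noise_source=None) -> PharmacophoreCloud:
    """Sample one pharmacophore cloud inside `pocket` by running the reverse
    diffusion chain.  Repeatable for a fixed rng seed."""
    return sample_pharmacophores_batch(
        [pocket], [n_points], model, schedule, rng, noise_source)[0]


def sample_pharmacophores_batch(pockets, n_points_list, model: EGNNDenoiser,
                                schedule: NoiseSchedule,
                                rng: np.random.Generator,
                                noise_source=None) -> list[PharmacophoreCloud]:
    """Sample one cloud per pocket, running all reverse chains jointly
    (block-diagonal graphs, one network evaluation per timestep)."""
    noise = noise_source or RngNoise(rng)
    sizes: list[int] = []
    for n in n_points_list:
        if n is None:
            if not model.size_histogram:
                raise ValueError(
                    "n_points not given and the model has no size histogram")
            ks = sorted(model.size_histogram)
            ws = np.array([model.size_histogram[k] for k in ks], dtype=float)
            n = int(rng.choice(ks, p=ws / ws.sum()))
        if n < 1:
            raise ValueError(f"n_points must be >= 1, got {n}")
        sizes.append(int(n))

    cs = model.config.coord_scale
    frames = [_pocket_frame(p) for p in pockets]
    pkt_xyz_list = [(p.positions - f) / cs for p, f in zip(pockets, frames)]
    pkt_oh = np.concatenate([model.pocket_onehot(p.features) for p in pockets])
    pkt_xyz = np.concatenate(pkt_xyz_list)
    n_lig_total = sum(sizes)
    bounds = np.cumsum([0] + sizes)

    coords = noise.coords((n_lig_total, 3))
    feats = noise.feats((n_lig_total, len(CATEGORIES)))

    # clean-state estimates are kept inside a ball of this radius around the
    # pocket centroid (radial scaling, hence rotation-equivariant); without
    # it the 1/alpha_T amplification makes the first reverse steps blow up
    # for a weakly trained predictor
    clip_radius = max(float(np.linalg.norm(px, axis=1).max())
                      for px in pkt_xyz_list) + 10.0 / cs

    # static pocket encoding: shared by every step of the reverse chain
    pkt_edges = _pocket_edge_blocks(pkt_xyz_list,
                                    model.config.pocket_cutoff / cs)
    pkt_hidden = model.encode_pocket(pkt_xyz, pkt_oh, edges=pkt_edges)

    for t in range(schedule.T, 0, -1):
        s = t - 1
        edges = _batch_edges(coords, bounds, pkt_xyz_list, n_lig_total,
                             model.config.cutoff / cs)
        eps_c, eps_f = model.forward(coords, feats, pkt_xyz, pkt_oh,
                                     t / schedule.T, edges=edges,
                                     pkt_hidden=pkt_hidden)
        z0_c = coords / schedule.alpha[t] - (schedule.sigma[t] / schedule.alpha[t]) * eps_c
        z0_f = feats / schedule.alpha[t] - (schedule.sigma[t] / schedule.alpha[t]) * eps_f
        norms = np.linalg.norm(z0_c, axis=1, keepdims=True)
        z0_c = np.where(norms > clip_radius, z0_c * (clip_radius / norms), z0_c)
        z0_f = np.clip(z0_f, -4.0, 4.0)
        c_zt, c_z0, var = posterior_coefficients(schedule, t, s)
        std = np.sqrt(var)
        coords = (c_zt * coords + c_z0 * z0_c
                  + std * noise.coords((n_lig_total, 3)))
        feats = (c_zt * feats + c_z0 * z0_f
                 + std * noise.feats((n_lig_total, len(CATEGORIES))))

    clouds = []
    for (a, b), frame in zip(zip(bounds[:-1], bounds[1:]), frames):
        cats = np.argmax(feats[a:b], axis=1)
        clouds.append(PharmacophoreCloud.from_arrays(
            coords[a:b] * cs + frame, cats, provenance="diffusion-sampled"))
    return clouds


def _pocket_edge_blocks(pkt_coords_list, cutoff):
    """Block-diagonal pocket-pocket edge list over stacked pocket arrays."""
    blocks = []
    off = 0
    for px in pkt_coords_list:
        local = radius_graph(px, cutoff)
        if len(local):
            blocks.append(local + off)
        off += len(px)
    return np.concatenate(blocks) if blocks else np.zeros((0, 2), dtype=np.intp)


def _batch_edges(lig_coords, bounds, pkt_xyz_list, n_lig_total, cutoff):
    blocks = []
    pkt_off = n_lig_total
    for (a, b), px in zip(zip(bounds[:-1], bounds[1:]), pkt_xyz_list):
        nl = b - a
        local = radius_graph(np.concatenate([lig_coords[a:b], px]), cutoff,
                             n_receive=nl)
        if len(local):
            remap = np.where(local < nl, local + a, local - nl + pkt_off)
            blocks.append(remap)
        pkt_off += len(px)
    return np.concatenate(blocks) if blocks else np.zeros((0, 2), dtype=np.intp)


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(model: EGNNDenoiser, schedule: NoiseSchedule, path) -> None:
    """Single-file archive: weights + config + schedule + category alphabet."""
    cfg = model.config
    np.savez(
        path,
        **model.state_dict(),
        _alphabet=np.array(model.pocket_alphabet),
        _categories=np.array(CATEGORIES),
        _config=np.array([cfg.cutoff, cfg.hidden_dim, cfg.n_layers, cfg.lr,
                          cfg.batch_size, cfg.grad_clip, cfg.epochs, cfg.seed,
                          cfg.T, cfg.coord_scale, cfg.pocket_cutoff]),
        _schedule_kind=np.array(schedule.kind),
        _sizes=np.array(sorted(model.size_histogram.items())
                        if model.size_histogram else np.zeros((0, 2))),
        _trained=np.array(model.trained),
    )


def load_checkpoint(path):
    """Returns (model, schedule)."""
    with np.load(str(path) if str(path).endswith(".npz") else str(path),
                 allow_pickle=False) as z:
        raw = dict(z.items())
    c = raw.pop("_config")
    config = DenoiserConfig(
        cutoff=float(c[0]), hidden_dim=int(c[1]), n_layers=int(c[2]),
        lr=float(c[3]), batch_size=int(c[4]), grad_clip=float(c[5]),
        epochs=int(c[6]), seed=int(c[7]), T=int(c[8]), coord_scale=float(c[9]),
        pocket_cutoff=float(c[10]),
        schedule_kind=str(raw.pop("_schedule_kind")),
    )
    alphabet = [str(a) for a in raw.pop("_alphabet")]
    stored_cats = tuple(str(c) for c in raw.pop("_categories"))
    if stored_cats != CATEGORIES:
        raise ValueError("checkpoint category alphabet does not match")
    sizes = raw.pop("_sizes")
    trained = bool(raw.pop("_trained"))
    model = EGNNDenoiser(alphabet, config, np.random.default_rng(config.seed))
    model.load_state_dict(raw)
    model.size_histogram = {int(k): int(v) for k, v in np.atleast_2d(sizes)
                            if sizes.size}
    model.trained = trained
    return model, build_schedule(config.T, config.schedule_kind)
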