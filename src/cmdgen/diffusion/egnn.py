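"""E(3)-equivariant graph network used as the diffusion noise predictor.

Node features (category one-hots for the ligand cloud, element/residue
one-hots for the pocket, plus a t/T time scalar and a ligand/pocket flag) are
invariant; coordinates enter only through squared pairwise distances and
coordinate updates are linear combinations of difference vectors, so the
coordinate head is rotation-equivariant by construction and the feature head
invariant.  Pocket nodes are fixed context: their coordinates are never
updated and only ligand rows receive coordinate output.

The same forward pass runs in two modes: on autodiff tensors during training
(gradients w.r.t. parameters) and on plain numpy arrays during sampling,
where the 500-step reverse chain makes tape overhead the bottleneck.  The
two paths share the parameter objects and are checked against each other in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import expit

from ..nn import MLP, Linear, Module, Tensor
from ..nn.tensor import concat as t_concat

__all__ = ["DenoiserConfig", "EGNNDenoiser", "radius_graph"]


@dataclass
class DenoiserConfig:
    """Hyperparameters of the noise predictor and its training loop."""

    cutoff: float = 6.0          # Å, radius-graph cutoff
    hidden_dim: int = 256
    n_layers: int = 5
    lr: float = 1e-4
    batch_size: int = 16
    grad_clip: float = 1.0       # global-norm bound
    epochs: int = 100
    seed: int = 0
    schedule_kind: str = "polynomial"
    T: int = 500
    #: Å, radius of pocket-pocket message passing in the static pocket
    #: encoder; local density context (cavity rim detection) needs a shorter
    #: reach than ligand-pocket conditioning
    pocket_cutoff: float = 8.0
    #: internal coordinate normalization (Å per diffusion unit): the chain
    #: runs on coords / coord_scale so that pocket-scale geometry has roughly
    #: unit variance, matching the N(0, I) terminal distribution
    coord_scale: float = 1.0

    def __post_init__(self):
        for name in ("cutoff", "hidden_dim", "n_layers", "lr", "batch_size",
                     "grad_clip", "T", "coord_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DenoiserConfig.{name} must be positive")


def radius_graph(coords: np.ndarray, cutoff: float,
                 n_receive: int | None = None) -> np.ndarray:
    """Directed edge list (E, 2) of ordered pairs within `cutoff` Å.

    With `n_receive`, only edges whose receiving node (first column) is among
    the first `n_receive` rows are kept — the pocket is fixed context, so
    messages into pocket nodes are never needed.
    """
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=np.intp)
    edges = np.concatenate([pairs, pairs[:, ::-1]], axis=0).astype(np.intp)
    if n_receive is not None:
        edges = edges[edges[:, 0] < n_receive]
    return edges


# -- dispatch helpers: Tensor during training, numpy during sampling ---------

def _lin(layer: Linear, x):
    if isinstance(x, Tensor):
        return layer(x)
    y = x @ layer.w.data
    return y + layer.b.data if layer.b is not None else y


def _mlp(mlp: MLP, x):
    for i, layer in enumerate(mlp.layers):
        x = _lin(layer, x)
        if i < len(mlp.layers) - 1:
            if isinstance(x, Tensor):
                x = x.silu()
            else:
                x = x * expit(x)
    return x


def _cat(parts, axis=-1):
    if any(isinstance(p, Tensor) for p in parts):
        return t_concat([p if isinstance(p, Tensor) else Tensor(p) for p in parts], axis)
    return np.concatenate(parts, axis=axis)


def _gather(x, idx):
    return x.take_rows(idx) if isinstance(x, Tensor) else x[idx]


def _scatter_sum(values, idx, n):
    """Segment sum of edge values into node rows (autodiff-aware)."""
    if isinstance(values, Tensor):
        out_data = np.zeros((n, values.shape[-1]))
        np.add.at(out_data, idx, values.data)
        return values._make(out_data, (values,), lambda g: (g[idx],))
    out = np.zeros((n, values.shape[-1]))
    np.add.at(out, idx, values)
    return out


class EGNNLayer(Module):
    def __init__(self, hidden: int, cutoff: float, rng: np.random.Generator):
        # edge features: h_i, h_j and the rotation-invariant geometry
        # scalars |x_i - x_j|^2, |x_i|^2, |x_j|^2, x_i . x_j (the origin is
        # the pocket centroid — a covariant frame, so these are invariant
        # under common rotations of the whole complex)
        self.edge_mlp = MLP([2 * hidden + 4, hidden, hidden], rng)
        self.node_mlp = MLP([2 * hidden, hidden, hidden], rng, out_scale=0.1)
        self.coord_mlp = MLP([hidden, hidden, 1], rng, out_scale=1e-2)
        # second coordinate head along the neighbor's frame position x_j:
        # with the pocket centroid as (covariant) origin this lets the layer
        # express fields aligned with pocket anisotropy (e.g. the cavity
        # mouth), which pure difference vectors represent only indirectly
        self.coord_mlp_abs = MLP([hidden, hidden, 1], rng, out_scale=1e-2)
        self.cutoff = cutoff

    def __call__(self, h, x, edges: np.ndarray, n_lig: int):
        """One message-passing round.  Edges are directed into ligand nodes
        only (src < n_lig); pocket rows of h and x never change."""
        if len(edges) == 0:
            return h, x
        src, dst = edges[:, 0], edges[:, 1]
        xi, xj = _gather(x, src), _gather(x, dst)
        diff = xi - xj
        d2 = (diff**2).sum(axis=-1, keepdims=True)
        inv_c2 = 1.0 / self.cutoff**2
        ri2 = (xi**2).sum(axis=-1, keepdims=True)
        rj2 = (xj**2).sum(axis=-1, keepdims=True)
        dot = (xi * xj).sum(axis=-1, keepdims=True)
        m = _mlp(self.edge_mlp,
                 _cat([_gather(h, src), _gather(h, dst), d2 * inv_c2,
                       ri2 * inv_c2, rj2 * inv_c2, dot * inv_c2]))
        # coordinate update: sum_j (x_i - x_j)/(d_ij + 1) * phi_x(m_ij)
        #                  + sum_j x_j/(|x_j| + 1) * phi_x'(m_ij)
        w = _mlp(self.coord_mlp, m)
        w_abs = _mlp(self.coord_mlp_abs, m)
        denom = (d2 + 1e-12) ** 0.5 + 1.0
        denom_j = (rj2 + 1e-12) ** 0.5 + 1.0
        dx = _scatter_sum(diff / denom * w + xj / denom_j * w_abs, src, n_lig)
        agg = _scatter_sum(m, src, n_lig)
        h_lig = h[:n_lig] + _mlp(self.node_mlp, _cat([h[:n_lig], agg]))
        h = _cat([h_lig, h[n_lig:]], axis=0)
        x = _cat([x[:n_lig] + dx, x[n_lig:]], axis=0)
        return h, x


class PocketLayer(Module):
    """Feature-only message passing among pocket nodes (coordinates fixed).

    Enriches each pocket atom's embedding with its local geometric context
    (e.g. proximity to the cavity rim), which downstream ligand messages can
    then weight — a single ligand<-pocket hop alone can only form linearly
    weighted centroids of the pocket."""

    def __init__(self, hidden: int, cutoff: float, rng: np.random.Generator):
        self.edge_mlp = MLP([2 * hidden + 4, hidden, hidden], rng)
        self.node_mlp = MLP([2 * hidden, hidden, hidden], rng, out_scale=0.1)
        self.cutoff = cutoff

    def __call__(self, h, x: np.ndarray, edges: np.ndarray):
        if len(edges) == 0:
            return h
        src, dst = edges[:, 0], edges[:, 1]
        xi, xj = x[src], x[dst]
        d2 = ((xi - xj) ** 2).sum(axis=-1, keepdims=True)
        inv_c2 = 1.0 / self.cutoff**2
        ri2 = (xi**2).sum(axis=-1, keepdims=True)
        rj2 = (xj**2).sum(axis=-1, keepdims=True)
        dot = (xi * xj).sum(axis=-1, keepdims=True)
        m = _mlp(self.edge_mlp,
                 _cat([_gather(h, src), _gather(h, dst), d2 * inv_c2,
                       ri2 * inv_c2, rj2 * inv_c2, dot * inv_c2]))
        agg = _scatter_sum(m, src, x.shape[0])
        return h + _mlp(self.node_mlp, _cat([h, agg]))


class EGNNDenoiser(Module):
    """Noise predictor phi_theta(z_t, pocket, t) -> (eps_coords, eps_feats)."""

    N_CAT = 8

    def __init__(self, pocket_alphabet: list[str], config: DenoiserConfig,
                 rng: np.random.Generator):
        self.config = config
        self.pocket_alphabet = list(pocket_alphabet)
        h = config.hidden_dim
        # inputs: one-hot features + time scalar (ligand/pocket separated
        # by their own projections, which encodes the node flag)
        self.lig_in = Linear(self.N_CAT + 1, h, rng)
        self.pkt_in = Linear(len(pocket_alphabet), h, rng)
        self.pkt_time = Linear(1, h, rng, scale=0.1)
        self.pocket_layers = [
            PocketLayer(h, config.pocket_cutoff / config.coord_scale, rng)
            for _ in range(2)
        ]
        self.layers = [EGNNLayer(h, config.cutoff / config.coord_scale, rng)
                       for _ in range(config.n_layers)]
        self.feat_out = MLP([h, h, self.N_CAT], rng, out_scale=0.05)
        # time-dependent scalar skip on the input coordinates: the optimal
        # noise estimate contains a z_t-proportional component (~1/sigma_t on
        # the translational subspace) that message passing represents only
        # slowly; x * g(t) expresses it directly and stays equivariant
        self.coord_skip = MLP([1, 32, 1], rng, out_scale=1e-3)
        #: histogram of training-cloud sizes, filled by the trainer; used to
        #: draw n_points at sampling time when the caller passes none
        self.size_histogram: dict[int, int] = {}
        self.trained = False

    def pocket_onehot(self, features: list[str]) -> np.ndarray:
        index = {f: i for i, f in enumerate(self.pocket_alphabet)}
        h = np.zeros((len(features), len(self.pocket_alphabet)))
        for i, f in enumerate(features):
            j = index.get(f)
            if j is not None:
                h[i, j] = 1.0
        return h

    def encode_pocket(self, pkt_coords: np.ndarray, pkt_onehot: np.ndarray,
                      training: bool = False,
                      edges: np.ndarray | None = None):
        """Static pocket-atom embeddings (message passing among pocket
        nodes).  Independent of the diffusion timestep, so samplers compute
        this once per chain.  For several pockets stacked into one array,
        pass block-structured `edges` so complexes do not mix."""
        if edges is None:
            edges = radius_graph(
                pkt_coords, self.config.pocket_cutoff / self.config.coord_scale)
        h = _lin(self.pkt_in, Tensor(pkt_onehot) if training else pkt_onehot)
        for layer in self.pocket_layers:
            h = layer(h, pkt_coords, edges)
        return h

    def forward(self, lig_coords, lig_feats, pkt_coords: np.ndarray,
                pkt_onehot: np.ndarray, t_frac: float,
                edges: np.ndarray | None = None, pkt_hidden=None):
        """Predict the injected noise.

        `lig_coords`/`lig_feats` may be numpy arrays (fast inference path) or
        autodiff Tensors (training).  The radius graph is built from the
        current numpy coordinates (rebuilt by the caller every denoising
        step); pass `edges` to reuse a precomputed one and `pkt_hidden` to
        reuse the static pocket encoding.
        """
        n_lig = lig_coords.shape[0]
        lig_xyz_np = lig_coords.data if isinstance(lig_coords, Tensor) else lig_coords
        all_xyz_np = np.concatenate([lig_xyz_np, pkt_coords], axis=0)
        if edges is None:
            edges = radius_graph(all_xyz_np,
                                 self.config.cutoff / self.config.coord_scale,
                                 n_receive=n_lig)
        if np.isscalar(t_frac):
            t_all = np.full(len(all_xyz_np), float(t_frac))
        else:
            t_all = np.asarray(t_frac, dtype=np.float64).reshape(-1)
        t_lig = t_all[:n_lig, None]
        t_pkt = t_all[n_lig:, None]
        training = isinstance(lig_coords, Tensor) or isinstance(lig_feats, Tensor)
        h_lig = _lin(self.lig_in, _cat([lig_feats, t_lig]))
        if pkt_hidden is None:
            pkt_hidden = self.encode_pocket(pkt_coords, pkt_onehot, training)
        h_pkt = pkt_hidden + _lin(self.pkt_time,
                                  Tensor(t_pkt) if training else t_pkt)
        h = _cat([h_lig, h_pkt], axis=0) if isinstance(h_lig, Tensor) \
            else np.concatenate([h_lig, h_pkt], axis=0)
        x = _cat([lig_coords, pkt_coords], axis=0) \
            if isinstance(lig_coords, Tensor) else all_xyz_np.copy()
        x0 = x
        for layer in self.layers:
            h, x = layer(h, x, edges, n_lig)
        g = _mlp(self.coord_skip, Tensor(t_lig) if training else t_lig)
        eps_coords = (x - x0)[:n_lig] + lig_coords * g
        eps_feats = _mlp(self.feat_out, h[:n_lig] if isinstance(h, Tensor)
                         else h[:n_lig])
        return eps_coords, eps_feats
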