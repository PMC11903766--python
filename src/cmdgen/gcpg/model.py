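"""Pharmacophore-conditioned, property-gated SMILES generator.

A latent-variable encoder-decoder: the condition c_com combines a
pharmacophore graph embedding (distance-aware attention over feature nodes)
with a gating vector g(c_feat) built from per-property channels that are
either open (value embedded) or closed (learned null vector).  A posterior
encoder P(z | c_com, x) produces a Gaussian latent against the standard
normal prior; the decoder is an autoregressive causal-attention language
model over SMILES tokens with cross-attention into the pharmacophore memory.
A mapping head predicts, for every atom token, which pharmacophore node it
realizes (or none) — trained against the known feature-to-atom assignment.

The forward pass runs on autodiff tensors for training and on plain numpy
for generation (same parameters, dispatched on input type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ..nn import MLP, Embedding, LayerNorm, Linear, Module, Tensor
from ..nn.tensor import concat as t_concat
from .pharm_graph import GATE_CHANNELS, GatingCondition, PharmGraph
from .tokenizer import SmilesTokenizer

__all__ = ["GcpgConfig", "GcpgModel"]


@dataclass
class GcpgConfig:
    hidden_dim: int = 384
    n_blocks: int = 8
    latent_dim: int = 64
    lr: float = 3e-4
    weight_decay: float = 1e-6
    lr_period: int = 4           # epochs per cyclic cosine-annealing cycle
    epochs: int = 32
    batch_size: int = 32
    seed: int = 0
    infill_rate: float = 0.5
    max_phar: int = 8
    max_len: int = 128
    kl_warmup_frac: float = 0.1  # linear KL warm-up over first 10% of steps
    temperature: float = 1.0

    def __post_init__(self):
        if min(self.hidden_dim, self.n_blocks, self.latent_dim,
               self.max_len) <= 0:
            raise ValueError("model dimensions must be positive")
        if not 0.0 <= self.infill_rate <= 1.0:
            raise ValueError("infill_rate must lie in [0, 1]")


# -- dispatch helpers (Tensor for training, numpy for generation) ------------

def _lin(layer: Linear, x):
    if isinstance(x, Tensor):
        return layer(x)
    y = x @ layer.w.data
    return y + layer.b.data if layer.b is not None else y


def _mlp(mlp: MLP, x):
    for i, layer in enumerate(mlp.layers):
        x = _lin(layer, x)
        if i < len(mlp.layers) - 1:
            x = x.silu() if isinstance(x, Tensor) else x * expit(x)
    return x


def _ln(ln: LayerNorm, x):
    if isinstance(x, Tensor):
        return ln(x)
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + ln.eps) * ln.gamma.data + ln.beta.data


def _emb(emb: Embedding, idx, train: bool):
    """Embedding lookup: differentiable in training, raw numpy otherwise."""
    return emb(idx) if train else emb.table.data[np.asarray(idx, dtype=np.intp)]


def _softmax_np(x, axis=-1):
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax(x, axis=-1):
    if isinstance(x, Tensor):
        from ..nn.tensor import softmax as t_softmax
        return t_softmax(x, axis=axis)
    return _softmax_np(x, axis)


def _cat(parts, axis=-1):
    if any(isinstance(p, Tensor) for p in parts):
        return t_concat([p if isinstance(p, Tensor) else Tensor(p)
                         for p in parts], axis)
    return np.concatenate(parts, axis=axis)


def _bmm(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(a)
        b = b if isinstance(b, Tensor) else Tensor(b)
        return a @ b
    return a @ b


def _swap(x):
    """Transpose the last two axes."""
    if isinstance(x, Tensor):
        axes = tuple(range(x.ndim - 2)) + (x.ndim - 1, x.ndim - 2)
        return x.transpose(*axes)
    return np.swapaxes(x, -1, -2)


class Attention(Module):
    """Single-head scaled dot-product attention with additive bias/mask."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.o = Linear(dim, dim, rng, scale=0.02)
        self.scale = 1.0 / np.sqrt(dim)

    def __call__(self, x, memory=None, bias: np.ndarray | None = None):
        mem = x if memory is None else memory
        q = _lin(self.q, x)
        k = _lin(self.k, mem)
        v = _lin(self.v, mem)
        scores = _bmm(q, _swap(k)) * self.scale
        if bias is not None:
            scores = scores + bias
        att = _softmax(scores, axis=-1)
        return _lin(self.o, _bmm(att, v))


class Block(Module):
    """Pre-norm attention block (self-attention, optional cross-attention,
    feed-forward)."""

    def __init__(self, dim: int, rng: np.random.Generator, cross: bool = False):
        self.ln1 = LayerNorm(dim)
        self.attn = Attention(dim, rng)
        self.cross = Attention(dim, rng) if cross else None
        self.ln_c = LayerNorm(dim) if cross else None
        self.ln2 = LayerNorm(dim)
        self.ff = MLP([dim, 2 * dim, dim], rng, out_scale=0.02)

    def __call__(self, x, self_bias=None, memory=None, mem_bias=None):
        x = x + self.attn(_ln(self.ln1, x), bias=self_bias)
        if self.cross is not None and memory is not None:
            x = x + self.cross(_ln(self.ln_c, x), memory=memory, bias=mem_bias)
        x = x + _mlp(self.ff, _ln(self.ln2, x))
        return x


_N_RBF = 8
_RBF_CENTERS = np.linspace(0.0, 14.0, _N_RBF)
_RBF_GAMMA = 0.5


class GcpgModel(Module):
    N_CAT = 8

    def __init__(self, tokenizer: SmilesTokenizer, config: GcpgConfig,
                 rng: np.random.Generator):
        self.tokenizer = tokenizer
        self.config = config
        h, lat = config.hidden_dim, config.latent_dim
        v = tokenizer.vocab_size
        self.tok_emb = Embedding(v, h, rng)
        self.pos_emb = Embedding(config.max_len, h, rng)
        # pharmacophore graph encoder: category nodes, RBF distance bias
        self.cat_emb = Embedding(self.N_CAT + 1, h, rng)  # +1 = pad node
        self.dist_bias = Linear(_N_RBF, 1, rng)
        self.pharm_blocks = [Block(h, rng) for _ in range(2)]
        # gating channels: value embedding or learned null, + channel embedding
        self.gate_value = [Linear(1, h // 4, rng) for _ in GATE_CHANNELS]
        self.gate_null = Embedding(len(GATE_CHANNELS), h // 4, rng)
        self.gate_chan = Embedding(len(GATE_CHANNELS), h // 4, rng)
        self.gate_mlp = MLP([len(GATE_CHANNELS) * (h // 2), h, h], rng)
        # posterior encoder and latent projections
        self.enc_mlp = MLP([2 * h, h, 2 * lat], rng)
        self.z_proj = Linear(lat, h, rng)
        # decoder
        self.blocks = [Block(h, rng, cross=True)
                       for _ in range(config.n_blocks)]
        self.ln_f = LayerNorm(h)
        self.head = Linear(h, v, rng, scale=0.02)
        self.map_head = Linear(h, config.max_phar + 1, rng, scale=0.02)
        self.trained = False

    # -- condition encoders ---------------------------------------------------
    def encode_pharm(self, graphs: list[PharmGraph], train: bool = False):
        """Returns (memory (B, max_phar, H), node mask (B, max_phar))."""
        b = len(graphs)
        mp = self.config.max_phar
        cats = np.full((b, mp), self.N_CAT, dtype=np.intp)  # pad index
        dist = np.zeros((b, mp, mp))
        mask = np.zeros((b, mp), dtype=bool)
        for i, g in enumerate(graphs):
            n = min(len(g), mp)
            cats[i, :n] = g.node_categories[:n]
            dist[i, :n, :n] = g.edge_dist[:n, :n]
            mask[i, :n] = True
        x = _emb(self.cat_emb, cats, train)
        rbf = np.exp(-_RBF_GAMMA * (dist[..., None] - _RBF_CENTERS) ** 2)
        bias = _lin(self.dist_bias, Tensor(rbf) if train else rbf)
        pair_mask = (~(mask[:, None, :] & mask[:, :, None]))[..., None] * -1e9
        bias = (bias + pair_mask).reshape(b, mp, mp)
        for blk in self.pharm_blocks:
            x = blk(x, self_bias=bias)
        return x, mask

    def encode_gates(self, gatings: list[GatingCondition], train: bool = False):
        """g(c_feat): concatenated per-channel embeddings -> (B, H)."""
        b = len(gatings)
        parts = []
        for ci, ch in enumerate(GATE_CHANNELS):
            open_mask = np.array([g.is_open(ch) for g in gatings],
                                 dtype=float)[:, None]
            vals = np.array([[g.normalized(ch)] if g.is_open(ch) else [0.0]
                             for g in gatings])
            val_emb = _lin(self.gate_value[ci], Tensor(vals) if train else vals)
            ids = np.full(b, ci, dtype=np.intp)
            null_emb = _emb(self.gate_null, ids, train)
            chan_emb = _emb(self.gate_chan, ids, train)
            mixed = val_emb * open_mask + null_emb * (1.0 - open_mask)
            parts.append(_cat([mixed, chan_emb]))
        return _mlp(self.gate_mlp, _cat(parts))

    # -- posterior ------------------------------------------------------------
    def posterior(self, tokens: np.ndarray, cond, train: bool = True):
        """P(z | c_com, x): mean-pooled token embedding + condition ->
        (mu, logvar)."""
        emb = _emb(self.tok_emb, tokens, train)
        pad = tokens == self.tokenizer.pad_id
        w = (~pad).astype(float)[..., None]
        denom = np.maximum(w.sum(axis=1, keepdims=False), 1.0)
        pooled = (emb * w).sum(axis=1) * (1.0 / denom)
        out = _mlp(self.enc_mlp, _cat([pooled, cond]))
        lat = self.config.latent_dim
        return out[:, :lat], out[:, lat:]

    # -- decoder --------------------------------------------------------------
    def decode(self, tokens_in: np.ndarray, z, gate_vec, memory, mem_mask,
               train: bool = False):
        """Teacher-forced decode.  Returns (token logits, mapping logits)."""
        b, length = tokens_in.shape
        x = _emb(self.tok_emb, tokens_in, train) + _emb(
            self.pos_emb,
            np.broadcast_to(np.arange(length), (b, length)).copy(), train)
        cond = _lin(self.z_proj, z) + gate_vec
        cond_b = (cond.reshape(b, 1, self.config.hidden_dim)
                  if isinstance(cond, Tensor)
                  else cond.reshape(b, 1, -1))
        x = x + cond_b
        causal = np.triu(np.full((length, length), -1e9), k=1)[None]
        pad_keys = (tokens_in == self.tokenizer.pad_id)[:, None, :] * -1e9
        self_bias = causal + pad_keys
        mem_bias = (~mem_mask)[:, None, :] * -1e9
        for blk in self.blocks:
            x = blk(x, self_bias=self_bias, memory=memory, mem_bias=mem_bias)
        x = _ln(self.ln_f, x)
        return _lin(self.head, x), _lin(self.map_head, x)

    def condition(self, graphs, gatings, train: bool = False):
        """c_com: pharmacophore memory + pooled summary fused with the
        gating vector."""
        memory, mask = self.encode_pharm(graphs, train)
        gate_vec = self.encode_gates(gatings, train)
        w = mask[..., None].astype(float)
        denom = np.maximum(w.sum(axis=1), 1.0)
        pooled = (memory * w).sum(axis=1) * (1.0 / denom)
        cond = pooled + gate_vec
        return memory, mask, gate_vec, cond

    # -- generation (numpy fast path) ----------------------------------------
    def generate(self, graph: PharmGraph, gating: GatingCondition, n: int,
                 rng: np.random.Generator,
                 temperature: float | None = None) -> list[str]:
        """Draw n SMILES strings for one condition.  Validity is not
        guaranteed; invalid strings are returned as-is for the caller's
        metrics to count."""
        if not self.trained:
            raise ValueError("model has not been trained")
        if n == 0:
            return []
        if n < 0:
            raise ValueError("n must be >= 0")
        temp = self.config.temperature if temperature is None else temperature
        tk = self.tokenizer
        memory, mask, gate_vec, _ = self.condition([graph] * n, [gating] * n)
        z = rng.standard_normal((n, self.config.latent_dim))
        tokens = np.full((n, self.config.max_len), tk.pad_id, dtype=np.intp)
        tokens[:, 0] = tk.bos_id
        done = np.zeros(n, dtype=bool)
        length = 1
        while length < self.config.max_len and not done.all():
            logits, _ = self.decode(tokens[:, :length], z, gate_vec,
                                    memory, mask)
            last = logits[:, -1, :] / max(temp, 1e-6)
            probs = _softmax_np(last)
            # never emit pad/bos
            probs[:, tk.pad_id] = 0.0
            probs[:, tk.bos_id] = 0.0
            probs /= probs.sum(axis=1, keepdims=True)
            cum = probs.cumsum(axis=1)
            u = rng.random((n, 1))
            nxt = (cum < u).sum(axis=1)
            nxt[done] = tk.pad_id
            tokens[:, length] = nxt
            done |= nxt == tk.eos_id
            length += 1
        out = []
        for row in tokens:
            ids = []
            for i in row[1:]:
                if i in (tk.eos_id, tk.pad_id):
                    break
                ids.append(i)
            out.append(tk.detokenize(ids))
        return out
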