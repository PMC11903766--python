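"""Training loop and losses for the property-gated SMILES generator.

The objective has three terms: closed-form Gaussian KL against the N(0, I)
prior, token cross-entropy (language-model loss), and the mapping loss — a
cross-entropy on the predicted pharmacophore-node assignment of every atom
token.  Gates are randomly opened/closed per example per epoch so the model
learns both conditional and unconditional behavior for every property
channel; a linear KL warm-up over the first 10% of steps guards against
posterior collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Adam, Tensor, clip_grad_norm
from ..nn.tensor import concat as t_concat, logsumexp
from .model import GcpgConfig, GcpgModel
from .pharm_graph import (
    GATE_CHANNELS,
    GatingCondition,
    feature_cache,
    pair_from_cache,
)
from .tokenizer import SmilesTokenizer

__all__ = ["loss", "train_gcpg", "finetune_with_scores", "prepare_corpus"]


@dataclass
class _Example:
    smiles: str
    token_ids: np.ndarray        # (max_len,) with bos/eos/pad
    atom_positions: np.ndarray   # token index of each heavy atom (seq coords)
    cache: tuple                 # feature cache for graph resampling
    properties: dict             # gate channel -> value


def prepare_corpus(corpus, tokenizer: SmilesTokenizer, max_len: int,
                   properties: list[dict] | None = None) -> list[_Example]:
    """Tokenize molecules and precompute per-molecule invariants; molecules
    with fewer than two pharmacophore features are skipped (logged)."""
    from ..metrics import property_panel

    examples = []
    for i, smi in enumerate(corpus):
        try:
            cache = feature_cache(smi)
            toks = tokenizer.split(smi)
            ids = np.array(tokenizer.encode(smi, max_len), dtype=np.intp)
        except ValueError:
            continue
        # +1 for the <bos> offset
        atom_pos = np.array(tokenizer.atom_positions(toks), dtype=np.intp) + 1
        props = properties[i] if properties is not None else property_panel(smi)
        examples.append(_Example(smi, ids, atom_pos, cache, props))
    if not examples:
        raise ValueError("no trainable molecules in the corpus")
    return examples


def _sample_gating(ex: _Example, rng: np.random.Generator,
                   p_open: float = 0.5,
                   channels=GATE_CHANNELS[:-1]) -> GatingCondition:
    gates = {}
    for ch in channels:
        if ch in ex.properties and rng.random() < p_open:
            gates[ch] = float(ex.properties[ch])
    return GatingCondition(gates)


def _batch_arrays(model: GcpgModel, batch, rng: np.random.Generator,
                  gate_channels) -> dict:
    cfg = model.config
    graphs, gatings, mappings = [], [], []
    for ex in batch:
        graph, mapping = pair_from_cache(ex.cache, rng,
                                         max_phar=cfg.max_phar,
                                         infill_rate=cfg.infill_rate)
        graphs.append(graph)
        mappings.append(mapping)
        gatings.append(_sample_gating(ex, rng, channels=gate_channels))
    max_l = max(int((ex.token_ids != model.tokenizer.pad_id).sum())
                for ex in batch)
    tokens = np.stack([ex.token_ids[:max_l] for ex in batch])
    # mapping labels per input position: pharm node index, max_phar = none,
    # -1 = not an atom position (ignored)
    map_labels = np.full(tokens.shape, -1, dtype=np.intp)
    for bi, (ex, mapping) in enumerate(zip(batch, mappings)):
        atom_to_node = np.full(mapping.shape[1], cfg.max_phar, dtype=np.intp)
        for node, row in enumerate(mapping):
            hit = np.flatnonzero(row[:-1])
            if len(hit):
                atom_to_node[hit[0]] = node
        for ai, pos in enumerate(ex.atom_positions):
            if pos < max_l:
                map_labels[bi, pos] = atom_to_node[ai]
    return {"graphs": graphs, "gatings": gatings, "tokens": tokens,
            "map_labels": map_labels}


def loss(batch: dict, model: GcpgModel, rng: np.random.Generator,
         kl_weight: float = 1.0):
    """Compute (kl, lm, mapping, total) on a prepared batch.

    kl      : closed-form KL(N(mu, sigma^2) || N(0, I)), mean per example
    lm      : token cross-entropy (nats/token, teacher forcing)
    mapping : cross-entropy of atom-to-pharmacophore-node assignment
    total   : kl_weight * kl + lm + mapping
    """
    tokens = batch["tokens"]
    b, length = tokens.shape
    memory, mask, gate_vec, cond = model.condition(
        batch["graphs"], batch["gatings"], train=True)
    mu, logvar = model.posterior(tokens, cond, train=True)
    eps = rng.standard_normal(mu.shape)
    z = mu + (logvar * 0.5).exp() * eps

    kl = ((mu**2 + logvar.exp() - 1.0 - logvar) * 0.5).sum(axis=1).mean()

    logits, map_logits = model.decode(tokens[:, :-1], z, gate_vec,
                                      memory, mask, train=True)
    targets = tokens[:, 1:]
    t_mask = targets != model.tokenizer.pad_id
    bi, li = np.nonzero(t_mask)
    lse = logsumexp(logits, axis=-1)
    tok_logp = logits[bi, li, targets[bi, li]] - lse[bi, li]
    lm = -(tok_logp.sum() / max(len(bi), 1))

    labels = batch["map_labels"][:, :-1]
    mbi, mli = np.nonzero(labels >= 0)
    if len(mbi):
        mlse = logsumexp(map_logits, axis=-1)
        map_logp = map_logits[mbi, mli, labels[mbi, mli]] - mlse[mbi, mli]
        mapping = -(map_logp.sum() / len(mbi))
    else:
        mapping = Tensor(0.0)

    total = kl * kl_weight + lm + mapping
    for name, term in (("kl", kl), ("lm", lm), ("mapping", mapping)):
        if not np.isfinite(term.data).all():
            raise FloatingPointError(f"non-finite {name} loss term")
    return kl, lm, mapping, total


def _cyclic_lr(base: float, epoch: int, period: int) -> float:
    """Cyclic cosine annealing restarting every `period` epochs."""
    phase = (epoch % period) / max(period, 1)
    return 0.1 * base + 0.9 * base * 0.5 * (1.0 + np.cos(np.pi * phase))


def train_gcpg(corpus, config: GcpgConfig | None = None,
               properties: list[dict] | None = None,
               model: GcpgModel | None = None,
               gate_channels=GATE_CHANNELS[:-1]):
    """Train the gated generator on a SMILES corpus.

    Returns (model, trace) where trace is a list of per-epoch dicts with the
    mean kl/lm/mapping/total losses.  Deterministic given config.seed.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty training corpus")
    config = config or GcpgConfig()
    rng = np.random.default_rng(config.seed)
    if model is None:
        tokenizer = SmilesTokenizer()
        model = GcpgModel(tokenizer, config, rng)
    examples = prepare_corpus(corpus, model.tokenizer, model.config.max_len,
                              properties)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    n = len(examples)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    total_steps = max(config.epochs * steps_per_epoch, 1)
    warmup_steps = max(1, int(config.kl_warmup_frac * total_steps))
    step = 0
    trace = []
    for epoch in range(config.epochs):
        lr = _cyclic_lr(config.lr, epoch, config.lr_period)
        order = rng.permutation(n)
        sums = np.zeros(4)
        nb = 0
        for start in range(0, n, config.batch_size):
            batch_ex = [examples[i] for i in order[start:start + config.batch_size]]
            batch = _batch_arrays(model, batch_ex, rng, gate_channels)
            kl_w = min(1.0, step / warmup_steps)
            kl, lm, mp, total = loss(batch, model, rng, kl_weight=kl_w)
            opt.zero_grad()
            total.backward()
            clip_grad_norm(model.parameters(), 1.0)
            opt.step(lr=lr)
            sums += [float(kl.data), float(lm.data), float(mp.data),
                     float(total.data)]
            nb += 1
            step += 1
        trace.append({"kl": sums[0] / nb, "lm": sums[1] / nb,
                      "mapping": sums[2] / nb, "total": sums[3] / nb})
    model.trained = model.trained or config.epochs > 0
    return model, trace


def finetune_with_scores(model: GcpgModel, scored, config: GcpgConfig):
    """Continue training with only the DockScore gate open.

    `scored` is a list of (smiles, score_kcal_mol).  The tokenizer and
    vocabulary are reused unchanged; with config.epochs == 0 the model is
    returned as-is.
    """
    scored = list(scored)
    if not scored:
        raise ValueError("empty score table")
    if not model.trained:
        raise ValueError("finetune requires a pretrained model")
    corpus = [s for s, _ in scored]
    properties = [{"DockScore": float(v)} for _, v in scored]
    if config.epochs == 0:
        return model, []
    return train_gcpg(corpus, config, properties=properties, model=model,
                      gate_channels=("DockScore",))
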