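"""Single-file (npz) checkpointing for the gated SMILES generator."""

from __future__ import annotations

import numpy as np

from .model import GcpgConfig, GcpgModel
from .tokenizer import SmilesTokenizer

__all__ = ["save_gcpg", "load_gcpg"]


def save_gcpg(model: GcpgModel, path) -> None:
    cfg = model.config
    np.savez(
        path,
        **model.state_dict(),
        _vocab=np.array(model.tokenizer.tokens),
        _config=np.array([cfg.hidden_dim, cfg.n_blocks, cfg.latent_dim,
                          cfg.lr, cfg.weight_decay, cfg.lr_period, cfg.epochs,
                          cfg.batch_size, cfg.seed, cfg.infill_rate,
                          cfg.max_phar, cfg.max_len, cfg.kl_warmup_frac,
                          cfg.temperature]),
        _trained=np.array(model.trained),
    )


def load_gcpg(path) -> GcpgModel:
    with np.load(str(path), allow_pickle=False) as z:
        raw = dict(z.items())
    c = raw.pop("_config")
    config = GcpgConfig(
        hidden_dim=int(c[0]), n_blocks=int(c[1]), latent_dim=int(c[2]),
        lr=float(c[3]), weight_decay=float(c[4]), lr_period=int(c[5]),
        epochs=int(c[6]), batch_size=int(c[7]), seed=int(c[8]),
        infill_rate=float(c[9]), max_phar=int(c[10]), max_len=int(c[11]),
        kl_warmup_frac=float(c[12]), temperature=float(c[13]),
    )
    vocab = [str(t) for t in raw.pop("_vocab")]
    trained = bool(raw.pop("_trained"))
    tokenizer = SmilesTokenizer()
    if list(tokenizer.tokens) != vocab:
        raise ValueError("checkpoint vocabulary does not match this version")
    model = GcpgModel(tokenizer, config, np.random.default_rng(config.seed))
    model.load_state_dict(raw)
    model.trained = trained
    return model
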