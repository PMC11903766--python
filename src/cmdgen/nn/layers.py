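"""Parameter containers and standard layers on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = ["Module", "Linear", "MLP", "LayerNorm", "Embedding"]


class Module:
    """Base class: recursively collects parameters for the optimizer and
    for checkpoint (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            params.extend(_collect(v))
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None):
        s = scale if scale is not None else np.sqrt(2.0 / (n_in + n_out))
        self.w = Tensor(rng.normal(0.0, s, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class MLP(Module):
    """Two-or-more layer perceptron with SiLU activations."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 out_scale: float | None = None):
        self.layers = [
            Linear(a, b, rng, scale=(out_scale if i == len(dims) - 2 else None))
            for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.normal(0.0, 0.02, size=(n, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table.take_rows(np.asarray(idx, dtype=np.intp))
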