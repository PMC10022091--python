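"""Shared neural building blocks: parameter modules, linear maps, layer
normalization and dropout, all on the in-package autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor


class Module:
    """Base class: recursive parameter collection and a train/eval switch."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping for checkpointing."""
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays but the model has "
                f"{len(params)} parameter tensors"
            )
        for i, p in enumerate(params):
            a = arrays[f"p{i}"]
            if a.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter p{i} has shape {a.shape}, "
                    f"model expects {p.data.shape}"
                )
            p.data = a.astype(np.float64)


class Linear(Module):
    """Affine map y = xW + b (bias optional)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator):
        self.table = Parameter(rng.normal(0.0, 0.02, size=(n_vocab, d)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.table.take_rows(indices)


class LayerNorm(Module):
    """Normalize the last axis to zero mean / unit variance, then rescale."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def normalized(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5

    def __call__(self, x: Tensor) -> Tensor:
        return self.normalized(x) * self.gamma + self.beta


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            train: bool) -> Tensor:
    """Inverted dropout; identity when p == 0 or in eval mode."""
    if not train or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in train mode requires an rng")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
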