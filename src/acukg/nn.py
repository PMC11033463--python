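"""Small neural building blocks: embedding, linear, LSTM and BiLSTM.

Everything is sized for desk-scale sequence labeling (sentences of tens of
characters, vocabularies of a few hundred), runs on the in-package autodiff
engine, and is deterministic given the seed used to draw the initial weights.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, parameter, stack


class Module:
    """Base: a named container of parameter tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data
            elif isinstance(v, Module):
                for k, arr in v.state_dict().items():
                    out[f"{name}.{k}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[name], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_dict(
                    {k[len(name) + 1 :]: a for k, a in state.items() if k.startswith(name + ".")}
                )


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weight = parameter((vocab_size, dim), rng, scale=0.1)

    def __call__(self, ids) -> Tensor:
        return self.weight.take_rows(ids)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = parameter((in_dim, out_dim), rng)
        self.bias = parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTM(Module):
    """Single-direction LSTM run over a whole (n, in_dim) sequence."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, reverse: bool = False):
        self.hidden = hidden
        self.reverse = reverse
        # gate order: input, forget, cell, output (stacked along columns)
        self.w_x = parameter((in_dim, 4 * hidden), rng)
        self.w_h = parameter((hidden, 4 * hidden), rng)
        self.bias = parameter(np.zeros(4 * hidden))

    def __call__(self, xs: Tensor) -> Tensor:
        n = xs.shape[0]
        h = Tensor(np.zeros(self.hidden))
        c = Tensor(np.zeros(self.hidden))
        order = range(n - 1, -1, -1) if self.reverse else range(n)
        outs: dict[int, Tensor] = {}
        H = self.hidden
        for t in order:
            z = xs[t] @ self.w_x + h @ self.w_h + self.bias
            i = z[slice(0, H)].sigmoid()
            f = z[slice(H, 2 * H)].sigmoid()
            g = z[slice(2 * H, 3 * H)].tanh()
            o = z[slice(3 * H, 4 * H)].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h
        return stack([outs[t] for t in range(n)], axis=0)


class BiLSTM(Module):
    """Forward + backward LSTM with concatenated hidden states (n, 2*hidden)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(in_dim, hidden, rng, reverse=False)
        self.bwd = LSTM(in_dim, hidden, rng, reverse=True)

    def __call__(self, xs: Tensor) -> Tensor:
        return concat([self.fwd(xs), self.bwd(xs)], axis=1)
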