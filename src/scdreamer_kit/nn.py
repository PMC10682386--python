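"""Dense layers, multi-layer perceptrons and the ADAM optimizer.

Networks are plain pytrees of :class:`~scdreamer_kit.autodiff.Tensor`
parameters; checkpointing serializes the flat parameter dict so a reloaded
model reproduces its forward pass bit-identically.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, relu


class Dense:
    """Affine layer with Glorot-uniform weight initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Relu-activated dense stack with one or more linear output heads.

    ``heads`` maps head name -> output dimension; every head reads the last
    hidden layer.  With ``hidden=[]`` the heads act directly on the input.
    """

    def __init__(
        self,
        n_in: int,
        hidden: Sequence[int],
        heads: dict[str, int],
        rng: np.random.Generator,
        name: str = "mlp",
    ):
        self.name = name
        self.layers: list[Dense] = []
        d = n_in
        for i, h in enumerate(hidden):
            self.layers.append(Dense(d, h, rng, name=f"{name}.h{i}"))
            d = h
        self.heads = {k: Dense(d, n_out, rng, name=f"{name}.{k}") for k, n_out in heads.items()}

    def __call__(self, *inputs: Tensor) -> dict[str, Tensor]:
        x = inputs[0] if len(inputs) == 1 else concat(list(inputs), axis=-1)
        for layer in self.layers:
            x = relu(layer(x))
        return {k: head(x) for k, head in self.heads.items()}

    def parameters(self) -> list[Tensor]:
        ps = [p for layer in self.layers for p in layer.parameters()]
        for head in self.heads.values():
            ps.extend(head.parameters())
        return ps

    def named_parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            out[f"{layer.name}.W"] = layer.W.data
            out[f"{layer.name}.b"] = layer.b.data
        for head in self.heads.values():
            out[f"{head.name}.W"] = head.W.data
            out[f"{head.name}.b"] = head.b.data
        return out

    def load_named_parameters(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers + list(self.heads.values()):
            layer.W.data = np.asarray(state[f"{layer.name}.W"], dtype=np.float64)
            layer.b.data = np.asarray(state[f"{layer.name}.b"], dtype=np.float64)


class Adam:
    """ADAM with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state(self, s: dict) -> None:
        self.t = int(s["t"])
        self.m = [np.asarray(m) for m in s["m"]]
        self.v = [np.asarray(v) for v in s["v"]]
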