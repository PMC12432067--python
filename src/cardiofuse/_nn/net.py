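"""Sequential container, loss, optimizer and capture hooks for attribution."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False, capture: bool = False):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                x = layer.forward(x, training=training, capture=capture)
            else:
                x = layer.forward(x, training=training)
                if capture:
                    layer.cached_output = x
        return x

    def backward(self, dy, capture: bool = False):
        for layer in reversed(self.layers):
            if isinstance(layer, Sequential):
                dy = layer.backward(dy, capture=capture)
            else:
                if capture:
                    layer.cached_output_grad = dy
                dy = layer.backward(dy)
        return dy

    # -- parameter bookkeeping -------------------------------------------
    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer

    def named_params(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            name = f"{prefix}{i}"
            if isinstance(layer, Sequential):
                yield from layer.named_params(prefix=f"{name}.")
            else:
                for k, v in layer.params.items():
                    yield f"{name}.{k}", layer, k, v

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.iter_layers())

    def trainable_param_count(self) -> int:
        return sum(l.n_params for l in self.iter_layers() if not l.frozen)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: v.copy() for name, _, _, v in self.named_params()}
        for i, layer in enumerate(self.iter_layers()):
            if hasattr(layer, "running_mean"):
                state[f"_bnstat.{i}.mean"] = layer.running_mean.copy()
                state[f"_bnstat.{i}.var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, k, v in self.named_params():
            if name in state:
                if state[name].shape != v.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{state[name].shape} vs {v.shape}")
                layer.params[k] = state[name].astype(v.dtype).copy()
        for i, layer in enumerate(self.iter_layers()):
            if hasattr(layer, "running_mean") and f"_bnstat.{i}.mean" in state:
                layer.running_mean = state[f"_bnstat.{i}.mean"].copy()
                layer.running_var = state[f"_bnstat.{i}.var"].copy()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns (mean loss, dL/dz)."""
    z = z.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / z.size
    return float(loss), dz


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style).

    Decay applies to weight matrices only, never to biases or batch-norm
    affine parameters, and never to frozen layers."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, layer, k, p in self.model.named_params():
            if layer.frozen or k not in layer.grads:
                continue
            g = layer.grads[k].astype(p.dtype)
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
            if self.weight_decay and k == "W":
                p -= (self.lr * self.weight_decay) * p
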