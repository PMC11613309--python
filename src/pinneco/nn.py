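"""Multilayer perceptron and Adam optimiser on the autodiff tape.

The MLP is the single network type used throughout: a fully connected net
with a linear last layer, i.e. a regression model under a normality
assumption when paired with an MSE loss.  An optional leading *ensemble*
axis lets many independently initialised networks (e.g. one per
cross-validation fold and seed) train simultaneously as one batched tape:
weights have shape ``(E, n_in, n_out)`` and inputs ``(E, N, n_in)``; since
the loss is a mean of per-member terms and Adam is elementwise (and
invariant to loss scaling), this is numerically equivalent to training the
members one by one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

_ACTIVATIONS = {"tanh": ad.tanh, "relu": ad.relu, "sigmoid": ad.sigmoid, "identity": lambda x: x}


@dataclass
class MLPSpec:
    """Architecture of a fully connected network.

    ``hidden`` are the hidden-layer widths; the last layer is always linear.
    """

    input_dim: int
    hidden: tuple = (32, 32)
    output_dim: int = 1
    activation: str = "relu"

    def sizes(self):
        return (self.input_dim, *self.hidden, self.output_dim)


class MLP:
    """Fully connected network; Glorot-uniform initialisation, linear output."""

    def __init__(self, spec: MLPSpec, rng: np.random.Generator | None = None, ensemble: int | None = None):
        if spec.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {spec.activation!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        self.ensemble = ensemble
        self.weights: list[ad.Tensor] = []
        self.biases: list[ad.Tensor] = []
        sizes = spec.sizes()
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (n_in + n_out))
            wshape = (n_in, n_out) if ensemble is None else (ensemble, n_in, n_out)
            bshape = (n_out,) if ensemble is None else (ensemble, 1, n_out)
            self.weights.append(ad.Tensor(rng.uniform(-bound, bound, size=wshape), requires_grad=True))
            self.biases.append(ad.Tensor(np.zeros(bshape), requires_grad=True))

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [*self.weights, *self.biases]

    def __call__(self, x):
        """Forward pass. ``x``: (N, input_dim), or (E, N, input_dim) for ensembles."""
        h = ad.as_tensor(x)
        if h.value.shape[-1] != self.spec.input_dim:
            raise ValueError(
                f"input has {h.value.shape[-1]} features, expected {self.spec.input_dim}"
            )
        act = _ACTIVATIONS[self.spec.activation]
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.matmul(h, w) + b
            if i < n_layers - 1:
                h = act(h)
        return h

    # ----------------------------------------------------------- persistence
    def state_dict(self) -> dict:
        return {
            "spec": {
                "input_dim": self.spec.input_dim,
                "hidden": list(self.spec.hidden),
                "output_dim": self.spec.output_dim,
                "activation": self.spec.activation,
            },
            "ensemble": self.ensemble,
            "weights": [w.value.tolist() for w in self.weights],
            "biases": [b.value.tolist() for b in self.biases],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLP":
        spec = MLPSpec(
            input_dim=state["spec"]["input_dim"],
            hidden=tuple(state["spec"]["hidden"]),
            output_dim=state["spec"]["output_dim"],
            activation=state["spec"]["activation"],
        )
        net = cls(spec, rng=np.random.default_rng(0), ensemble=state.get("ensemble"))
        for w, v in zip(net.weights, state["weights"]):
            w.value = np.asarray(v, dtype=np.float64)
        for b, v in zip(net.biases, state["biases"]):
            b.value = np.asarray(v, dtype=np.float64)
        return net


class Adam:
    """Adam optimiser over a list of tape Tensors (Kingma & Ba update)."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def adam_update_array(theta, grad, state, lr, b1=0.9, b2=0.999, eps=1e-8):
    """One Adam step on a plain numpy parameter array (non-tape training loops).

    ``state`` is a dict with keys m, v, t, mutated in place.
    """
    state["t"] += 1
    state["m"] = b1 * state["m"] + (1 - b1) * grad
    state["v"] = b2 * state["v"] + (1 - b2) * grad * grad
    mhat = state["m"] / (1 - b1 ** state["t"])
    vhat = state["v"] / (1 - b2 ** state["t"])
    return theta - lr * mhat / (np.sqrt(vhat) + eps)


def fresh_adam_state(shape) -> dict:
    return {"m": np.zeros(shape), "v": np.zeros(shape), "t": 0}
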