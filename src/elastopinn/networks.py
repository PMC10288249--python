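"""Coordinate-based field networks with hand-rolled reverse mode.

Each field (displacement or elasticity) is represented by a fully
connected network mapping a material point's normalized position
(x, y) in [-1, 1]^2 to the field values at that point.  The networks
are small enough that plain numpy matrix products are fast, so forward
evaluation and backpropagation are implemented directly; gradients are
checked against numerical differentiation in the tests.

Output heads:

* displacement components use an identity head scaled by
  ``output_scale`` (an affine de-normalization to mm),
* Young's modulus uses a softplus head by default — a positivity guard
  scaled so a fresh network starts near the mean-modulus constraint
  target (a raw linear head is available via ``identity``),
* Poisson's ratio uses ``0.5 * sigmoid``, squashing the output into
  (0, 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "NetworkConfig",
    "FieldNetwork",
    "make_activation",
    "ACTIVATIONS",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# activations (value and derivative)

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _relu(x):
    return np.maximum(x, 0.0)


def _drelu(x, y):
    return (x > 0.0).astype(float)


def _dsigmoid(x, y):
    return y * (1.0 - y)


def _swish(x):
    return x * _sigmoid(x)


def _dswish(x, y):
    s = _sigmoid(x)
    return s + x * s * (1.0 - s)


def _tanh(x):
    return np.tanh(x)


def _dtanh(x, y):
    return 1.0 - y * y


#: name -> (f, df) where df takes (pre-activation, activation value)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _drelu),
    "sigmoid": (_sigmoid, _dsigmoid),
    "swish": (_swish, _dswish),
    "tanh": (_tanh, _dtanh),
}


def make_activation(name: str) -> tuple[Callable, Callable]:
    """Return (function, derivative) for a named activation."""
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


_SOFTPLUS0 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and output contract of a field network.

    ``outputs`` names the predicted quantities (1 or 2 of u_x/u_y or
    E/nu); ``output_transform`` maps each to one of ``identity``,
    ``softplus`` (positive), ``sigmoid_half`` (bounded in (0, 0.5));
    ``output_scale`` is the per-output affine scale applied after the
    transform (physical units).  Defaults follow the full-scale protocol:
    16 hidden layers, swish for displacement / relu for elasticity.
    """

    outputs: tuple[str, ...]
    depth: int = 16
    width: int = 128
    activation: str = "swish"
    output_transform: dict = field(default_factory=dict)
    output_scale: dict = field(default_factory=dict)
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.width < 1:
            raise ValueError("depth and width must be >= 1")
        if not 1 <= len(self.outputs) <= 2:
            raise ValueError("a field network predicts one or two quantities")
        make_activation(self.activation)
        for name, tr in self.output_transform.items():
            if tr not in ("identity", "softplus", "sigmoid_half"):
                raise ValueError(f"unknown output transform {tr!r} for {name}")

    def transform_for(self, name: str) -> str:
        return self.output_transform.get(name, "identity")

    def scale_for(self, name: str) -> float:
        return float(self.output_scale.get(name, 1.0))


def displacement_config(**overrides) -> NetworkConfig:
    """Default displacement network: swish hidden layers, linear heads."""
    cfg = dict(outputs=("u_x", "u_y"), activation="swish")
    cfg.update(overrides)
    return NetworkConfig(**cfg)


def elasticity_config(mean_E: float = 1.0, with_nu: bool = True, **overrides) -> NetworkConfig:
    """Default elasticity network: relu hidden layers, softplus E head
    calibrated so a fresh network's mean modulus starts near ``mean_E``,
    and a (0, 0.5)-bounded sigmoid head for Poisson's ratio."""
    outputs = ("E", "nu") if with_nu else ("E",)
    cfg = dict(
        outputs=outputs,
        activation="relu",
        output_transform={"E": "softplus", "nu": "sigmoid_half"},
        output_scale={"E": mean_E / _SOFTPLUS0},
    )
    cfg.update(overrides)
    return NetworkConfig(**cfg)


# ---------------------------------------------------------------------------
# the network

class FieldNetwork:
    """Fully connected coordinate network with explicit backprop.

    Parameters are a flat list alternating weight matrices and bias
    vectors.  ``forward`` caches the per-layer pre-activations so that
    ``backward`` can run reverse mode for arbitrary output cotangents.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        dims = [2] + [config.width] * config.depth + [len(config.outputs)]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            # fan-in-scaled Gaussian init
            self.weights.append(rng.normal(0.0, np.sqrt(1.0 / fan_in), (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._act, self._dact = make_activation(config.activation)

    # -- parameter plumbing -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        if len(params) != 2 * len(self.weights):
            raise ValueError("parameter count mismatch")
        for k in range(len(self.weights)):
            w, b = params[2 * k], params[2 * k + 1]
            if w.shape != self.weights[k].shape or b.shape != self.biases[k].shape:
                raise ValueError(
                    f"parameter shape mismatch in layer {k}: "
                    f"{w.shape}/{b.shape} vs {self.weights[k].shape}/{self.biases[k].shape}"
                )
            self.weights[k] = w.copy()
            self.biases[k] = b.copy()

    # -- evaluation ---------------------------------------------------------
    def forward(self, positions: np.ndarray, cache: dict | None = None) -> dict[str, np.ndarray]:
        """Evaluate all configured outputs at (N, 2) normalized positions.

        When ``cache`` is a dict it is filled with the intermediates
        needed by :meth:`backward`.
        """
        a = np.asarray(positions, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        pre_acts, acts = [], [a]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = a @ w + b
            a = self._act(z)
            pre_acts.append(z)
            acts.append(a)
        z_out = a @ self.weights[-1] + self.biases[-1]

        outputs: dict[str, np.ndarray] = {}
        head_grads: dict[str, np.ndarray] = {}
        for k, name in enumerate(self.config.outputs):
            raw = z_out[:, k]
            tr = self.config.transform_for(name)
            scale = self.config.scale_for(name)
            if tr == "identity":
                val, dval = raw, np.ones_like(raw)
            elif tr == "softplus":
                val = _softplus(raw)
                dval = _sigmoid(raw)
            else:  # sigmoid_half
                s = _sigmoid(raw)
                val = 0.5 * s
                dval = 0.5 * s * (1.0 - s)
            outputs[name] = scale * val
            head_grads[name] = scale * dval
        if cache is not None:
            cache.update(pre_acts=pre_acts, acts=acts, head_grads=head_grads)
        return outputs

    def evaluate_field(self, positions: np.ndarray, grid_shape: tuple[int, int] | None = None):
        """Dense evaluation; reshapes each output to ``grid_shape`` if given."""
        out = self.forward(positions)
        if grid_shape is not None:
            out = {k: v.reshape(grid_shape) for k, v in out.items()}
        return out

    def backward(self, cache: dict, grad_outputs: dict[str, np.ndarray]) -> list[np.ndarray]:
        """Reverse mode: cotangents of each output -> parameter gradients.

        ``grad_outputs`` maps output names to (N,) arrays dL/d(output);
        missing outputs contribute zero.  Returns gradients in the same
        order as :attr:`parameters`.
        """
        acts, pre_acts, head_grads = cache["acts"], cache["pre_acts"], cache["head_grads"]
        n = acts[0].shape[0]
        delta = np.zeros((n, len(self.config.outputs)))
        for k, name in enumerate(self.config.outputs):
            g = grad_outputs.get(name)
            if g is not None:
                delta[:, k] = np.ravel(g) * head_grads[name]

        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        grads_w[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        back = delta @ self.weights[-1].T
        for k in range(len(self.weights) - 2, -1, -1):
            dz = back * self._dact(pre_acts[k], acts[k + 1])
            grads_w[k] = acts[k].T @ dz
            grads_b[k] = dz.sum(axis=0)
            if k > 0:
                back = dz @ self.weights[k].T
        out: list[np.ndarray] = []
        for gw, gb in zip(grads_w, grads_b):
            out.extend((gw, gb))
        return out

    def reinitialize(self, seed: int) -> "FieldNetwork":
        """Fresh network with the same architecture and a new seed."""
        return FieldNetwork(replace(self.config, init_seed=seed))


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: FieldNetwork, path) -> None:
    """Serialize weights + config to an .npz with an embedded JSON header."""
    cfg = {
        "outputs": list(net.config.outputs),
        "depth": net.config.depth,
        "width": net.config.width,
        "activation": net.config.activation,
        "output_transform": net.config.output_transform,
        "output_scale": net.config.output_scale,
        "init_seed": net.config.init_seed,
    }
    arrays = {f"p{k}": p for k, p in enumerate(net.parameters)}
    np.savez(path, config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> FieldNetwork:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config"]).decode())
        cfg["outputs"] = tuple(cfg["outputs"])
        net = FieldNetwork(NetworkConfig(**cfg))
        params = [data[f"p{k}"] for k in range(2 * len(net.weights))]
    net.set_parameters(params)
    return net
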