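"""Neural-network building blocks on top of the autograd engine.

Layers follow the (channels, positions) convention for feature maps,
with a leading batch axis: tensors are (N, C, m).  Parameter
initialisation is variance-scaling (fan-in) and fully seedable.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, concatenate, conv1d_same,
                       conv1d_transpose_same)

ACTIVATIONS = ("ELU", "ReLU", "LeakyReLU", "PReLU")


def activation_apply(x: Tensor, name: str, alpha=None) -> Tensor:
    """Apply a named pointwise nonlinearity.

    LeakyReLU uses the fixed slope 0.01; PReLU takes a learnable
    `alpha` Tensor (slope on the negative half-line).
    """
    if name == "ELU":
        return x.elu(1.0)
    if name == "ReLU":
        return x.relu()
    if name == "LeakyReLU":
        return x.leaky_relu(0.01 if alpha is None else float(alpha))
    if name == "PReLU":
        if alpha is None or not isinstance(alpha, Tensor):
            raise ValueError("PReLU requires a learnable alpha Tensor")
        return x.maximum(0.0) + alpha * x.minimum(0.0)
    raise ValueError(f"unknown activation {name!r}; expected one of {ACTIVATIONS}")


class Module:
    """Base class: a named bag of parameters and sub-modules."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        object.__setattr__(self, key, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for mod in self._modules.values():
            out.extend(mod.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for mod_name, mod in self._modules.items():
            out.extend(mod.named_parameters(prefix + mod_name + "."))
        return out

    def regularized_parameters(self) -> list[Tensor]:
        """Kernels subject to L2 weight decay (conv/dense weights only)."""
        out = []
        for mod in self._modules.values():
            out.extend(mod.regularized_parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.data.shape)
        for name, _ in self.named_buffers():
            self.set_buffer(name, np.asarray(state[name], dtype=np.float64))

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for name in getattr(self, "_buffer_names", ()):  # leaf buffers
            out.append((prefix + name, getattr(self, name)))
        for mod_name, mod in self._modules.items():
            out.extend(mod.named_buffers(prefix + mod_name + "."))
        return out

    def set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        target = self
        for part in parts[:-1]:
            target = target._modules[part]
        object.__setattr__(target, parts[-1], value)


def _fan_in_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(1.0 / max(fan_in, 1)), size=shape)


class Conv1dSame(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 transpose: bool = False):
        super().__init__()
        if k % 2 == 0 or k < 1:
            raise ValueError("kernel width must be odd and positive")
        self.transpose = transpose
        self.weight = Tensor.param(_fan_in_init(rng, (c_out, c_in, k), c_in * k))
        self.bias = Tensor.param(np.zeros(c_out))

    def regularized_parameters(self):
        return [self.weight]

    def __call__(self, x: Tensor) -> Tensor:
        op = conv1d_transpose_same if self.transpose else conv1d_same
        return op(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, position).

    Defaults: momentum 0.99 on the running statistics, epsilon 1e-3.
    Scale/shift are trainable but excluded from L2 decay.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor.param(np.ones(channels))
        self.beta = Tensor.param(np.zeros(channels))
        object.__setattr__(self, "running_mean", np.zeros(channels))
        object.__setattr__(self, "running_var", np.ones(channels))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
            xhat = centered * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None]
            var = self.running_var[None, :, None]
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor.param(_fan_in_init(rng, (d_in, d_out), d_in))
        self.bias = Tensor.param(np.zeros(d_out))

    def regularized_parameters(self):
        return [self.weight]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Activation(Module):
    """Wraps a named activation; owns the slope parameter when PReLU."""

    def __init__(self, name: str):
        super().__init__()
        if name not in ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}")
        self.kind = name
        if name == "PReLU":
            self.alpha = Tensor.param(np.asarray(0.25))

    def __call__(self, x: Tensor) -> Tensor:
        return activation_apply(x, self.kind, getattr(self, "alpha", None))


class FusedECA(Module):
    """Fused efficient channel attention.

    Global average and global max pooling each compress the spectral
    axis to one descriptor per channel; each descriptor stream runs
    through a shared-weight 1-D convolution ALONG THE CHANNEL AXIS
    (zero-padded, with bias) and a sigmoid, and the two attention maps
    are fused by elementwise maximum before rescaling the input map.
    With ``fused=False`` the max-pooling branch is skipped and the block
    degrades to plain GAP-only ECA (the ablation variant).
    """

    def __init__(self, kernel_size: int, rng: np.random.Generator, fused: bool = True):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("ECA kernel size must be odd and >= 1")
        self.kernel_size = kernel_size
        self.fused = fused
        self.gap_weight = Tensor.param(_fan_in_init(rng, (1, 1, kernel_size), kernel_size))
        self.gap_bias = Tensor.param(np.zeros(1))
        self.gmp_weight = Tensor.param(_fan_in_init(rng, (1, 1, kernel_size), kernel_size))
        self.gmp_bias = Tensor.param(np.zeros(1))

    def attention(self, x: Tensor) -> Tensor:
        """Channel attention weights s in (0,1), shape (N, C)."""
        z_gap = x.mean(axis=2)                                   # (N, C)
        s = conv1d_same(z_gap.reshape(z_gap.shape[0], 1, -1),
                        self.gap_weight, self.gap_bias).sigmoid()
        s = s.reshape(z_gap.shape)
        if self.fused:
            z_gmp = x.max(axis=2)
            s_gmp = conv1d_same(z_gmp.reshape(z_gmp.shape[0], 1, -1),
                                self.gmp_weight, self.gmp_bias).sigmoid()
            s = s.maximum(s_gmp.reshape(z_gmp.shape))
        return s

    def __call__(self, x: Tensor) -> Tensor:
        s = self.attention(x)
        return x * s.reshape(s.shape[0], s.shape[1], 1)


class SpectralResidualGate(Module):
    """Adaptive residual gate.

    At every spectral position i the channel vectors of the trunk x and
    the residual r are concatenated (2C), pushed through a 2C -> h_d -> C
    -> 1 MLP, and squashed to a scalar gate g(i) in (0,1).  The output is
    x + alpha * g * r with alpha a learnable global scalar (init 1).  The
    MLP has biases on the first two layers only, so the initial gate
    logit is centred (gate 0.5).
    """

    def __init__(self, channels: int, hidden_dim: int, rng: np.random.Generator,
                 activation: str = "ELU", alpha_init: float = 1.0,
                 global_gate: bool = False):
        super().__init__()
        if hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        c = channels
        self.act = Activation(activation)
        self.w1 = Tensor.param(_fan_in_init(rng, (2 * c, hidden_dim), 2 * c))
        self.b1 = Tensor.param(np.zeros(hidden_dim))
        self.w2 = Tensor.param(_fan_in_init(rng, (hidden_dim, c), hidden_dim))
        self.b2 = Tensor.param(np.zeros(c))
        self.w3 = Tensor.param(_fan_in_init(rng, (c, 1), c))
        self.alpha = Tensor.param(np.asarray(float(alpha_init)))
        self.global_gate = global_gate

    def gate(self, x: Tensor, r: Tensor) -> Tensor:
        """Position-wise gate values, shape (N, 1, m).

        The per-position MLP is evaluated as a stack of width-1
        convolutions, which keeps the (N, *, m) layout contiguous.
        """
        n, c, m = x.shape
        h_d = self.w1.shape[1]
        z = concatenate([x, r], axis=1)                  # (N, 2C, m)
        k1 = self.w1.transpose((1, 0)).reshape(h_d, 2 * c, 1)
        h = self.act(conv1d_same(z, k1, self.b1))        # (N, h_d, m)
        k2 = self.w2.transpose((1, 0)).reshape(c, h_d, 1)
        h = conv1d_same(h, k2, self.b2)                  # (N, C, m)
        k3 = self.w3.transpose((1, 0)).reshape(1, c, 1)
        g = conv1d_same(h, k3).sigmoid()                 # (N, 1, m)
        if self.global_gate:
            g = g.mean(axis=2, keepdims=True)
        return g

    def __call__(self, x: Tensor, r: Tensor) -> Tensor:
        if x.shape != r.shape:
            raise ValueError(f"trunk/residual shape mismatch: {x.shape} vs {r.shape}")
        return x + self.alpha * self.gate(x, r) * r
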