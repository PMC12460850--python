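"""Reference semantics of the two attention/gating blocks.

These functions operate on plain NumPy feature maps of shape (C, m)
— channels by spectral positions — with explicitly supplied parameters,
and define the exact contract of the fused channel-attention block and
the spectral residual gate.  The trainable layers in :mod:`.nn` realise
the same computation inside the autograd graph; both routes are checked
against each other and against straight-line transcriptions in the
test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ECAConfig", "SRGConfig",
    "gap_descriptor", "gmp_descriptor", "eca_branch", "fuse_attention",
    "fused_eca_forward", "srg_forward",
]


@dataclass(frozen=True)
class ECAConfig:
    """Channel-attention settings: odd conv kernel over the channel axis."""
    kernel_size: int = 5
    fused: bool = True

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("ECA kernel_size must be odd and >= 1")


@dataclass(frozen=True)
class SRGConfig:
    """Residual-gate settings: MLP width, initial global scale, activation."""
    hidden_dim: int = 92
    alpha_init: float = 1.0
    activation: str = "ELU"

    def __post_init__(self):
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")


def _check_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("feature map must be 2-D (channels x positions)")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite entries")
    return x


def gap_descriptor(x: np.ndarray) -> np.ndarray:
    """Global average pooling over the spectral axis: z_k = mean_i x_k(i)."""
    return _check_map(x).mean(axis=1)


def gmp_descriptor(x: np.ndarray) -> np.ndarray:
    """Global max pooling over the spectral axis: z_k = max_i x_k(i)."""
    return _check_map(x).max(axis=1)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def eca_branch(z: np.ndarray, weights: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Attention from one pooled descriptor.

    The length-C descriptor is treated as a 1-D sequence over the
    channel axis and cross-correlated with a single shared kernel of odd
    width K under zero "same" padding, then shifted by `bias` and passed
    through a sigmoid.  Output entries lie strictly in (0, 1).
    """
    z = np.asarray(z, dtype=float).reshape(-1)
    w = np.asarray(weights, dtype=float).reshape(-1)
    if w.size % 2 == 0:
        raise ValueError("ECA kernel width must be odd")
    pad = (w.size - 1) // 2
    zp = np.pad(z, pad)
    conv = np.array([np.dot(w, zp[i:i + w.size]) for i in range(z.size)])
    return _sigmoid(conv + float(bias))


def fuse_attention(s_gap: np.ndarray, s_gmp: np.ndarray) -> np.ndarray:
    """Fuse the two branch attention maps by elementwise maximum."""
    s_gap = np.asarray(s_gap, dtype=float)
    s_gmp = np.asarray(s_gmp, dtype=float)
    if s_gap.shape != s_gmp.shape:
        raise ValueError("attention vectors must have equal length")
    return np.maximum(s_gap, s_gmp)


def fused_eca_forward(x: np.ndarray, cfg: ECAConfig,
                      gap_kernel: np.ndarray, gap_bias: float,
                      gmp_kernel: np.ndarray | None = None,
                      gmp_bias: float = 0.0) -> np.ndarray:
    """Recalibrate a (C, m) feature map by fused channel attention.

    With ``cfg.fused`` false, the max-pooling branch is skipped and the
    attention is the GAP branch alone (plain-ECA ablation variant).
    """
    x = _check_map(x)
    s = eca_branch(gap_descriptor(x), gap_kernel, gap_bias)
    if cfg.fused:
        if gmp_kernel is None:
            raise ValueError("fused variant requires the GMP-branch kernel")
        s = fuse_attention(s, eca_branch(gmp_descriptor(x), gmp_kernel, gmp_bias))
    return s[:, None] * x


def _activation(v: np.ndarray, name: str) -> np.ndarray:
    if name == "ELU":
        return np.where(v >= 0, v, np.exp(np.minimum(v, 0.0)) - 1.0)
    if name == "ReLU":
        return np.maximum(v, 0.0)
    if name == "LeakyReLU":
        return np.where(v >= 0, v, 0.01 * v)
    raise ValueError(f"unsupported SRG activation {name!r}")


def srg_forward(x: np.ndarray, r: np.ndarray, cfg: SRGConfig,
                w1: np.ndarray, b1: np.ndarray, w2: np.ndarray,
                b2: np.ndarray, w3: np.ndarray, alpha: float) -> np.ndarray:
    """Gated residual addition on a (C, m) map pair.

    Per spectral position i the concatenated channel vector [x(:,i); r(:,i)]
    runs through the 2C -> h_d -> C -> 1 MLP and a sigmoid, giving a
    scalar gate g(i) in (0,1); the output is x(:,i) + alpha * g(i) * r(:,i).
    """
    x = _check_map(x)
    r = _check_map(r)
    if x.shape != r.shape:
        raise ValueError(f"trunk/residual shape mismatch: {x.shape} vs {r.shape}")
    c, m = x.shape
    w1 = np.asarray(w1, float)
    if w1.shape != (2 * c, cfg.hidden_dim):
        raise ValueError("W1 must be (2C, hidden_dim)")
    out = np.empty_like(x)
    for i in range(m):
        v = np.concatenate([x[:, i], r[:, i]])
        h = _activation(v @ w1 + b1, cfg.activation)
        logit = ((h @ w2 + b2) @ w3).item()
        g = _sigmoid(np.array(logit))
        out[:, i] = x[:, i] + alpha * g * r[:, i]
    return out
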