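"""SpecFuseNet architecture assembly.

The network is a 1-D convolutional autoencoder with a classification
head on the shared latent code:

* encoder: three blocks (1 -> 32 -> 16 -> 8 channels), each
  Conv1D(k=3, same) -> BN -> activation -> FusedECA -> SRG, where the
  SRG residual is the block input projected to the block's channel
  count by a width-1 convolution;
* decoder: the mirror image (8 -> 16 -> 32) with transposed
  convolutions and the same attention/gating blocks, then an output
  transposed-conv block back to 1 channel;
* classifier: Flatten -> Dense(128, activation, L2) -> Dense(K, softmax).

All layers preserve the spectral length m (stride 1, same padding), so
the latent code is (8, m) — 2648 features for the default 331-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attention import ECAConfig, SRGConfig
from .autograd import Tensor
from .nn import (Activation, BatchNorm1d, Conv1dSame, Dense, FusedECA, Module,
                 SpectralResidualGate)

__all__ = ["ModelConfig", "SpecFuseNet", "EncoderBlock",
           "build_encoder", "build_decoder", "build_classifier",
           "build_specfusenet", "softmax"]


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter in one validated record."""

    filters: tuple[int, ...] = (32, 16, 8)
    out_filters: int = 1
    kernel_size: int = 3
    activation: str = "ELU"
    eca: ECAConfig = field(default_factory=ECAConfig)
    srg: SRGConfig = field(default_factory=SRGConfig)
    dense_units: int = 128
    num_classes: int = 2
    l2_lambda: float = 0.01
    use_eca: bool = True
    use_srg: bool = True
    use_attention_in_decoder: bool = True
    srg_global_gate: bool = False
    linear_output: bool = False  # drop BN+activation after the last deconv

    def __post_init__(self):
        if not self.filters or any(f < 1 for f in self.filters):
            raise ValueError("filters must be a nonempty tuple of positive counts")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        object.__setattr__(self, "filters", tuple(self.filters))


class EncoderBlock(Module):
    """Conv/deconv -> BN -> activation -> [FusedECA] -> [SRG(block input)]."""

    def __init__(self, c_in: int, c_out: int, cfg: ModelConfig,
                 rng: np.random.Generator, transpose: bool,
                 with_attention: bool, with_bn_act: bool = True):
        super().__init__()
        self.conv = Conv1dSame(c_in, c_out, cfg.kernel_size, rng, transpose=transpose)
        self.with_bn_act = with_bn_act
        if with_bn_act:
            self.bn = BatchNorm1d(c_out)
            self.act = Activation(cfg.activation)
        self.use_eca = cfg.use_eca and with_attention
        self.use_srg = cfg.use_srg and with_attention
        if self.use_eca:
            self.eca = FusedECA(cfg.eca.kernel_size, rng, fused=cfg.eca.fused)
        if self.use_srg:
            self.srg = SpectralResidualGate(
                c_out, cfg.srg.hidden_dim, rng, activation=cfg.srg.activation,
                alpha_init=cfg.srg.alpha_init, global_gate=cfg.srg_global_gate)
            if c_in != c_out:
                self.proj = Conv1dSame(c_in, c_out, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.with_bn_act:
            y = self.act(self.bn(y))
        if self.use_eca:
            y = self.eca(y)
        if self.use_srg:
            r = self.proj(x) if hasattr(self, "proj") else x
            y = self.srg(y, r)
        return y


class _Sequential(Module):
    def __init__(self, blocks: list[Module]):
        super().__init__()
        for i, b in enumerate(blocks):
            setattr(self, f"block{i}", b)
        self.n_blocks = len(blocks)

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(self.n_blocks):
            x = getattr(self, f"block{i}")(x)
        return x


def build_encoder(cfg: ModelConfig, seed: int = 0) -> _Sequential:
    rng = np.random.default_rng(seed)
    blocks, c_in = [], 1
    for c_out in cfg.filters:
        blocks.append(EncoderBlock(c_in, c_out, cfg, rng, transpose=False,
                                   with_attention=True))
        c_in = c_out
    return _Sequential(blocks)


def build_decoder(cfg: ModelConfig, seed: int = 0) -> _Sequential:
    rng = np.random.default_rng(seed)
    widths = tuple(reversed(cfg.filters))
    blocks, c_in = [], widths[0]
    for c_out in widths[1:]:
        blocks.append(EncoderBlock(c_in, c_out, cfg, rng, transpose=True,
                                   with_attention=cfg.use_attention_in_decoder))
        c_in = c_out
    blocks.append(EncoderBlock(c_in, cfg.out_filters, cfg, rng, transpose=True,
                               with_attention=False,
                               with_bn_act=not cfg.linear_output))
    return _Sequential(blocks)


class _Classifier(Module):
    def __init__(self, cfg: ModelConfig, latent_len: int, rng: np.random.Generator):
        super().__init__()
        self.dense1 = Dense(latent_len, cfg.dense_units, rng)
        self.act = Activation(cfg.activation)
        self.dense2 = Dense(cfg.dense_units, cfg.num_classes, rng)

    def __call__(self, latent_flat: Tensor) -> Tensor:
        return softmax(self.dense2(self.act(self.dense1(latent_flat))))


def softmax(logits: Tensor) -> Tensor:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


def build_classifier(cfg: ModelConfig, latent_len: int, seed: int = 0) -> _Classifier:
    return _Classifier(cfg, latent_len, np.random.default_rng(seed))


class SpecFuseNet(Module):
    """Shared encoder feeding a reconstruction decoder and a softmax head."""

    def __init__(self, cfg: ModelConfig, n_features: int, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.n_features = n_features
        self.latent_len = cfg.filters[-1] * n_features
        # independent per-component seeds derived from the build seed
        sub = np.random.SeedSequence(seed).generate_state(3) % (2**31)
        self.encoder = build_encoder(cfg, int(sub[0]))
        self.decoder = build_decoder(cfg, int(sub[1]))
        self.classifier = build_classifier(cfg, self.latent_len, int(sub[2]))

    def encode(self, x: Tensor) -> Tensor:
        """Latent feature map (N, C_last, m)."""
        return self.encoder(x)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (reconstruction (N,1,m), class probabilities (N,K))."""
        latent = self.encode(x)
        recon = self.decoder(latent)
        flat = latent.reshape(latent.shape[0], self.latent_len)
        probs = self.classifier(flat)
        return recon, probs

    def l2_penalty(self) -> Tensor:
        """lambda * sum of squared conv/dense kernel entries."""
        total = Tensor(0.0)
        for w in self.regularized_parameters():
            total = total + (w * w).sum()
        return total * self.cfg.l2_lambda


def build_specfusenet(cfg: ModelConfig, n_features: int, seed: int = 0) -> SpecFuseNet:
    return SpecFuseNet(cfg, n_features, seed)
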