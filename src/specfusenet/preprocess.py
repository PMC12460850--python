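"""Spectral preprocessing: SG derivative, standardization, stratified folds.

The default pipeline matches common chemometric practice: a
Savitzky-Golay first derivative (window 5 points, quadratic local
polynomial) that removes additive baseline offsets while smoothing
noise, followed by per-wavelength standardization to zero mean and unit
variance fitted on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SGConfig", "PreprocessState", "FoldSplit",
    "sg_derivative", "fit_standardizer", "apply_preprocess",
    "stratified_kfold", "NIRPreprocessor",
]

_STD_FLOOR = 1e-12


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay settings: odd window, polynomial order, derivative order."""

    window: int = 5
    polyorder: int = 2
    deriv_order: int = 1
    delta: float = 1.0  # grid step in nm; 1.0 -> per-index derivative

    def __post_init__(self):
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and greater than polyorder")
        if self.deriv_order > self.polyorder:
            raise ValueError("derivative order cannot exceed polynomial order")
        if self.delta <= 0:
            raise ValueError("grid step must be positive")


@dataclass(frozen=True)
class PreprocessState:
    """Fitted per-column statistics of the SG-transformed training matrix."""

    feature_means: np.ndarray
    feature_stds: np.ndarray
    sg: SGConfig | None

    def __post_init__(self):
        object.__setattr__(self, "feature_means", np.asarray(self.feature_means, float))
        object.__setattr__(self, "feature_stds", np.asarray(self.feature_stds, float))
        if np.any(self.feature_stds <= 0):
            raise ValueError("stored stds must be strictly positive")


def sg_derivative(spectra: np.ndarray, cfg: SGConfig) -> np.ndarray:
    """Row-wise SG-smoothed derivative, scaled per grid step.

    Edge points are handled by evaluating the one-sided local polynomial
    fit (polynomial-extension mode), so output length equals input length.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] < cfg.window:
        raise ValueError(
            f"need at least window={cfg.window} spectral points, got {spectra.shape[1]}")
    return savgol_filter(spectra, cfg.window, cfg.polyorder,
                         deriv=cfg.deriv_order, delta=cfg.delta,
                         axis=1, mode="interp")


def fit_standardizer(train_spectra: np.ndarray, sg: SGConfig | None) -> PreprocessState:
    """Fit per-column mean/std (population) of the SG-transformed matrix.

    Dead channels (std < 1e-12 after the derivative) get std 1 so the
    transform never divides by zero.
    """
    x = np.atleast_2d(np.asarray(train_spectra, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("standardizer needs at least 2 training rows")
    if sg is not None:
        x = sg_derivative(x, sg)
    means = x.mean(axis=0)
    stds = x.std(axis=0)  # population (divide by n)
    stds = np.where(stds < _STD_FLOOR, 1.0, stds)
    return PreprocessState(means, stds, sg)


def apply_preprocess(spectra: np.ndarray, state: PreprocessState) -> np.ndarray:
    """SG derivative then columnwise (x - mean) / std.  Pure function."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] != state.feature_means.size:
        raise ValueError(
            f"expected {state.feature_means.size} columns, got {x.shape[1]}")
    if state.sg is not None:
        x = sg_derivative(x, state.sg)
    return (x - state.feature_means) / state.feature_stds


class NIRPreprocessor(BaseEstimator, TransformerMixin):
    """sklearn transformer: SG derivative + standardization.

    Parameters
    ----------
    window, polyorder, deriv : SG filter settings (window must be odd).
    delta : wavelength step in nm used to scale the derivative.
    apply_sg : set False for a standardize-only pipeline.
    """

    def __init__(self, window: int = 5, polyorder: int = 2, deriv: int = 1,
                 delta: float = 1.0, apply_sg: bool = True):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta
        self.apply_sg = apply_sg

    def _sg_config(self) -> SGConfig | None:
        if not self.apply_sg:
            return None
        return SGConfig(self.window, self.polyorder, self.deriv, self.delta)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.state_ = fit_standardizer(X, self._sg_config())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "state_"):
            raise RuntimeError("NIRPreprocessor is not fitted")
        return apply_preprocess(np.asarray(X, dtype=float), self.state_)


@dataclass(frozen=True)
class FoldSplit:
    """k disjoint row-index lists covering all rows, class-stratified."""

    k: int
    folds: tuple[np.ndarray, ...]
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[fold]
        train = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return np.sort(train), np.sort(test)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Deterministic stratified k-fold split.

    Each class's rows are shuffled with the seed and dealt round-robin
    across folds, so per-fold class counts stay within one of the
    proportional share.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n={n}]")
    counts = np.bincount(labels)
    if np.any((counts > 0) & (counts < k)):
        warnings.warn(f"some classes have fewer than k={k} members; "
                      "those classes will be absent from some folds",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    buckets: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in np.unique(labels):
        rows = np.nonzero(labels == cls)[0]
        rows = rng.permutation(rows)
        # rotate the starting fold per class so small classes spread evenly
        for i, row in enumerate(rows):
            buckets[(start + i) % k].append(int(row))
        start = (start + rows.size) % k
    folds = tuple(np.array(sorted(b), dtype=int) for b in buckets)
    return FoldSplit(k, folds, seed)
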