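"""Chemometric and deep baselines: PCA + classic classifiers, encoder
features + classic classifiers, a dense autoencoder, a sparse
convolutional autoencoder, and the module-ablation harness.

PCA is computed from first principles (mean-centering, 1/(n-1)
covariance, eigendecomposition) with a deterministic sign convention;
the classic classifiers are configured established implementations
(scikit-learn SVM/RF, xgboost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .autograd import Tensor
from .network import ModelConfig
from .nn import Activation, Dense, Module
from .preprocess import NIRPreprocessor, stratified_kfold
from .spectra import SpectralDataset
from .training import (EvalReport, SpecFuseNetClassifier,
                       confusion_from_predictions, _aggregate_reports)

__all__ = [
    "PCAState", "pca_fit", "pca_transform", "SpectralPCA",
    "ClassicClassifierConfig", "classic_fit_predict",
    "pca_pipeline", "encoder_feature_pipeline",
    "DenseAutoencoderClassifier", "SparseConvAutoencoderClassifier",
    "SparsityConfig", "run_ablation", "ABLATION_VARIANTS",
]


# ---------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PCAState:
    """Fitted PCA: mean, top-k orthonormal components, eigenvalues."""

    mean: np.ndarray
    components: np.ndarray      # (m, k), columns are eigenvectors
    eigenvalues: np.ndarray     # (k,), nonincreasing

    @property
    def k(self) -> int:
        return self.components.shape[1]


def pca_fit(X: np.ndarray, k) -> PCAState:
    """Principal components of X (n x m) by covariance eigendecomposition.

    `k` is either the number of components or a fraction in (0, 1): the
    smallest k whose explained-variance ratio reaches that fraction.
    Each component's largest-magnitude coordinate is made positive for
    reproducible score signs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, m = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    xc = X - mean
    cov = (xc.T @ xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    if isinstance(k, float) and 0 < k < 1:
        ratio = np.cumsum(evals) / max(evals.sum(), np.finfo(float).tiny)
        k = int(np.searchsorted(ratio, k) + 1)
    k = int(k)
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}]")
    comps = evecs[:, :k].copy()
    flip = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(k)])
    comps *= np.where(flip == 0, 1.0, flip)
    return PCAState(mean, comps, evals[:k])


def pca_transform(X: np.ndarray, state: PCAState) -> np.ndarray:
    """Scores Z = (X - mu) V_k."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != state.mean.size:
        raise ValueError(f"expected {state.mean.size} features, got {X.shape[1]}")
    return (X - state.mean) @ state.components


class SpectralPCA(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper over :func:`pca_fit` / :func:`pca_transform`.

    ``n_components`` may be an integer or an explained-variance fraction
    (default 0.99).
    """

    def __init__(self, n_components=0.99):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.state_ = pca_fit(X, self.n_components)
        self.n_features_in_ = np.asarray(X).shape[1]
        self.explained_variance_ = self.state_.eigenvalues
        self.components_ = self.state_.components.T
        self.mean_ = self.state_.mean
        return self

    def transform(self, X):
        return pca_transform(X, self.state_)


# ---------------------------------------------------------------------
# classic classifiers
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ClassicClassifierConfig:
    """Named classic classifier with the reference hyperparameters."""

    kind: str = "svm_linear"
    params: dict = field(default_factory=dict)


def _make_classic(kind: str, seed: int):
    if kind == "svm_linear":
        return SVC(kernel="linear", C=0.1, max_iter=200, class_weight="balanced",
                   random_state=seed)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, max_iter=200, class_weight="balanced",
                   random_state=seed)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=200, class_weight="balanced",
                                      random_state=seed)
    if kind == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(objective="multi:softmax", n_estimators=200,
                             learning_rate=0.1, random_state=seed, verbosity=0)
    raise ValueError(f"unknown classifier kind {kind!r}")


def classic_fit_predict(X_train, y_train, X_test, kind: str = "svm_linear",
                        seed: int = 0) -> np.ndarray:
    """Fit one of {svm_linear, svm_rbf, rf, xgb} and predict the test rows."""
    y_train = np.asarray(y_train, int)
    if np.unique(y_train).size == 1:
        return np.full(np.asarray(X_test).shape[0], y_train[0])
    clf = _make_classic(kind, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if kind == "xgb":
            # xgboost requires contiguous 0..K-1 encoding and, with the
            # multi:softmax objective, an explicit class count
            classes, y_enc = np.unique(y_train, return_inverse=True)
            clf.set_params(num_class=classes.size)
            clf.fit(np.asarray(X_train), y_enc)
            return classes[clf.predict(np.asarray(X_test)).astype(int)]
        clf.fit(np.asarray(X_train), y_train)
        return clf.predict(np.asarray(X_test))


# ---------------------------------------------------------------------
# feature-extraction pipelines (shared fold harness)
# ---------------------------------------------------------------------

def _feature_cv(ds: SpectralDataset, featurize, kind: str, k: int,
                seed: int) -> EvalReport:
    """Generic k-fold loop: preprocess, featurize, classic classify."""
    split = stratified_kfold(ds.labels, k=k, seed=seed)
    fold_reports = []
    for fold in range(k):
        tr, te = split.train_test(fold)
        pre = NIRPreprocessor(delta=ds.grid.step)
        X_tr = pre.fit_transform(ds.spectra[tr])
        X_te = pre.transform(ds.spectra[te])
        F_tr, F_te = featurize(fold, X_tr, ds.labels[tr], X_te)
        y_pred = classic_fit_predict(F_tr, ds.labels[tr], F_te, kind, seed)
        cm = confusion_from_predictions(ds.labels[te], y_pred, ds.n_classes)
        rep = EvalReport.from_confusion(cm)
        rep.meta = {"fold": fold}
        fold_reports.append(rep)
    return _aggregate_reports(fold_reports, {"k": k, "seed": seed, "classifier": kind})


def pca_pipeline(ds: SpectralDataset, kind: str = "svm_linear",
                 n_components=0.99, k: int = 5, seed: int = 0) -> EvalReport:
    """PCA features + classic classifier under stratified k-fold CV."""

    def featurize(fold, X_tr, y_tr, X_te):
        pca = SpectralPCA(n_components).fit(X_tr)
        return pca.transform(X_tr), pca.transform(X_te)

    rep = _feature_cv(ds, featurize, kind, k, seed)
    rep.meta["features"] = f"pca({n_components})"
    return rep


def encoder_feature_pipeline(ds: SpectralDataset, kind: str = "svm_linear",
                             k: int = 5, seed: int = 0,
                             **estimator_params) -> EvalReport:
    """Latent encoder features + classic classifier, leakage-free.

    The network is trained inside each fold on that fold's training rows
    only; its flattened latent code then feeds the classic classifier.
    """
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)

    def featurize(fold, X_tr, y_tr, X_te):
        est = SpecFuseNetClassifier(random_state=int(fold_seeds[fold]),
                                    **estimator_params)
        est.fit(X_tr, y_tr)
        return est.transform(X_tr), est.transform(X_te)

    rep = _feature_cv(ds, featurize, kind, k, seed)
    rep.meta["features"] = "encoder-latent"
    return rep


# ---------------------------------------------------------------------
# dense autoencoder baseline
# ---------------------------------------------------------------------

class _DenseAE(Module):
    """Fully connected autoencoder m -> 256 -> 128 -> 64 -> ... -> m,
    with the shared classifier head on the 64-d latent code.

    The layer sizes are this package's own choice for a plain-AE
    comparison point; they are reported in every output that uses them.
    """

    def __init__(self, m: int, num_classes: int, activation: str,
                 rng: np.random.Generator, hidden=(256, 128), latent: int = 64,
                 dense_units: int = 128):
        super().__init__()
        sizes = [m, *hidden, latent]
        self.n_enc = len(sizes) - 1
        for i in range(self.n_enc):
            setattr(self, f"enc{i}", Dense(sizes[i], sizes[i + 1], rng))
        rev = list(reversed(sizes))
        for i in range(self.n_enc):
            setattr(self, f"dec{i}", Dense(rev[i], rev[i + 1], rng))
        self.act = Activation(activation)
        self.head1 = Dense(latent, dense_units, rng)
        self.head2 = Dense(dense_units, num_classes, rng)
        self.latent_len = latent

    def encode(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        z = x.reshape(n, -1)
        for i in range(self.n_enc):
            z = self.act(getattr(self, f"enc{i}")(z))
        return z.reshape(n, 1, self.latent_len)

    @property
    def decoder(self):
        return self._decode

    def _decode(self, latent: Tensor) -> Tensor:
        n = latent.shape[0]
        z = latent.reshape(n, self.latent_len)
        for i in range(self.n_enc):
            z = getattr(self, f"dec{i}")(z)
            if i < self.n_enc - 1:
                z = self.act(z)
        return z.reshape(n, 1, -1)

    @property
    def classifier(self):
        return self._classify

    def _classify(self, flat: Tensor) -> Tensor:
        from .network import softmax
        return softmax(self.head2(self.act(self.head1(flat))))

    def __call__(self, x: Tensor):
        latent = self.encode(x)
        flat = latent.reshape(latent.shape[0], self.latent_len)
        return self._decode(latent), self._classify(flat)

    def l2_penalty(self) -> Tensor:
        total = Tensor(0.0)
        for w in self.regularized_parameters():
            total = total + (w * w).sum()
        return total * self._l2_lambda

    _l2_lambda = 0.01


class DenseAutoencoderClassifier(SpecFuseNetClassifier):
    """Plain dense autoencoder + classifier, trained on the same joint loss."""

    def __init__(self, hidden=(256, 128), latent_dim=64, activation="ELU",
                 dense_units=128, l2_lambda=0.01, optimizer="Adam",
                 learning_rate=1e-4, epochs=30, batch_size=32,
                 loss_weights=(0.5, 0.5), sched_factor=0.5, sched_patience=5,
                 min_lr=1e-6, random_state=0, verbose=0):
        super().__init__(activation=activation, dense_units=dense_units,
                         l2_lambda=l2_lambda, use_eca=False, use_srg=False,
                         optimizer=optimizer, learning_rate=learning_rate,
                         epochs=epochs, batch_size=batch_size,
                         loss_weights=loss_weights, sched_factor=sched_factor,
                         sched_patience=sched_patience, min_lr=min_lr,
                         random_state=random_state, verbose=verbose)
        self.hidden = hidden
        self.latent_dim = latent_dim

    def _build_model(self, cfg: ModelConfig, n_features: int, seed: int):
        ae = _DenseAE(n_features, cfg.num_classes, cfg.activation,
                      np.random.default_rng(seed), tuple(self.hidden),
                      int(self.latent_dim), cfg.dense_units)
        ae._l2_lambda = self.l2_lambda
        return ae


# ---------------------------------------------------------------------
# sparse convolutional autoencoder baseline
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SparsityConfig:
    """L1 coefficients: encoder conv kernels and latent activations."""

    weight_l1: float = 1e-4
    activity_l1: float = 1e-5

    def __post_init__(self):
        if self.weight_l1 < 0 or self.activity_l1 < 0:
            raise ValueError("sparsity coefficients must be nonnegative")


class SparseConvAutoencoderClassifier(SpecFuseNetClassifier):
    """Convolutional autoencoder backbone (no attention/gating) with
    L1 penalties on the encoder conv kernels and the latent activations."""

    def __init__(self, weight_l1=1e-4, activity_l1=1e-5, filters=(32, 16, 8),
                 kernel_size=3, activation="ELU", dense_units=128,
                 l2_lambda=0.01, optimizer="Adam", learning_rate=1e-4,
                 epochs=30, batch_size=32, loss_weights=(0.5, 0.5),
                 sched_factor=0.5, sched_patience=5, min_lr=1e-6,
                 random_state=0, verbose=0):
        super().__init__(filters=filters, kernel_size=kernel_size,
                         activation=activation, dense_units=dense_units,
                         l2_lambda=l2_lambda, use_eca=False, use_srg=False,
                         optimizer=optimizer, learning_rate=learning_rate,
                         epochs=epochs, batch_size=batch_size,
                         loss_weights=loss_weights, sched_factor=sched_factor,
                         sched_patience=sched_patience, min_lr=min_lr,
                         random_state=random_state, verbose=verbose)
        self.weight_l1 = weight_l1
        self.activity_l1 = activity_l1

    def _extra_penalty(self, latent: Tensor):
        penalty = Tensor(0.0)
        if self.weight_l1 > 0:
            for w in self.model_.encoder.regularized_parameters():
                penalty = penalty + w.abs().sum() * self.weight_l1
        if self.activity_l1 > 0:
            # per-sample sum of absolute latent activations, batch-averaged
            n = latent.shape[0]
            penalty = penalty + latent.abs().sum() * (self.activity_l1 / n)
        return penalty


# ---------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------

ABLATION_VARIANTS = (
    ("CAE", dict(use_eca=False, use_srg=False)),
    ("CAE+ECA", dict(use_eca=True, eca_fused=False, use_srg=False)),
    ("CAE+FusedECA", dict(use_eca=True, eca_fused=True, use_srg=False)),
    ("CAE+FusedECA+SRG", dict(use_eca=True, eca_fused=True, use_srg=True)),
)


def run_ablation(ds: SpectralDataset, k: int = 5, seed: int = 0,
                 **estimator_params) -> tuple[pd.DataFrame, dict]:
    """Cross-validate the four module variants on shared fold splits.

    Returns a four-row table (Acc/Pre/Rec/F1 %) plus the full reports.
    """
    from .training import cross_validate

    rows, reports = [], {}
    for name, flags in ABLATION_VARIANTS:
        params = {**estimator_params, **flags}
        rep = cross_validate(ds, k=k, seed=seed, **params)
        rep.meta["variant"] = name
        rep.meta["flags"] = flags
        reports[name] = rep
        rows.append({"variant": name, "acc": rep.accuracy, "pre": rep.precision,
                     "rec": rep.recall, "f1": rep.f1, **flags})
    return pd.DataFrame(rows), reports
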