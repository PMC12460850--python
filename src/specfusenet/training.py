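"""Joint-loss training, cross-validation, metrics, and the sweep harness.

The model is trained on a joint objective
``w1 * MSE(reconstruction) + w2 * sparse-CE(classification) + lambda * sum w_i^2``
with equal default weights (0.5 / 0.5), the L2 term taken over conv and
dense kernels only.  A plateau scheduler halves the learning rate after
five stagnant validation epochs.

The public entry point is the sklearn-style :class:`SpecFuseNetClassifier`;
``train_one_fold`` / ``cross_validate`` / ``run_sweep`` are thin
orchestration wrappers over it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .autograd import Tensor
from .network import ModelConfig, build_specfusenet
from .optim import ReduceLROnPlateau, make_optimizer
from .preprocess import NIRPreprocessor, stratified_kfold
from .spectra import SpectralDataset

__all__ = [
    "TrainConfig", "EvalReport", "mse_loss", "sparse_ce_loss", "total_loss",
    "confusion_from_predictions", "compute_metrics", "SpecFuseNetClassifier",
    "train_one_fold", "cross_validate", "run_sweep",
]

_PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def mse_loss(y, y_hat):
    """Mean squared error over all elements of the batch."""
    if _is_tensor(y) or _is_tensor(y_hat):
        y = y if _is_tensor(y) else Tensor(y)
        y_hat = y_hat if _is_tensor(y_hat) else Tensor(y_hat)
        if y.shape != y_hat.shape:
            raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
        diff = y - y_hat
        return (diff * diff).mean()
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


def sparse_ce_loss(labels, probs):
    """Sparse categorical cross-entropy: -(1/N) sum log p_{i, y_i}.

    Probabilities are clamped at 1e-12 before the log.
    """
    labels = np.asarray(labels, dtype=int)
    k = probs.shape[1]
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    if _is_tensor(probs):
        onehot = np.zeros(probs.shape, dtype=probs.data.dtype)
        onehot[np.arange(labels.size), labels] = 1.0
        p_true = (probs * Tensor(onehot)).sum(axis=1)
        return -(p_true.maximum(_PROB_FLOOR).log()).mean()
    probs = np.asarray(probs, float)
    p_true = np.maximum(probs[np.arange(labels.size), labels], _PROB_FLOOR)
    return float(-np.mean(np.log(p_true)))


def total_loss(mse, ce, weights=(0.5, 0.5), l2_penalty=0.0):
    """w1 * MSE + w2 * CE + L2 penalty (penalty passed in pre-multiplied)."""
    w1, w2 = weights
    if w1 < 0 or w2 < 0:
        raise ValueError("loss weights must be nonnegative")
    return w1 * mse + w2 * ce + l2_penalty


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def confusion_from_predictions(y_true, y_pred, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return cm


def compute_metrics(confusion: np.ndarray, average: str = "weighted") -> dict:
    """Accuracy / precision / recall / F1 (percent) from a confusion matrix.

    Per-class precision, recall and F1 are combined by support-weighted
    averaging by default (``average='macro'`` for the unweighted mean).
    Classes with no predicted positives get precision 0; classes with no
    true members are excluded from averaging (zero support weight).
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or np.any(cm < 0):
        raise ValueError("confusion matrix must be square and nonnegative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)       # true counts per class
    predicted = cm.sum(axis=0).astype(float)     # predicted counts per class
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if average == "weighted":
        w = support / total
    elif average == "macro":
        present = support > 0
        w = present / present.sum()
    else:
        raise ValueError("average must be 'weighted' or 'macro'")
    return {
        "accuracy": 100.0 * tp.sum() / total,
        "precision": 100.0 * float(precision @ w),
        "recall": 100.0 * float(recall @ w),
        "f1": 100.0 * float(f1 @ w),
    }


@dataclass
class EvalReport:
    """Metrics (percent) + confusion matrix, optionally with per-fold reports."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion_matrix: np.ndarray
    per_fold: list["EvalReport"] = field(default_factory=list)
    fold_mean: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @staticmethod
    def from_confusion(cm: np.ndarray, average: str = "weighted",
                       **meta) -> "EvalReport":
        m = compute_metrics(cm, average)
        return EvalReport(m["accuracy"], m["precision"], m["recall"], m["f1"],
                          np.asarray(cm), meta=dict(meta))

    def to_dict(self) -> dict:
        out = {"accuracy": self.accuracy, "precision": self.precision,
               "recall": self.recall, "f1": self.f1,
               "confusion_matrix": np.asarray(self.confusion_matrix).tolist(),
               "meta": self.meta}
        if self.per_fold:
            out["per_fold"] = [f.to_dict() for f in self.per_fold]
            out["fold_mean"] = self.fold_mean
        return out


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults match the reference training setup)."""

    optimizer: str = "Adam"
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    rmsprop_decay: float = 0.99
    sched_factor: float = 0.5
    sched_patience: int = 5
    min_lr: float = 1e-6
    epochs: int = 300
    batch_size: int = 32
    loss_weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be nonnegative")


# ---------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------

class SpecFuseNetClassifier(BaseEstimator, ClassifierMixin):
    """Attention-gated convolutional autoencoder classifier (sklearn API).

    ``fit`` expects an (n, m) matrix of already-preprocessed spectra and
    integer labels; pass ``validation_data=(X_val, y_val)`` to drive the
    plateau scheduler from held-out loss (training loss is used
    otherwise).  ``transform`` exposes the flattened latent code.
    """

    def __init__(self, filters=(32, 16, 8), kernel_size=3, activation="ELU",
                 eca_kernel_size=5, eca_fused=True, srg_hidden_dim=92,
                 dense_units=128, l2_lambda=0.01,
                 use_eca=True, use_srg=True, use_attention_in_decoder=True,
                 srg_global_gate=False, linear_output=False,
                 optimizer="Adam", learning_rate=1e-4, epochs=30,
                 batch_size=32, loss_weights=(0.5, 0.5),
                 sched_factor=0.5, sched_patience=5, min_lr=1e-6,
                 dtype="float32", random_state=0, verbose=0):
        self.filters = filters
        self.kernel_size = kernel_size
        self.activation = activation
        self.eca_kernel_size = eca_kernel_size
        self.eca_fused = eca_fused
        self.srg_hidden_dim = srg_hidden_dim
        self.dense_units = dense_units
        self.l2_lambda = l2_lambda
        self.use_eca = use_eca
        self.use_srg = use_srg
        self.use_attention_in_decoder = use_attention_in_decoder
        self.srg_global_gate = srg_global_gate
        self.linear_output = linear_output
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.loss_weights = loss_weights
        self.sched_factor = sched_factor
        self.sched_patience = sched_patience
        self.min_lr = min_lr
        self.dtype = dtype
        self.random_state = random_state
        self.verbose = verbose

    # -- config assembly ----------------------------------------------
    def _model_config(self, num_classes: int) -> ModelConfig:
        from .attention import ECAConfig, SRGConfig
        return ModelConfig(
            filters=tuple(self.filters), kernel_size=self.kernel_size,
            activation=self.activation,
            eca=ECAConfig(self.eca_kernel_size, self.eca_fused),
            srg=SRGConfig(self.srg_hidden_dim, activation="ELU"),
            dense_units=self.dense_units, num_classes=num_classes,
            l2_lambda=self.l2_lambda, use_eca=self.use_eca,
            use_srg=self.use_srg,
            use_attention_in_decoder=self.use_attention_in_decoder,
            srg_global_gate=self.srg_global_gate,
            linear_output=self.linear_output)

    def _build_model(self, cfg: ModelConfig, n_features: int, seed: int):
        return build_specfusenet(cfg, n_features, seed=seed)

    def _make_optimizer(self, params):
        kwargs = {}
        if self.optimizer == "RMSprop":
            kwargs["decay"] = 0.99
        elif self.optimizer == "Adam":
            kwargs["betas"] = (0.9, 0.999)
        return make_optimizer(self.optimizer, params, self.learning_rate, **kwargs)

    # -- training ------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, m) with one label per row")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        self.n_features_in_ = X.shape[1]
        cfg = self._model_config(self.classes_.size)
        seeds = np.random.SeedSequence(self.random_state).generate_state(2) % (2**31)
        self.model_ = self._build_model(cfg, X.shape[1], int(seeds[0]))
        dtype = np.dtype(self.dtype)
        for p in self.model_.parameters():
            p.data = p.data.astype(dtype)
        for name, buf in self.model_.named_buffers():
            self.model_.set_buffer(name, buf.astype(dtype))
        X = X.astype(dtype)
        rng = np.random.default_rng(int(seeds[1]))

        opt = self._make_optimizer(self.model_.parameters())
        sched = ReduceLROnPlateau(opt, self.sched_factor, self.sched_patience,
                                  self.min_lr)
        if validation_data is not None:
            X_val = np.asarray(validation_data[0], dtype=float)
            y_val = np.searchsorted(self.classes_, np.asarray(validation_data[1]))

        n = X.shape[0]
        w1, w2 = self.loss_weights
        history = {"epoch": [], "train_loss": [], "train_mse": [], "train_ce": [],
                   "val_loss": [], "lr": []}
        for epoch in range(self.epochs):
            self.model_.train()
            order = rng.permutation(n)
            ep_loss = ep_mse = ep_ce = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = Tensor(X[idx][:, None, :])
                latent = self.model_.encode(xb)
                recon = self.model_.decoder(latent)
                flat = latent.reshape(latent.shape[0], self.model_.latent_len)
                probs = self.model_.classifier(flat)
                l_mse = mse_loss(xb, recon)
                l_ce = sparse_ce_loss(y_idx[idx], probs)
                penalty = self.model_.l2_penalty() + self._extra_penalty(latent)
                loss = total_loss(l_mse, l_ce, (w1, w2), penalty)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: mse={l_mse.data}, "
                        f"ce={l_ce.data}")
                self.model_.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += float(loss.data)
                ep_mse += float(l_mse.data)
                ep_ce += float(l_ce.data)
                n_batches += 1
            train_loss = ep_loss / max(n_batches, 1)
            if validation_data is not None:
                val_loss = self.evaluate_loss(X_val, y_val)
            else:
                val_loss = train_loss
            sched.step(val_loss)
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["train_mse"].append(ep_mse / max(n_batches, 1))
            history["train_ce"].append(ep_ce / max(n_batches, 1))
            history["val_loss"].append(val_loss)
            history["lr"].append(sched.lr)
            if self.verbose:
                print(f"epoch {epoch:3d}  loss {train_loss:.4f}  "
                      f"val {val_loss:.4f}  lr {sched.lr:.2e}")
        self.history_ = history
        self.model_.eval()
        return self

    def _extra_penalty(self, latent: Tensor):
        """Additional regularization term; subclasses may override."""
        return 0.0

    # -- inference -----------------------------------------------------
    def _forward_batches(self, X, batch: int = 256):
        X = np.asarray(X, dtype=float)
        self.model_.eval()
        recons, probs = [], []
        for start in range(0, X.shape[0], batch):
            xb = Tensor(X[start:start + batch][:, None, :])
            r, p = self.model_(xb)
            recons.append(r.data)
            probs.append(p.data)
        return np.concatenate(recons), np.concatenate(probs)

    def predict_proba(self, X):
        return self._forward_batches(X)[1]

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def reconstruct(self, X):
        """Decoder output, shape (n, m)."""
        return self._forward_batches(X)[0][:, 0, :]

    def transform(self, X, batch: int = 256):
        """Flattened latent embeddings (n, last_filter * m)."""
        X = np.asarray(X, dtype=float)
        self.model_.eval()
        out = []
        for start in range(0, X.shape[0], batch):
            xb = Tensor(X[start:start + batch][:, None, :])
            z = self.model_.encode(xb)
            out.append(z.data.reshape(z.shape[0], -1))
        return np.concatenate(out)

    def evaluate_loss(self, X, y) -> float:
        """Total loss (joint objective incl. L2) in inference mode."""
        recon, probs = self._forward_batches(X)
        l_mse = mse_loss(X[:, None, :], recon)
        l_ce = sparse_ce_loss(np.asarray(y, int), probs)
        return float(total_loss(l_mse, l_ce, self.loss_weights,
                                float(self.model_.l2_penalty().data)))


# ---------------------------------------------------------------------
# fold orchestration
# ---------------------------------------------------------------------

def train_one_fold(X_train, y_train, X_val, y_val, n_classes: int,
                   estimator: SpecFuseNetClassifier | None = None,
                   **estimator_params):
    """Train on one fold's preprocessed data; report on the held-out rows."""
    if estimator is None:
        estimator = SpecFuseNetClassifier(**estimator_params)
    estimator.fit(X_train, y_train, validation_data=(X_val, y_val))
    y_pred = estimator.predict(X_val)
    cm = confusion_from_predictions(y_val, y_pred, n_classes)
    report = EvalReport.from_confusion(cm)
    return estimator, estimator.history_, report


def _aggregate_reports(fold_reports: list[EvalReport], meta: dict) -> EvalReport:
    cm = np.sum([f.confusion_matrix for f in fold_reports], axis=0)
    agg = EvalReport.from_confusion(cm)
    agg.per_fold = fold_reports
    agg.fold_mean = {k: float(np.mean([getattr(f, k) for f in fold_reports]))
                     for k in ("accuracy", "precision", "recall", "f1")}
    agg.meta = meta
    return agg


def cross_validate(ds: SpectralDataset, k: int = 5, seed: int = 0,
                   preprocessor: NIRPreprocessor | None = None,
                   estimator_factory=None, return_models: bool = False,
                   global_scaling: bool = False,
                   **estimator_params) -> EvalReport:
    """Stratified k-fold CV with leakage-free per-fold preprocessing.

    Preprocessing (SG derivative + standardization) is fitted on each
    fold's training rows only; ``global_scaling=True`` instead fits it
    once on the full dataset (the alternative protocol, which leaks
    scale statistics across folds).  The aggregate confusion matrix is
    the sum of the fold matrices (metrics on it = pooled aggregation);
    per-fold metrics and their mean are reported alongside.
    """
    split = stratified_kfold(ds.labels, k=k, seed=seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    global_pre = None
    if global_scaling:
        global_pre = (NIRPreprocessor(delta=ds.grid.step) if preprocessor is None
                      else preprocessor.__class__(**preprocessor.get_params()))
        global_pre.fit(ds.spectra)
    fold_reports, models = [], []
    for fold in range(k):
        tr, te = split.train_test(fold)
        if global_pre is not None:
            pre = global_pre
            X_tr = pre.transform(ds.spectra[tr])
        else:
            pre = (NIRPreprocessor(delta=ds.grid.step) if preprocessor is None
                   else preprocessor.__class__(**preprocessor.get_params()))
            X_tr = pre.fit_transform(ds.spectra[tr])
        X_te = pre.transform(ds.spectra[te])
        if estimator_factory is not None:
            est = estimator_factory(random_state=int(fold_seeds[fold]))
        else:
            est = SpecFuseNetClassifier(random_state=int(fold_seeds[fold]),
                                        **estimator_params)
        est, _, rep = train_one_fold(X_tr, ds.labels[tr], X_te, ds.labels[te],
                                     ds.n_classes, estimator=est)
        rep.meta = {"fold": fold}
        fold_reports.append(rep)
        if return_models:
            models.append((est, pre, tr, te))
    agg = _aggregate_reports(fold_reports, {"k": k, "seed": seed})
    if return_models:
        return agg, models
    return agg


def run_sweep(ds: SpectralDataset, optimizers=("Adam", "RMSprop", "SGD", "Adadelta"),
              activations=("ELU", "ReLU", "LeakyReLU", "PReLU"),
              k: int = 5, seed: int = 0, **estimator_params) -> pd.DataFrame:
    """Cross-validate every optimizer x activation cell; one row per cell.

    Failed cells are recorded with NaN metrics and the error message so
    the sweep always completes.
    """
    rows = []
    for opt in optimizers:
        for act in activations:
            t0 = time.time()
            try:
                rep = cross_validate(ds, k=k, seed=seed, optimizer=opt,
                                     activation=act, **estimator_params)
                rows.append({"optimizer": opt, "activation": act,
                             "acc": rep.accuracy, "pre": rep.precision,
                             "rec": rep.recall, "f1": rep.f1,
                             "seconds": time.time() - t0, "error": ""})
            except Exception as exc:  # noqa: BLE001 - sweep must survive cells
                rows.append({"optimizer": opt, "activation": act,
                             "acc": np.nan, "pre": np.nan, "rec": np.nan,
                             "f1": np.nan, "seconds": time.time() - t0,
                             "error": str(exc)})
    return pd.DataFrame(rows)
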