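"""Single-archive model checkpoints.

A checkpoint is one ``.npz`` archive holding a JSON header (schema
version, estimator class + constructor params, fitted class labels,
preprocessing statistics) plus every network parameter and buffer.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import NIRPreprocessor, PreprocessState, SGConfig

SCHEMA_VERSION = 1


def save_checkpoint(estimator, preprocessor: NIRPreprocessor | None, path) -> Path:
    """Serialize a fitted estimator (+ optional fitted preprocessor)."""
    if not hasattr(estimator, "model_"):
        raise ValueError("estimator is not fitted")
    path = Path(path)
    header = {
        "schema_version": SCHEMA_VERSION,
        "estimator_class": type(estimator).__name__,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in estimator.get_params().items()},
        "classes": np.asarray(estimator.classes_).tolist(),
        "n_features_in": int(estimator.n_features_in_),
    }
    arrays = {f"state::{k}": v for k, v in estimator.model_.state_dict().items()}
    if preprocessor is not None:
        st = preprocessor.state_
        header["preprocessor"] = {"params": preprocessor.get_params()}
        arrays["pre::means"] = st.feature_means
        arrays["pre::stds"] = st.feature_stds
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path):
    """Rebuild the estimator (and preprocessor, if stored) from an archive."""
    from . import baselines, training

    with np.load(Path(path)) as arch:
        header = json.loads(bytes(arch["__header__"]).decode())
        if header["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema "
                             f"{header['schema_version']}")
        cls = {
            "SpecFuseNetClassifier": training.SpecFuseNetClassifier,
            "DenseAutoencoderClassifier": baselines.DenseAutoencoderClassifier,
            "SparseConvAutoencoderClassifier":
                baselines.SparseConvAutoencoderClassifier,
        }[header["estimator_class"]]
        params = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in header["params"].items()}
        est = cls(**params)
        est.classes_ = np.asarray(header["classes"])
        est.n_features_in_ = header["n_features_in"]
        cfg = est._model_config(est.classes_.size)
        est.model_ = est._build_model(cfg, est.n_features_in_, 0)
        est.model_.load_state_dict(
            {k.split("::", 1)[1]: arch[k] for k in arch.files
             if k.startswith("state::")})
        est.model_.eval()
        pre = None
        if "preprocessor" in header:
            p = header["preprocessor"]["params"]
            pre = NIRPreprocessor(**p)
            sg = pre._sg_config()
            pre.state_ = PreprocessState(arch["pre::means"], arch["pre::stds"], sg)
            pre.n_features_in_ = arch["pre::means"].size
        return est, pre
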