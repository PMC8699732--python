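"""Classifier contracts: random forest and maximum-margin (SVM)
classification over feature tables, with probability outputs and
persistence.

The random forest follows the standard recipe — bootstrap-sampled trees,
sqrt(k) random candidate features per split, majority voting — with 100
trees by default.  The SVM is a maximum-margin classifier (C = 1,
degree-1 polynomial kernel, i.e. linear, by default) with one-vs-one
pairwise coupling for multiclass problems; class probabilities are the
pairwise vote fractions, which keeps prediction deterministic.
"""

from __future__ import annotations

import io
import json
import pickle
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .feature_selection import FeatureTable

__all__ = ["ClassifierSpec", "TrainedModel", "train", "predict_proba",
           "save_model", "load_model"]

_MAGIC = b"GEOSEGM1"


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "random_forest"       # or "svm"
    rf_trees: int = 100
    rf_split_features: str = "sqrt"
    svm_kernel: str = "polynomial"    # degree-1 polynomial == linear
    svm_degree: int = 1
    svm_C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        if self.svm_kernel not in ("linear", "polynomial"):
            raise ValueError(f"unknown SVM kernel {self.svm_kernel!r}")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    classes: List
    feature_names: List[str]
    estimator: object

    def check_signature(self, names: List[str]) -> None:
        if list(names) != list(self.feature_names):
            raise ValueError(
                "feature signature mismatch: model was trained on "
                f"{len(self.feature_names)} features, got {len(names)} "
                "or different names/order"
            )


def train(table: FeatureTable, spec: ClassifierSpec | None = None) -> TrainedModel:
    """Fit the classifier described by ``spec`` on a labeled feature table."""
    spec = spec or ClassifierSpec()
    classes = list(table.classes)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    X, y = table.matrix, table.labels
    if spec.kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=spec.rf_trees,
            max_features="sqrt" if spec.rf_split_features == "sqrt" else None,
            bootstrap=True,
            random_state=spec.seed,
            n_jobs=1,
        )
    else:
        kernel = "linear" if (spec.svm_kernel == "linear" or spec.svm_degree == 1) else "poly"
        est = SVC(
            kernel=kernel,
            degree=spec.svm_degree,
            C=spec.svm_C,
            decision_function_shape="ovo",
            random_state=spec.seed,
        )
    est.fit(X, y)
    return TrainedModel(spec=spec, classes=classes,
                        feature_names=table.feature_names, estimator=est)


def _svm_vote_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """One-vs-one pairwise vote fractions as class probabilities."""
    est = model.estimator
    k = len(model.classes)
    dec = est.decision_function(X)
    if k == 2:
        # binary sklearn convention: positive margin -> second class
        dec = -dec.reshape(-1, 1)
    votes = np.zeros((X.shape[0], k))
    pair = 0
    for i in range(k):
        for j in range(i + 1, k):
            # multiclass ovo: positive margin votes for the pair's first class
            win_i = dec[:, pair] > 0
            votes[win_i, i] += 1
            votes[~win_i, j] += 1
            pair += 1
    return votes / votes.sum(axis=1, keepdims=True)


def predict_proba(model: TrainedModel, table: FeatureTable | np.ndarray,
                  feature_names: List[str] | None = None) -> np.ndarray:
    """Per-instance class-probability rows (columns follow model.classes).

    Rows are non-negative and sum to 1; argmax ties break toward the
    lower class index.
    """
    if isinstance(table, FeatureTable):
        names = table.feature_names
        X = table.matrix
    else:
        names = feature_names if feature_names is not None else model.feature_names
        X = np.asarray(table, dtype=np.float64)
    model.check_signature(names)
    if model.spec.kind == "random_forest":
        proba = model.estimator.predict_proba(X)
        order = [list(model.estimator.classes_).index(c) for c in model.classes]
        return proba[:, order]
    return _svm_vote_proba(model, X)


def predict(model: TrainedModel, table: FeatureTable | np.ndarray,
            feature_names: List[str] | None = None) -> np.ndarray:
    """Argmax class labels (ties toward the lower class index)."""
    proba = predict_proba(model, table, feature_names)
    idx = np.argmax(proba, axis=1)  # np.argmax returns the first maximum
    return np.asarray(model.classes)[idx]


def save_model(model: TrainedModel, path) -> None:
    """Versioned binary container: magic + JSON header + pickled estimator."""
    header = {
        "format_version": 1,
        "spec": asdict(model.spec),
        "classes": [c.item() if hasattr(c, "item") else c for c in model.classes],
        "feature_names": model.feature_names,
    }
    hbytes = json.dumps(header, sort_keys=True).encode()
    payload = pickle.dumps(model.estimator, protocol=4)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(hbytes).to_bytes(8, "little"))
        fh.write(hbytes)
        fh.write(payload)


def load_model(path) -> TrainedModel:
    """Load a model container; corrupted or foreign files raise ValueError."""
    raw = Path(path).read_bytes()
    if len(raw) < len(_MAGIC) + 8 or raw[: len(_MAGIC)] != _MAGIC:
        raise ValueError(f"{path}: not a geoseg model file")
    hlen = int.from_bytes(raw[len(_MAGIC): len(_MAGIC) + 8], "little")
    start = len(_MAGIC) + 8
    try:
        header = json.loads(raw[start: start + hlen].decode())
        estimator = pickle.loads(raw[start + hlen:])
    except Exception as exc:  # noqa: BLE001 - rewrap any parse failure
        raise ValueError(f"{path}: corrupted model file ({exc})") from exc
    if header.get("format_version") != 1:
        raise ValueError(f"{path}: unsupported model format version")
    return TrainedModel(
        spec=ClassifierSpec(**header["spec"]),
        classes=header["classes"],
        feature_names=header["feature_names"],
        estimator=estimator,
    )
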