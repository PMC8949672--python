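"""Classifiers over reduced feature vectors: SVM (primary) and kNN.

Thin, seed-stable wrappers around scikit-learn estimators, plus the kernel
comparison sweep.  Multiclass SVM uses the one-vs-one decomposition that
kernel SVMs conventionally use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import metrics as _metrics

__all__ = ["ClassifierSpec", "FittedClassifier", "fit", "predict", "kernel_sweep"]

SVM_KERNELS = ("linear", "rbf", "polynomial")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm"  # "svm" | "knn"
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    degree: int = 3
    n_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "svm" and self.kernel not in SVM_KERNELS:
            raise ValueError(f"unknown SVM kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    estimator: object
    classes: list[str]
    n_features: int


def _make_estimator(spec: ClassifierSpec):
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.n_neighbors)
    kernel = "poly" if spec.kernel == "polynomial" else spec.kernel
    return SVC(kernel=kernel, C=spec.C, gamma=spec.gamma, degree=spec.degree,
               decision_function_shape="ovo", random_state=spec.seed)


def _as_matrix(rfvs) -> np.ndarray:
    rows = [r.histogram if hasattr(r, "histogram") else np.asarray(r) for r in rfvs]
    return np.asarray(rows, dtype=float)


def fit(spec: ClassifierSpec, rfvs, labels) -> FittedClassifier:
    X = _as_matrix(rfvs)
    y = np.asarray(list(labels))
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if X.ndim != 2 or len(set(map(len, X))) > 1:
        raise ValueError("all RFVs must have the same length")
    est = _make_estimator(spec)
    est.fit(X, y)
    return FittedClassifier(spec=spec, estimator=est, classes=classes,
                            n_features=X.shape[1])


def predict(model: FittedClassifier, rfvs) -> list[str]:
    X = _as_matrix(rfvs)
    if X.size == 0:
        return []
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"RFV length {X.shape[1]} != training length {model.n_features}"
        )
    return list(model.estimator.predict(X))


def kernel_sweep(
    train_rfvs, train_labels, test_rfvs, test_labels,
    kernels=SVM_KERNELS,
    include_knn: bool = True,
    base_spec: ClassifierSpec = ClassifierSpec(),
) -> pd.DataFrame:
    """One evaluation row per (classifier, kernel) on a shared split."""
    if not kernels:
        raise ValueError("need at least one kernel")
    classes = sorted(set(list(train_labels) + list(test_labels)))
    rows = []
    specs = [replace(base_spec, kind="svm", kernel=k) for k in kernels]
    if include_knn:
        specs.append(replace(base_spec, kind="knn"))
    for spec in specs:
        model = fit(spec, train_rfvs, train_labels)
        pred = predict(model, test_rfvs)
        rep = _metrics.report(list(test_labels), pred, classes)
        rows.append({
            "classifier": spec.kind,
            "kernel": spec.kernel if spec.kind == "svm" else "",
            "accuracy": rep.accuracy,
            "f1": rep.f1,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "kappa": rep.kappa,
            "error": rep.error,
        })
    return pd.DataFrame(rows)
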