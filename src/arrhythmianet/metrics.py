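"""Evaluation metrics for multiclass arrhythmia classification.

Accuracy is trace/total of the confusion matrix.  Sensitivity, specificity
and Cohen's kappa are defined on binary one-vs-rest tallies and extended to
the multiclass report by macro averaging over classes (classes whose
denominator is empty are excluded with a warning).  The F1-score here is the
harmonic mean of sensitivity and specificity,

    F1 = 2 * SE * SP / (SE + SP),

and kappa uses the 2x2 form

    kappa = 2 (TP*TN - FP*FN) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)),

which is algebraically identical to the usual chance-corrected agreement
(po - pe) / (1 - pe) on a 2x2 table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "BinaryTally",
    "EvalReport",
    "confusion",
    "binary_tally",
    "accuracy",
    "sensitivity",
    "specificity",
    "f1_from_se_sp",
    "cohens_kappa",
    "report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = truth, cols = prediction
    classes: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass(frozen=True)
class BinaryTally:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("tally entries must be non-negative")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise ValueError("tally must count at least one sample")


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: float  # percent
    sensitivity: float  # percent, macro
    specificity: float  # percent, macro
    f1: float  # fraction
    kappa: float  # fraction, macro
    error: float  # percent, = 100 - accuracy exactly

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "kappa": self.kappa,
            "error": self.error,
            "classes": self.confusion.classes,
            "confusion": self.confusion.counts.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary_row(self) -> dict:
        """Rounded display row: percentages to 2 decimals, F1/kappa to 3."""
        return {
            "Accuracy": round(self.accuracy, 2),
            "F1-Score": round(self.f1, 3),
            "Sensitivity": round(self.sensitivity, 2),
            "Specificity": round(self.specificity, 2),
            "Cohen's Kappa": round(self.kappa, 3),
            "Error": round(self.error, 2),
        }


def confusion(labels_true, labels_pred, classes) -> ConfusionMatrix:
    lt, lp = list(labels_true), list(labels_pred)
    if len(lt) != len(lp) or not lt:
        raise ValueError("label sequences must be equal-length and non-empty")
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(lt, lp):
        if t not in lut or p not in lut:
            raise ValueError(f"label {t if t not in lut else p!r} not in class list")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts=counts, classes=list(classes))


def binary_tally(cm: ConfusionMatrix, c) -> BinaryTally:
    """One-vs-rest reduction of the confusion matrix for class ``c``."""
    if c not in cm.classes:
        raise ValueError(f"class {c!r} not in {cm.classes}")
    i = cm.classes.index(c)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return BinaryTally(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified samples (trace / total)."""
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def sensitivity(t: BinaryTally) -> float:
    """TP / (TP + FN), as a fraction; NaN when the class has no positives."""
    denom = t.TP + t.FN
    return t.TP / denom if denom > 0 else float("nan")


def specificity(t: BinaryTally) -> float:
    """TN / (TN + FP), as a fraction; NaN when there are no negatives."""
    denom = t.TN + t.FP
    return t.TN / denom if denom > 0 else float("nan")


def f1_from_se_sp(se: float, sp: float) -> float:
    """Harmonic mean of sensitivity and specificity (fractions in, out)."""
    if se + sp <= 0:
        raise ValueError("SE + SP must be > 0")
    return 2.0 * se * sp / (se + sp)


def cohens_kappa(t: BinaryTally) -> float:
    """2x2 chance-corrected agreement."""
    denom = (t.TP + t.FP) * (t.FP + t.TN) + (t.TP + t.FN) * (t.FN + t.TN)
    if denom <= 0:
        raise ValueError("kappa undefined: zero denominator")
    return 2.0 * (t.TP * t.TN - t.FP * t.FN) / denom


def _macro(values: list[float], name: str) -> float:
    arr = np.asarray(values, dtype=float)
    bad = np.isnan(arr)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} class(es) with undefined {name} excluded "
            "from the macro average"
        )
        arr = arr[~bad]
    if arr.size == 0:
        return float("nan")
    return float(arr.mean())


def report(labels_true, labels_pred, classes) -> EvalReport:
    """Full evaluation: confusion matrix plus macro-averaged metrics."""
    cm = confusion(labels_true, labels_pred, classes)
    tallies = [binary_tally(cm, c) for c in classes]
    se_list, sp_list, ka_list = [], [], []
    for t in tallies:
        se_list.append(sensitivity(t))
        sp_list.append(specificity(t))
        try:
            ka_list.append(cohens_kappa(t))
        except ValueError:
            ka_list.append(float("nan"))
    se = _macro(se_list, "sensitivity")
    sp = _macro(sp_list, "specificity")
    ka = _macro(ka_list, "kappa")
    acc = accuracy(cm)
    return EvalReport(
        confusion=cm,
        accuracy=acc,
        sensitivity=100.0 * se,
        specificity=100.0 * sp,
        f1=f1_from_se_sp(se, sp),
        kappa=ka,
        error=100.0 - acc,
    )


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    """Optional heat-map rendering of the confusion matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.classes)), cm.classes, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
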