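"""Leave-one-out SVM discrimination from cluster-mean features.

Every held-out subject is predicted by an SVM fit on the remaining
subjects, with features standardized using training-fold statistics only.
Results are reported as percentage-with-fraction strings, e.g.
``92.31%(48/52)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_core import PasymError


@dataclass
class SvmSettings:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    standardize: bool = True
    class_weight: dict | str | None = None


@dataclass
class ClassifierResult:
    features: tuple
    tp: int
    tn: int
    fp: int
    fn: int
    predictions: np.ndarray  # per-subject left-out predictions (bool: positive?)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def row(self) -> dict:
        return {
            "features": "+".join(self.features),
            "accuracy": format_fraction(self.tp + self.tn, self.n),
            "sensitivity": format_fraction(self.tp, self.tp + self.fn),
            "specificity": format_fraction(self.tn, self.tn + self.fp),
        }


def format_fraction(num: int, den: int) -> str:
    """``48/52 -> '92.31%(48/52)'``; integral percentages drop the decimals."""
    pct = 100.0 * num / den
    text = f"{pct:.2f}".rstrip("0").rstrip(".")
    return f"{text}%({num}/{den})"


def loocv_svm(
    features: np.ndarray,
    labels: np.ndarray,
    settings: SvmSettings | None = None,
) -> ClassifierResult:
    """Leave-one-out SVM with fold-internal standardization.

    ``labels`` is boolean (True = positive class).  A decision value of
    exactly zero predicts the negative class.
    """
    settings = settings or SvmSettings()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise PasymError("features must be subject-by-feature, aligned with labels")
    if not np.isfinite(X).all():
        raise PasymError("features contain missing values")
    n = len(y)
    if y.sum() < 2 or (~y).sum() < 2:
        raise PasymError("need at least 2 subjects per class")

    preds = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if ytr.all() or not ytr.any():
            raise PasymError(f"training fold {i} contains a single class")
        if settings.standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu, sd = 0.0, 1.0
        clf = SVC(
            kernel=settings.kernel,
            C=settings.C,
            gamma=settings.gamma,
            class_weight=settings.class_weight,
        )
        clf.fit((Xtr - mu) / sd, ytr.astype(int))
        dval = float(clf.decision_function(((X[i] - mu) / sd).reshape(1, -1))[0])
        preds[i] = dval > 0  # ties go to the negative class

    tp = int((preds & y).sum())
    tn = int((~preds & ~y).sum())
    fp = int((preds & ~y).sum())
    fn = int((~preds & y).sum())
    return ClassifierResult(features=(), tp=tp, tn=tn, fp=fp, fn=fn, predictions=preds)


def feature_subset_sweep(
    features: pd.DataFrame,
    labels: np.ndarray,
    subsets: Sequence[Sequence[str]],
    settings: SvmSettings | None = None,
) -> list[ClassifierResult]:
    """One leave-one-out run per named feature subset, in the given order."""
    results = []
    for subset in subsets:
        if len(subset) == 0:
            raise PasymError("empty feature subset")
        deduped = list(dict.fromkeys(subset))
        if len(deduped) < len(subset):
            warnings.warn(f"duplicate feature(s) in subset {list(subset)}; deduplicated")
        unknown = [f for f in deduped if f not in features.columns]
        if unknown:
            raise PasymError(f"unknown feature name(s): {', '.join(unknown)}")
        res = loocv_svm(features[deduped].to_numpy(float), labels, settings)
        res.features = tuple(deduped)
        results.append(res)
    return results


def sweep_to_frame(results: list[ClassifierResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])
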