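"""Classifier evaluation: confusion matrices, geometric accuracy,
leave-one-out cross-validation and permutation tests.

The headline summary statistic is the *geometric accuracy*: the geometric
mean of per-reference-class sensitivities,

    GA = (prod_k TP_k / n_k) ** (1/K),

optionally restricted to a class subset (e.g. Hox groups only for relaxed
classifier versions, which deliberately misroute non-Hox homeobox genes
and would otherwise be penalised for doing their job). A single class
with zero sensitivity drives the geometric accuracy to zero, making the
statistic far stricter than plain accuracy on unbalanced data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .discriminant import (
    CTL,
    DiscriminantModel,
    LabelledScores,
    Prediction,
    PriorSpec,
    _pooled_covariance,
    _prior_vector,
    class_order,
    predict,
    train_discriminant,
)

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Reference-class x predicted-class integer counts."""

    data: pd.DataFrame  # rows: reference, columns: predicted

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        self.data = self.data.astype(int)

    @property
    def classes(self) -> list[str]:
        return list(self.data.index)

    @property
    def total(self) -> int:
        return int(self.data.to_numpy().sum())

    def sensitivities(self) -> dict[str, float]:
        """Per-reference-class recall for classes with at least one member."""
        out = {}
        for c in self.data.index:
            n = int(self.data.loc[c].sum())
            if n > 0:
                tp = int(self.data.loc[c, c]) if c in self.data.columns else 0
                out[c] = tp / n
        return out

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "reference"
        out.to_csv(path, sep="\t")


def confusion_matrix(
    predictions: Sequence[Prediction], reference: Mapping[str, str]
) -> ConfusionMatrix:
    """Tabulate (reference, predicted) counts; classes are the label union."""
    missing = [p.seq_id for p in predictions if p.seq_id not in reference]
    if missing:
        raise ValueError(f"predictions without reference labels: {missing[:5]}")
    labels = class_order(
        list({reference[p.seq_id] for p in predictions}
             | {p.predicted for p in predictions})
    )
    df = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for p in predictions:
        df.loc[reference[p.seq_id], p.predicted] += 1
    return ConfusionMatrix(df)


def geometric_accuracy(
    confusion: ConfusionMatrix, restrict_to: Optional[Sequence[str]] = None
) -> float:
    """Geometric mean of per-reference-class sensitivities.

    ``restrict_to`` limits the product to a class subset (every restricted
    class must have at least one reference member).
    """
    sens = confusion.sensitivities()
    if restrict_to is not None:
        restrict = list(restrict_to)
        if not restrict:
            raise ValueError("restriction set must not be empty")
        missing = [c for c in restrict if c not in sens]
        if missing:
            raise ValueError(f"restricted classes without reference members: {missing}")
        values = [sens[c] for c in restrict]
    else:
        values = list(sens.values())
    if not values:
        raise ValueError("no reference classes to evaluate")
    arr = np.asarray(values)
    if np.any(arr == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))


@dataclass
class EvaluationReport:
    """Aggregated evaluation of one set of predictions."""

    confusion: ConfusionMatrix
    per_class_sensitivity: dict[str, float]
    geometric_accuracy: float
    n_evaluated: int
    restricted_to: Optional[list[str]] = None
    predictions: Optional[list[Prediction]] = None

    def to_dict(self) -> dict:
        return {
            "geometric_accuracy": self.geometric_accuracy,
            "per_class_sensitivity": self.per_class_sensitivity,
            "n_evaluated": self.n_evaluated,
            "restricted_to": self.restricted_to,
            "confusion": {
                "classes": self.confusion.classes,
                "counts": self.confusion.data.to_numpy().tolist(),
            },
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = [self.confusion.data.to_string(), ""]
        for c, s in self.per_class_sensitivity.items():
            lines.append(f"sensitivity[{c}] = {s:.4f}")
        scope = ", ".join(self.restricted_to) if self.restricted_to else "all classes"
        lines.append(f"geometric accuracy ({scope}) = {self.geometric_accuracy:.4f}")
        return "\n".join(lines)


def evaluate_predictions(
    predictions: Sequence[Prediction],
    reference: Mapping[str, str],
    restrict_to: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    cm = confusion_matrix(predictions, reference)
    return EvaluationReport(
        confusion=cm,
        per_class_sensitivity=cm.sensitivities(),
        geometric_accuracy=geometric_accuracy(cm, restrict_to),
        n_evaluated=cm.total,
        restricted_to=list(restrict_to) if restrict_to is not None else None,
        predictions=list(predictions),
    )


def _loocv_codes(
    X: np.ndarray,
    codes: np.ndarray,
    n_classes: int,
    priors: PriorSpec,
    shrinkage: Union[str, float],
    classes: Sequence[str],
) -> np.ndarray:
    """Lean LOOCV inner loop on arrays; returns held-out predicted codes."""
    n, p = X.shape
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        Xt, ct = X[mask], codes[mask]
        counts = np.bincount(ct, minlength=n_classes).astype(float)
        means = np.vstack([Xt[ct == k].mean(axis=0) for k in range(n_classes)])
        cov, _ = _pooled_covariance(Xt, ct, n_classes, shrinkage)
        prior_vec = _prior_vector(priors, classes, counts)
        with np.errstate(divide="ignore"):
            log_priors = np.log(prior_vec)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled covariance in LOOCV; use shrinkage > 0 or 'auto'"
            ) from exc
        d = X[i][None, :] - means  # K x p
        w = solve_triangular(L, d.T, lower=True)
        maha = np.sum(w * w, axis=0)
        preds[i] = int(np.argmax(log_priors - 0.5 * maha))
    return preds


def loocv(
    data: LabelledScores,
    priors: PriorSpec = "empirical",
    shrinkage: Union[str, float] = "auto",
    restrict_to: Optional[Sequence[str]] = None,
    selected: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Leave-one-out cross-validation of the discriminant layer.

    Each sequence is predicted by a model trained on all remaining
    sequences (profile scores are fixed; only the discriminant is
    refitted per fold). Every class needs at least 3 members so each
    fold retains 2.
    """
    classes = data.classes
    y = data.label_array()
    counts = {c: int(np.sum(y == c)) for c in classes}
    small = [c for c, n in counts.items() if n < 3]
    if small:
        raise ValueError(f"classes too small for LOOCV (need >= 3 members): {small}")
    features = list(selected) if selected is not None else data.table.groups
    X = data.table.matrix(features)
    codes = np.array([classes.index(c) for c in y])
    pred_codes = _loocv_codes(X, codes, len(classes), priors, shrinkage, classes)
    seq_ids = data.table.seq_ids
    predictions = []
    for i, seq_id in enumerate(seq_ids):
        # LOOCV reports hard calls; posteriors are degenerate one-hot here
        cls = classes[pred_codes[i]]
        predictions.append(
            Prediction(seq_id=seq_id, predicted=cls,
                       posteriors={c: 1.0 if c == cls else 0.0 for c in classes})
        )
    reference = {s: data.labels[s] for s in seq_ids}
    return evaluate_predictions(predictions, reference, restrict_to)


@dataclass
class PermutationResult:
    """Observed geometric accuracy against a label-permutation null."""

    observed: float
    null_values: list[float]
    p_value: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_values": [round(v, 10) for v in self.null_values],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def permutation_test(
    data: LabelledScores,
    n_perm: int = 99,
    seed: int = 0,
    priors: PriorSpec = "empirical",
    shrinkage: Union[str, float] = "auto",
    restrict_to: Optional[Sequence[str]] = None,
    selected: Optional[Sequence[str]] = None,
) -> PermutationResult:
    """Label-permutation test of the LOOCV geometric accuracy.

    The p-value uses the add-one correction
    ``(1 + #{null >= observed}) / (1 + n_perm)`` so it can never be zero.
    """
    if n_perm < 19:
        raise ValueError("need n_perm >= 19 for a usable permutation p-value")
    observed = loocv(data, priors, shrinkage, restrict_to, selected).geometric_accuracy
    classes = data.classes
    features = list(selected) if selected is not None else data.table.groups
    X = data.table.matrix(features)
    y = data.label_array()
    codes = np.array([classes.index(c) for c in y])
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        pc = codes[perm]
        pred = _loocv_codes(X, pc, len(classes), priors, shrinkage, classes)
        cm = _code_confusion(pc, pred, len(classes))
        nulls.append(_code_geometric_accuracy(cm, classes, restrict_to))
    n_ge = sum(1 for v in nulls if v >= observed)
    p = (1 + n_ge) / (1 + n_perm)
    return PermutationResult(
        observed=float(observed),
        null_values=[float(v) for v in nulls],
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def _code_confusion(ref: np.ndarray, pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (ref, pred), 1)
    return cm


def _code_geometric_accuracy(
    cm: np.ndarray, classes: Sequence[str], restrict_to: Optional[Sequence[str]]
) -> float:
    row_sums = cm.sum(axis=1)
    if restrict_to is not None:
        keep = [i for i, c in enumerate(classes) if c in set(restrict_to)]
    else:
        keep = [i for i in range(len(classes)) if row_sums[i] > 0]
    sens = []
    for i in keep:
        if row_sums[i] == 0:
            return 0.0  # restricted class absent after permutation: worst case
        sens.append(cm[i, i] / row_sums[i])
    arr = np.asarray(sens)
    if np.any(arr == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))
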