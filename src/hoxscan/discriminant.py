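"""Linear discriminant classification of profile-score vectors.

Each query is represented by its vector of generalised-profile scores.
A Gaussian linear discriminant with a shared (pooled, optionally shrunk)
covariance converts that vector into posterior probabilities over the
homology groups plus the CTL rejection class. The CTL prior is set
deliberately high (default 0.90) so that divergent sequences fall into
the control class rather than being forced into a Hox group.

Class posteriors are computed in log space::

    log p(k | x) = log pi_k - (x - mu_k)' Sigma^-1 (x - mu_k) / 2 + const

followed by a log-sum-exp normalisation. Ties are broken in favour of
CTL, then lexicographically; this is implemented by ordering classes
CTL-first and taking the first argmax.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .profile import ScoreTable

logger = logging.getLogger(__name__)

CTL = "CTL"

PriorSpec = Union[str, Mapping[str, float]]


def class_order(labels: Sequence[str]) -> list[str]:
    """Deterministic class ordering: CTL first, then lexicographic."""
    rest = sorted(set(labels) - {CTL})
    return ([CTL] if CTL in labels else []) + rest


def make_priors(classes: Sequence[str], ctl_prior: float = 0.9) -> dict[str, float]:
    """CTL gets ``ctl_prior``; the remainder is spread equally over the groups."""
    classes = list(classes)
    if CTL not in classes:
        raise ValueError("make_priors requires a CTL class")
    if not 0 < ctl_prior < 1:
        raise ValueError("ctl_prior must be in (0, 1)")
    others = [c for c in classes if c != CTL]
    share = (1.0 - ctl_prior) / len(others)
    priors = {c: share for c in others}
    priors[CTL] = ctl_prior
    return priors


@dataclass
class LabelledScores:
    """A score table with a class label for every row."""

    table: ScoreTable
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.table.seq_ids if s not in self.labels]
        if missing:
            raise ValueError(f"unlabelled sequences in score table: {missing[:5]}")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 distinct classes")

    @property
    def classes(self) -> list[str]:
        return class_order([self.labels[s] for s in self.table.seq_ids])

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.table.seq_ids])

    def with_labels(self, labels: Mapping[str, str]) -> "LabelledScores":
        return LabelledScores(table=self.table, labels=dict(labels))


@dataclass
class Prediction:
    """Class call for one sequence with the full posterior map."""

    seq_id: str
    predicted: str
    posteriors: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.posteriors.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"posteriors for {self.seq_id!r} sum to {total}, expected 1"
            )


@dataclass
class DiscriminantModel:
    """Gaussian LDA: class means, pooled covariance, priors, selected profiles."""

    classes: list[str]
    priors: np.ndarray          # aligned with classes, sums to 1
    means: np.ndarray           # n_classes x n_features
    covariance: np.ndarray      # pooled, shrunk; symmetric positive-definite
    shrinkage: float
    selected_profiles: list[str]
    provenance: dict = field(default_factory=dict)
    _chol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = len(self.selected_profiles)
        if self.means.shape != (len(self.classes), p):
            raise ValueError("means must be n_classes x n_selected_profiles")
        if self.covariance.shape != (p, p):
            raise ValueError("covariance dimension must match selected profiles")
        if abs(self.priors.sum() - 1.0) > 1e-9 or np.any(self.priors < 0):
            raise ValueError("priors must be non-negative and sum to 1")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")

    def cholesky(self):
        if self._chol is None:
            try:
                self._chol = cho_factor(self.covariance, lower=True)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ValueError(
                    "covariance is not positive-definite; increase shrinkage"
                ) from exc
        return self._chol

    def log_posteriors(self, X: np.ndarray) -> np.ndarray:
        """Normalised log posteriors for rows of X (n x p)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValueError(
                f"expected {self.means.shape[1]} features, got {X.shape[1]}"
            )
        chol = self.cholesky()
        logp = np.empty((X.shape[0], len(self.classes)))
        with np.errstate(divide="ignore"):
            log_priors = np.log(self.priors)
        for k in range(len(self.classes)):
            d = X - self.means[k]
            maha = np.einsum("ij,ij->i", d, cho_solve(chol, d.T).T)
            logp[:, k] = log_priors[k] - 0.5 * maha
        return logp - logsumexp(logp, axis=1, keepdims=True)

    def with_priors(self, priors: Mapping[str, float]) -> "DiscriminantModel":
        vec = _prior_vector(priors, self.classes)
        return DiscriminantModel(
            classes=list(self.classes),
            priors=vec,
            means=self.means.copy(),
            covariance=self.covariance.copy(),
            shrinkage=self.shrinkage,
            selected_profiles=list(self.selected_profiles),
            provenance=dict(self.provenance),
        )

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "priors": [round(float(v), 12) for v in self.priors],
            "means": [[round(float(v), 10) for v in row] for row in self.means],
            "covariance": [[round(float(v), 10) for v in row] for row in self.covariance],
            "shrinkage": float(self.shrinkage),
            "selected_profiles": self.selected_profiles,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        return cls(
            classes=list(d["classes"]),
            priors=np.asarray(d["priors"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            shrinkage=float(d["shrinkage"]),
            selected_profiles=list(d["selected_profiles"]),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _prior_vector(priors: PriorSpec, classes: Sequence[str],
                  counts: Optional[np.ndarray] = None) -> np.ndarray:
    if isinstance(priors, str):
        if priors != "empirical":
            raise ValueError(f"unknown prior specification {priors!r}")
        if counts is None:
            raise ValueError("empirical priors need class counts")
        return counts / counts.sum()
    missing = [c for c in classes if c not in priors]
    if missing:
        raise ValueError(f"priors missing classes: {missing}")
    vec = np.array([float(priors[c]) for c in classes])
    if abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError(f"priors sum to {vec.sum()}, expected 1")
    return vec / vec.sum()


def _pooled_covariance(X: np.ndarray, codes: np.ndarray, n_classes: int,
                       shrinkage: Union[str, float]) -> tuple[np.ndarray, float]:
    """Pooled within-class covariance, optionally shrunk toward its diagonal."""
    n, p = X.shape
    centered = X.copy()
    for k in range(n_classes):
        mask = codes == k
        centered[mask] -= X[mask].mean(axis=0)
    S = centered.T @ centered / max(n - n_classes, 1)
    if shrinkage == "auto":
        from sklearn.covariance import ledoit_wolf_shrinkage

        lam = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1] or 'auto'")
    diag = np.diag(np.diag(S))
    cov = (1.0 - lam) * S + lam * diag
    if lam > 0.0:
        # zero-variance features would make even the diagonal target singular
        eps = 1e-12 * max(float(np.trace(cov)) / p, 1.0)
        cov[np.diag_indices_from(cov)] += eps
    return cov, lam


def train_discriminant(
    data: LabelledScores,
    priors: PriorSpec = "empirical",
    shrinkage: Union[str, float] = "auto",
    selected: Optional[Sequence[str]] = None,
) -> DiscriminantModel:
    """Fit a Gaussian linear discriminant on labelled score vectors.

    Class means are per-class score-vector means; the covariance is pooled
    across classes and shrunk toward its diagonal (Ledoit–Wolf intensity
    when ``shrinkage='auto'``). Priors may be 'empirical', or an explicit
    class → probability map (e.g. :func:`make_priors` for the high-CTL
    default).
    """
    features = list(selected) if selected is not None else data.table.groups
    classes = data.classes
    X = data.table.matrix(features)
    y = data.label_array()
    codes = np.array([classes.index(c) for c in y])
    counts = np.bincount(codes, minlength=len(classes)).astype(float)
    small = [classes[k] for k in range(len(classes)) if counts[k] < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 members: {small}")
    means = np.vstack([X[codes == k].mean(axis=0) for k in range(len(classes))])
    cov, lam = _pooled_covariance(X, codes, len(classes), shrinkage)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        raise ValueError(
            "pooled covariance is singular; retrain with shrinkage > 0 or 'auto'"
        )
    prior_vec = _prior_vector(priors, classes, counts)
    model = DiscriminantModel(
        classes=classes,
        priors=prior_vec,
        means=means,
        covariance=cov,
        shrinkage=lam,
        selected_profiles=features,
        provenance={"n_training": int(X.shape[0])},
    )
    try:
        model.cholesky()
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "pooled covariance is singular; retrain with shrinkage > 0 or 'auto'"
        ) from exc
    return model


def posterior_probabilities(
    model: DiscriminantModel, scores: Union[Mapping[str, float], np.ndarray]
) -> dict[str, float]:
    """Posterior probability of each class for one score vector.

    ``scores`` may be a mapping over profile labels (it must cover every
    selected profile) or an array already in selected-profile order.
    """
    if isinstance(scores, Mapping):
        missing = [g for g in model.selected_profiles if g not in scores]
        if missing:
            raise KeyError(f"score vector missing profiles: {missing}")
        x = np.array([float(scores[g]) for g in model.selected_profiles])
    else:
        x = np.asarray(scores, dtype=float)
    logp = model.log_posteriors(x[None, :])[0]
    post = np.exp(logp)
    post = post / post.sum()
    return {c: float(v) for c, v in zip(model.classes, post)}


def predict(model: DiscriminantModel, table: ScoreTable) -> list[Prediction]:
    """Predict every row of a score table; the argmax-posterior class wins.

    Exact posterior ties go to CTL when CTL is involved, otherwise to the
    lexicographically first class (the model's class order encodes this).
    """
    X = table.matrix(model.selected_profiles)
    logp = model.log_posteriors(X)
    post = np.exp(logp)
    post = post / post.sum(axis=1, keepdims=True)
    calls = np.argmax(logp, axis=1)  # first max: CTL-first, then lexicographic
    return [
        Prediction(
            seq_id=seq_id,
            predicted=model.classes[calls[i]],
            posteriors={c: float(v) for c, v in zip(model.classes, post[i])},
        )
        for i, seq_id in enumerate(table.seq_ids)
    ]


def select_variables(
    data: LabelledScores,
    priors: PriorSpec = "empirical",
    shrinkage: Union[str, float] = "auto",
    tol: float = 1e-6,
) -> list[str]:
    """Greedy forward profile selection by leave-one-out geometric accuracy.

    Starting from the empty set, repeatedly add the profile that most
    improves LOOCV geometric accuracy; stop when no candidate improves it
    by more than ``tol``. At least one profile is always selected; ties
    keep the earlier profile in table column order (fewer features win by
    construction, since additions must strictly improve).
    """
    from .evaluation import loocv

    candidates = list(data.table.groups)
    if len(candidates) == 1:
        return candidates
    selected: list[str] = []
    best_acc = -np.inf
    while True:
        best_gain_acc = best_acc
        best_candidate = None
        for g in candidates:
            if g in selected:
                continue
            report = loocv(data, priors=priors, shrinkage=shrinkage,
                           selected=selected + [g])
            acc = report.geometric_accuracy
            if acc > best_gain_acc + (tol if selected else 0.0):
                best_gain_acc = acc
                best_candidate = g
        if best_candidate is None:
            break
        selected.append(best_candidate)
        best_acc = best_gain_acc
        logger.debug("selected %s (LOOCV geometric accuracy %.4f)",
                     best_candidate, best_acc)
    return selected
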