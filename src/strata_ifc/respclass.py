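"""Responder stratification by a five-member classifier majority vote.

Treatment response is operationalized through patient-vs-control
classification: five binary classifiers — a linear-kernel SVM, a
Gaussian-kernel SVM, and three 1-nearest-neighbour classifiers (Euclidean,
cosine, chi-square distance) — are trained on baseline (M1) clinical features
z-scored across the pooled patient+control sample.  Each patient's follow-up
(M2) feature vector, normalized with the *frozen* M1 parameters, is then shown
to all five.  A majority vote of "control" (>= 3 of 5; the odd count forces a
strict majority) labels the patient a treatment Responder.

Hyperparameters are fixed by the contract, not tuned: SVMs are soft-margin
with box constraint 1, kernel scale 1 (Gaussian kernel exp(-||x-y||^2)),
offset 0; KNNs use k = 1, exhaustive search, equal weighting.  Distance ties
in the 1-NN members are broken by the smallest training-row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from strata_ifc.clinstats import FEATURE_COLUMNS, NormalizationModel, fit_normalization

__all__ = [
    "VoteEnsemble",
    "ResponderLabels",
    "chi_square_distance",
    "train_ensemble",
    "classify_m2",
    "MEMBER_NAMES",
]

MEMBER_NAMES = ("svm_linear", "svm_gaussian", "knn_euclidean", "knn_cosine", "knn_chisquare")

_CHI2_EPS = 1e-8

CONTROL, PATIENT = "control", "patient"


def chi_square_distance(x, y) -> float:
    """Chi-square distance sum((x-y)^2 / (|x|+|y|+eps)) for feature vectors.

    The classical chi-square distance assumes nonnegative inputs; on z-scored
    features the denominators use absolute values plus a small eps so the
    metric stays defined and nonnegative.  On nonnegative inputs it agrees
    with the classical form.  Symmetric, with d(x, x) = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sum((x - y) ** 2 / (np.abs(x) + np.abs(y) + _CHI2_EPS)))


def _pairwise_chi_square(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    num = (A[:, None, :] - B[None, :, :]) ** 2
    den = np.abs(A)[:, None, :] + np.abs(B)[None, :, :] + _CHI2_EPS
    return (num / den).sum(axis=-1)


class _OneNearestNeighbor:
    """1-NN with exhaustive search and smallest-training-index tie-breaking."""

    def __init__(self, metric: str):
        self.metric = metric

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OneNearestNeighbor":
        self.X_, self.y_ = np.asarray(X, dtype=float), np.asarray(y)
        return self

    def _distances(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "chisquare":
            return _pairwise_chi_square(np.asarray(X, dtype=float), self.X_)
        return cdist(X, self.X_, metric=self.metric)

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self._distances(np.atleast_2d(X))
        # np.argmin returns the first (smallest-index) minimizer on exact ties.
        return self.y_[np.argmin(d, axis=1)]


class _SvmMember:
    """SVC wrapper voting 'patient' when the decision value is exactly 0."""

    def __init__(self, kernel: str):
        # Gaussian kernel scale 1 -> gamma = 1 on the already z-scored features.
        self.clf = SVC(C=1.0, kernel=kernel, gamma=1.0, coef0=0.0)

    def fit(self, X, y):
        # Encode so that the positive decision side is 'patient'.
        self.clf.fit(X, (np.asarray(y) == PATIENT).astype(int))
        return self

    def predict(self, X) -> np.ndarray:
        dec = self.clf.decision_function(np.atleast_2d(X))
        return np.where(dec >= 0.0, PATIENT, CONTROL)


@dataclass
class VoteEnsemble:
    """Five trained members plus the frozen M1 normalization model."""

    members: dict[str, object]
    normalization: NormalizationModel
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if tuple(self.members) != MEMBER_NAMES:
            raise ValueError(f"ensemble must hold exactly the members {MEMBER_NAMES}")

    def member_votes(self, X_normalized: np.ndarray) -> pd.DataFrame:
        """Hard control/patient vote of each member for each row of X."""
        return pd.DataFrame(
            {name: member.predict(X_normalized) for name, member in self.members.items()}
        )


@dataclass
class ResponderLabels:
    """Per-patient member votes and the final majority-vote label."""

    votes: pd.DataFrame  # subject_id, 5 member columns, n_control_votes, final_label

    @property
    def final(self) -> pd.Series:
        return self.votes.set_index("subject_id")["final_label"]

    def to_csv(self, path) -> None:
        self.votes.to_csv(path, index=False)


def train_ensemble(
    m1_table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    group_col: str = "group",
    normalization: NormalizationModel | None = None,
) -> VoteEnsemble:
    """Train the five members on the pooled, z-normalized M1 sample.

    ``m1_table`` must hold the baseline rows of both groups with a
    ``group`` column in {control, patient}.  If ``normalization`` is not
    supplied it is fitted on the pooled table (the intended use); all five
    members are trained on the identical normalized design.
    """
    labels = m1_table[group_col].to_numpy()
    classes = set(labels)
    if classes != {CONTROL, PATIENT}:
        raise ValueError(f"training data must contain both classes, got {sorted(classes)}")
    if m1_table[list(features)].isna().any().any():
        raise ValueError("missing values in feature columns")
    if normalization is None:
        normalization = fit_normalization(m1_table, features)
    X = normalization.transform(m1_table)[list(features)].to_numpy()
    members = {
        "svm_linear": _SvmMember("linear").fit(X, labels),
        "svm_gaussian": _SvmMember("rbf").fit(X, labels),
        "knn_euclidean": _OneNearestNeighbor("euclidean").fit(X, labels),
        "knn_cosine": _OneNearestNeighbor("cosine").fit(X, labels),
        "knn_chisquare": _OneNearestNeighbor("chisquare").fit(X, labels),
    }
    return VoteEnsemble(members=members, normalization=normalization, features=tuple(features))


def classify_m2(
    ensemble: VoteEnsemble,
    m2_table: pd.DataFrame,
    id_col: str = "subject_id",
) -> ResponderLabels:
    """Label each M2 patient row Responder/NonResponder by majority vote.

    M2 rows are normalized with the ensemble's stored M1 parameters (never
    re-fitted on M2), each member casts a hard control/patient vote, and a
    patient is a Responder iff at least 3 of the 5 votes are "control".
    """
    missing = [f for f in ensemble.features if f not in m2_table.columns]
    if missing:
        raise ValueError(f"feature mismatch, missing columns: {missing}")
    X = ensemble.normalization.transform(m2_table)[list(ensemble.features)].to_numpy()
    votes = ensemble.member_votes(X)
    n_control = (votes == CONTROL).sum(axis=1)
    out = votes.copy()
    out.insert(0, "subject_id", m2_table[id_col].to_numpy())
    out["n_control_votes"] = n_control
    out["final_label"] = np.where(n_control >= 3, "Responder", "NonResponder")
    return ResponderLabels(votes=out)
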