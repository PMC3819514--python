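"""Normalization, t-test feature selection, classifiers, true error.

The evaluation protocol: z-score every feature with training statistics,
rank features by absolute pooled two-sample t statistic, keep the top ``d``
(or use the known global markers directly), train a rule (LDA, 3NN or
RBF-SVM) on the selected features, and estimate its true error on a large
independent test sample transformed by the same pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .model import ParameterError

__all__ = [
    "Normalizer",
    "ClassifierSpec",
    "TrainedClassifier",
    "t_scores",
    "select_top_features",
    "LDAClassifier",
    "KNNClassifier",
    "RBFSVMClassifier",
    "train_classifier",
    "true_error",
]

log = logging.getLogger(__name__)

RULES = ("LDA", "3NN", "RBF_SVM")
SELECTIONS = ("TTEST", "NONE_GLOBAL")


@dataclass
class Normalizer:
    """Per-feature z-scoring frozen at training time.

    Features with zero training SD are mapped to 0 everywhere (they carry
    no training information); the same coefficients are applied to test
    data.
    """

    mean_: np.ndarray
    sd_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        if X.shape[0] == 0:
            raise ParameterError("cannot fit a normalizer on an empty matrix")
        X = np.asarray(X, dtype=np.float64)
        return cls(X.mean(axis=0), X.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        scale = np.where(self.sd_ > 0, self.sd_, np.inf)
        return (np.asarray(X, dtype=np.float64) - self.mean_) / scale

    def subset(self, idx: np.ndarray) -> "Normalizer":
        return Normalizer(self.mean_[idx], self.sd_[idx])


def t_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistic per feature (class 1 - class 0).

    Degenerate features (zero pooled variance) score ``+/-inf`` when the
    class means differ and 0 otherwise.  Ranking uses the absolute value
    and is invariant under per-feature affine transforms, so it may be
    computed on raw or normalized data interchangeably.
    """
    y = np.asarray(y)
    n = len(y)
    n1 = int((y == 1).sum())
    n0 = n - n1
    if n0 < 2 or n1 < 2:
        raise ParameterError("need at least two training samples per class")
    V = np.asarray(X, dtype=np.float64)
    g = (y == 1).astype(np.float64)
    s_all = V.sum(axis=0)
    s1 = g @ V
    s0 = s_all - s1
    Q = V * V
    q1 = g @ Q
    q0 = Q.sum(axis=0) - q1
    mu1, mu0 = s1 / n1, s0 / n0
    v1 = np.maximum(q1 - n1 * mu1 * mu1, 0.0) / (n1 - 1)
    v0 = np.maximum(q0 - n0 * mu0 * mu0, 0.0) / (n0 - 1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    diff = mu1 - mu0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_var = denom == 0
    if zero_var.any():
        d = diff[zero_var]
        repl = np.zeros(d.shape)
        repl[d > 0] = np.inf
        repl[d < 0] = -np.inf
        t[zero_var] = repl
    return t


def select_top_features(scores: np.ndarray, d: int) -> np.ndarray:
    """Indices of the ``d`` largest ``|t|``, ties to the lowest index.

    The result is sorted ascending.
    """
    scores = np.asarray(scores)
    if d > len(scores):
        raise ParameterError(f"d={d} exceeds the number of features {len(scores)}")
    order = np.argsort(-np.abs(scores), kind="stable")
    return np.sort(order[:d])


class LDAClassifier:
    """Plug-in linear discriminant (equal priors).

    Sample class means and the pooled sample covariance are plugged into
    the Mahalanobis comparison; a point exactly on the boundary is assigned
    class 1.  A singular pooled covariance gets a small ridge
    (``1e-6 * trace / d``) with a logged warning.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n, d = X.shape
        n1 = int((y == 1).sum())
        n0 = n - n1
        if n0 < 2 or n1 < 2:
            raise ParameterError("LDA needs at least two samples per class")
        X0, X1 = X[y == 0], X[y == 1]
        self.mu0_ = X0.mean(axis=0)
        self.mu1_ = X1.mean(axis=0)
        S0 = np.cov(X0, rowvar=False).reshape(d, d)
        S1 = np.cov(X1, rowvar=False).reshape(d, d)
        S = ((n0 - 1) * S0 + (n1 - 1) * S1) / (n - 2)
        try:
            self._cho = cho_factor(S)
        except np.linalg.LinAlgError:
            ridge = 1e-6 * np.trace(S) / d
            if ridge <= 0:
                ridge = 1e-6  # fully degenerate: reduce to nearest centroid
            log.warning("singular pooled covariance; adding ridge %.3g", ridge)
            self._cho = cho_factor(S + ridge * np.eye(d))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        d1 = X - self.mu1_
        d0 = X - self.mu0_
        q1 = np.einsum("ij,ij->i", d1, cho_solve(self._cho, d1.T).T)
        q0 = np.einsum("ij,ij->i", d0, cho_solve(self._cho, d0.T).T)
        return (q1 <= q0).astype(np.int8)


class KNNClassifier:
    """k-nearest-neighbours majority vote (Euclidean; default k=3).

    Distance ties are broken by the lowest training index so predictions
    are deterministic.
    """

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < self.k:
            raise ParameterError(f"need at least k={self.k} training points")
        self.X_ = X
        self.y_ = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        dist = cdist(X, self.X_)
        nn = np.argsort(dist, axis=1, kind="stable")[:, :self.k]
        votes = self.y_[nn].mean(axis=1)
        return (votes > 0.5).astype(np.int8)


class RBFSVMClassifier:
    """Soft-margin SVM with a Gaussian kernel (scikit-learn backend).

    Hyperparameters default to cost ``C=1`` and kernel width
    ``gamma = 1/d`` on normalized features.
    """

    def __init__(self, C: float = 1.0, gamma: float | None = None):
        self.C = C
        self.gamma = gamma

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFSVMClassifier":
        X = np.asarray(X, dtype=np.float64)
        gamma = self.gamma if self.gamma is not None else 1.0 / X.shape[1]
        self._svc = SVC(C=self.C, kernel="rbf", gamma=gamma)
        self._svc.fit(X, np.asarray(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.atleast_2d(np.asarray(X, dtype=np.float64))).astype(np.int8)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classification scheme: rule, feature count and selection mode.

    ``rule=None`` requests feature selection only (marker-recovery runs
    without error estimation).  ``NONE_GLOBAL`` uses the known global
    markers directly (``d`` is then the number of global markers).
    """

    rule: str | None = "LDA"
    d: int = 10
    selection: str = "TTEST"
    knn_k: int = 3
    svm_C: float = 1.0
    svm_gamma: float | None = None

    def __post_init__(self) -> None:
        if self.rule is not None and self.rule not in RULES:
            raise ParameterError(f"unknown rule {self.rule!r}; choose from {RULES}")
        if self.selection not in SELECTIONS:
            raise ParameterError(
                f"unknown selection {self.selection!r}; choose from {SELECTIONS}")
        if self.d < 1:
            raise ParameterError(f"d must be >= 1, got {self.d}")

    def make_rule(self):
        if self.rule == "LDA":
            return LDAClassifier()
        if self.rule == "3NN":
            return KNNClassifier(k=self.knn_k)
        if self.rule == "RBF_SVM":
            return RBFSVMClassifier(C=self.svm_C, gamma=self.svm_gamma)
        raise ParameterError("spec has no rule to train")


@dataclass
class TrainedClassifier:
    """Selected features, frozen normalization and a fitted rule."""

    spec: ClassifierSpec
    feature_idx: np.ndarray        # original feature indices, sorted
    normalizer: Normalizer         # statistics at the selected features only
    rule: object

    def predict(self, X: np.ndarray, columns: np.ndarray | None = None) -> np.ndarray:
        """Predict labels; ``columns`` names the features in ``X``.

        With ``columns=None`` the matrix must hold all original features
        and the stored indices slice it; otherwise ``columns`` must equal
        the stored selection.
        """
        if columns is None:
            Xs = np.asarray(X)[:, self.feature_idx]
        else:
            if not np.array_equal(np.asarray(columns), self.feature_idx):
                raise ParameterError("test columns do not match the selected features")
            Xs = np.asarray(X)
        return self.rule.predict(self.normalizer.transform(Xs))

    def metadata(self) -> dict:
        """JSON-serialisable record of the trained state (for sidecars)."""
        spec = self.spec
        meta = {"rule": spec.rule, "selection": spec.selection, "d": spec.d,
                "selected_features": [int(j) for j in self.feature_idx]}
        if spec.rule == "3NN":
            meta["k"] = spec.knn_k
        if spec.rule == "RBF_SVM":
            meta["C"] = spec.svm_C
            meta["gamma"] = spec.svm_gamma if spec.svm_gamma is not None \
                else 1.0 / spec.d
        return meta


def train_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                     global_idx: np.ndarray | None = None,
                     scores: np.ndarray | None = None) -> TrainedClassifier:
    """Normalize, select features and fit the rule of ``spec``.

    ``global_idx`` is required for ``NONE_GLOBAL`` selection; ``scores``
    lets a caller reuse precomputed t statistics.
    """
    if spec.selection == "NONE_GLOBAL":
        if global_idx is None:
            raise ParameterError("NONE_GLOBAL selection needs the global marker indices")
        sel = np.sort(np.asarray(global_idx))
    else:
        if scores is None:
            scores = t_scores(X, y)
        sel = select_top_features(scores, spec.d)
    norm = Normalizer.fit(np.asarray(X, dtype=np.float64)[:, sel])
    rule = spec.make_rule()
    rule.fit(norm.transform(np.asarray(X, dtype=np.float64)[:, sel]), y)
    return TrainedClassifier(spec, sel, norm, rule)


def true_error(clf: TrainedClassifier, X_test: np.ndarray, y_test: np.ndarray,
               columns: np.ndarray | None = None) -> float:
    """Misclassification fraction on an independent test sample."""
    if len(y_test) == 0:
        raise ParameterError("empty test set")
    pred = clf.predict(X_test, columns=columns)
    return float(np.mean(pred != np.asarray(y_test)))
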