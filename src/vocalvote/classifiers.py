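"""Uniform train/predict contract over the benchmark classifier families.

Families and hyper-parameters mirror the comparison grid this framework
is evaluated with: k-NN with Euclidean distance (k in {1, 3, 5, 7}),
linear SVM and RBF SVM with kernel K(u, v) = exp(-||u-v||^2 / (2 sigma^2))
at sigma = 3 and C = 1, Gaussian naive Bayes, and linear discriminant
analysis (pooled covariance).  All are deterministic as configured;
estimators are delegated to scikit-learn behind this contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

FAMILIES = ("knn", "svm_linear", "svm_rbf", "naive_bayes", "discriminant")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration.

    ``k`` applies to knn only (odd, so binary votes cannot tie); ``sigma``
    is the RBF scaling factor (gamma = 1 / (2 sigma^2)); ``C`` is the SVM
    penalty.
    """

    family: str
    k: int = 5
    sigma: float = 3.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError("knn requires odd k >= 1")
        if self.family == "svm_rbf" and self.sigma <= 0:
            raise ValueError("svm_rbf requires sigma > 0")
        if self.family.startswith("svm") and self.C <= 0:
            raise ValueError("SVM requires C > 0")

    @property
    def name(self) -> str:
        if self.family == "knn":
            return f"knn_k{self.k}"
        return self.family


def make_estimator(spec: ClassifierSpec):
    """Build the scikit-learn estimator for a spec."""
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean", algorithm="brute")
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=spec.C)
    if spec.family == "svm_rbf":
        gamma = 1.0 / (2.0 * spec.sigma**2)
        return SVC(kernel="rbf", gamma=gamma, C=spec.C)
    if spec.family == "naive_bayes":
        return GaussianNB()
    if spec.family == "discriminant":
        return LinearDiscriminantAnalysis(solver="svd")
    raise AssertionError(spec.family)


def fit_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
) -> np.ndarray:
    """Train on (train_X, train_y) and predict labels for test_X.

    Deterministic given inputs and spec.  Raises if the training set has a
    single class (the decision rule would be undefined).
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain both classes")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test feature dimensions differ")
    if spec.family == "discriminant":
        return _lda_predict(train_X, train_y, test_X)
    est = make_estimator(spec)
    est.fit(train_X, train_y)
    return est.predict(test_X).astype(int)


def _lda_predict(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray) -> np.ndarray:
    """Linear discriminant with a degenerate-covariance fallback.

    Delegates to scikit-learn's LDA; when the pooled within-class scatter
    is identically zero (e.g. a feature that separates the classes
    exactly, common on toy subsets), that solver fails, so the decision is
    computed directly from the pooled covariance floored by a tiny ridge.
    """
    try:
        est = LinearDiscriminantAnalysis(solver="svd")
        est.fit(train_X, train_y)
        return est.predict(test_X).astype(int)
    except Exception:  # rank-0 within-class scatter
        pass
    classes = np.unique(train_y)
    mu0 = train_X[train_y == classes[0]].mean(axis=0)
    mu1 = train_X[train_y == classes[1]].mean(axis=0)
    centered = np.vstack(
        [train_X[train_y == classes[0]] - mu0, train_X[train_y == classes[1]] - mu1]
    )
    n, p = train_X.shape
    cov = centered.T @ centered / max(n - 2, 1)
    ridge = 1e-9 * max(1.0, float(np.trace(cov)) / p)
    w = np.linalg.solve(cov + ridge * np.eye(p), mu1 - mu0)
    n0, n1 = (train_y == classes[0]).sum(), (train_y == classes[1]).sum()
    scores = (test_X - 0.5 * (mu0 + mu1)) @ w + np.log(n1 / n0)
    return np.where(scores > 0, classes[1], classes[0]).astype(int)
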