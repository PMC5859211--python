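"""Arabica-Robusta discrimination on per-bean mean spectra.

Two classifier families, matching common chemometric practice:

* LDA/QDA after PCA compression — equal priors, a linear (pooled
  covariance) or quadratic (per-class covariance) discriminant in the
  retained principal-component subspace;
* C-SVC support vector machines with RBF or polynomial kernel, the
  (C, gamma) pair chosen by grid search under segmented cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.svm import SVC

from .preprocessing import PreprocessingChain

__all__ = ["ClassifierModel", "fit_lda", "fit_svm", "classify",
           "cv_accuracy", "DEFAULT_C_GRID", "DEFAULT_GAMMA_GRID"]

#: C-SVC grid-search defaults: powers of 4 spanning 2^-5..2^15 and 2^-15..2^3
DEFAULT_C_GRID = tuple(float(2.0 ** e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0 ** e) for e in range(-15, 4, 2))


@dataclass
class ClassifierModel:
    """A fitted species classifier (LDA/QDA after PCA, or SVM)."""

    kind: str  # lda_linear | lda_quadratic | svm
    estimator: object
    classes: np.ndarray
    pca: PCA | None = None
    n_pc: int | None = None
    params: dict = field(default_factory=dict)
    chain: PreprocessingChain | None = None
    n_features: int = 0

    def _project(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} bands, got {X.shape[1]}")
        if self.chain is not None:
            X = self.chain.transform(X)
        return self.pca.transform(X) if self.pca is not None else X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._project(X))


def _default_n_pc(Z: np.ndarray, n: int) -> int:
    """Smallest PC count explaining 99 % variance, capped at n/3."""
    pca = PCA().fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, 0.99) + 1)
    return max(1, min(k, n // 3))


def fit_lda(Xp: np.ndarray, labels: np.ndarray, n_pc: int | None = None,
            function: str = "linear",
            chain: PreprocessingChain | None = None) -> ClassifierModel:
    """PCA followed by a linear or quadratic discriminant, equal priors.

    Each class needs at least ``n_pc + 1`` members. A singular class
    covariance in the quadratic case is ridge-regularized with a
    warning.
    """
    Xp = np.asarray(Xp, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if function not in ("linear", "quadratic"):
        raise ValueError(f"unknown discriminant function {function!r}")
    if n_pc is None:
        n_pc = _default_n_pc(Xp, len(labels))
    n_pc = int(min(n_pc, len(labels) - 1, Xp.shape[1]))
    if counts.min() < n_pc + 1:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= n_pc + 1 = {n_pc + 1}"
        )
    pca = PCA(n_components=n_pc).fit(Xp)
    Z = pca.transform(Xp)
    priors = np.full(classes.size, 1.0 / classes.size)
    if function == "linear":
        est = LinearDiscriminantAnalysis(priors=priors, solver="svd")
        est.fit(Z, labels)
    else:
        est = None
        for reg in (0.0, 1e-6, 1e-3):
            candidate = QuadraticDiscriminantAnalysis(priors=priors, reg_param=reg)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", UserWarning)
                    candidate.fit(Z, labels)
            except (np.linalg.LinAlgError, UserWarning):
                continue
            if reg > 0:
                warnings.warn(
                    f"singular class covariance; ridge-regularized (reg_param={reg})",
                    stacklevel=2,
                )
            est = candidate
            break
        if est is None:
            raise np.linalg.LinAlgError(
                "class covariance singular even after ridge regularization"
            )
    return ClassifierModel(
        kind=f"lda_{function}", estimator=est, classes=classes, pca=pca,
        n_pc=n_pc, chain=chain, n_features=Xp.shape[1],
        params={"function": function, "n_pc": n_pc},
    )


def _fold_indices(n: int, n_segments: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [s for s in np.array_split(perm, n_segments) if s.size]


def cv_accuracy(fit_fn, Xp: np.ndarray, labels: np.ndarray,
                n_segments: int = 10, seed: int = 0) -> float:
    """Mean held-out accuracy of ``fit_fn(X_train, y_train) -> model``."""
    Xp = np.asarray(Xp, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    correct = 0
    for test in _fold_indices(n, n_segments, rng):
        train = np.setdiff1d(np.arange(n), test)
        model = fit_fn(Xp[train], labels[train])
        correct += int((model.predict(Xp[test]) == labels[test]).sum())
    return correct / n


def fit_svm(Xp: np.ndarray, labels: np.ndarray, kernel: str = "rbf",
            C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
            degree_grid=(2, 3), n_segments: int = 10, seed: int = 0,
            chain: PreprocessingChain | None = None):
    """Grid-searched C-SVC; returns (model, (train_accuracy, cv_accuracy)).

    The best (C, gamma[, degree]) maximizes mean CV accuracy over the
    fixed random segments; ties resolve toward smaller C, then smaller
    gamma. The winner is refitted on all rows.
    """
    Xp = np.asarray(Xp, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes for SVM")
    if kernel not in ("rbf", "poly", "polynomial"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    kernel = "poly" if kernel == "polynomial" else kernel
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grid must be non-empty")
    degrees = tuple(degree_grid) if kernel == "poly" else (3,)

    n = len(labels)
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, n_segments, rng)
    trains = [np.setdiff1d(np.arange(n), f) for f in folds]

    best = None  # (accuracy, C, gamma, degree)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            for degree in degrees:
                correct = 0
                for test, train in zip(folds, trains):
                    est = SVC(C=C, gamma=gamma, kernel=kernel, degree=degree)
                    est.fit(Xp[train], labels[train])
                    correct += int((est.predict(Xp[test]) == labels[test]).sum())
                acc = correct / n
                if best is None or acc > best[0]:
                    best = (acc, C, gamma, degree)
    cv_acc, C, gamma, degree = best
    est = SVC(C=C, gamma=gamma, kernel=kernel, degree=degree)
    est.fit(Xp, labels)
    train_acc = float((est.predict(Xp) == labels).mean())
    model = ClassifierModel(
        kind="svm", estimator=est, classes=classes, chain=chain,
        n_features=Xp.shape[1],
        params={"kernel": kernel, "C": C, "gamma": gamma, "degree": degree,
                "cv_accuracy": cv_acc, "train_accuracy": train_acc},
    )
    return model, (train_acc, cv_acc)


def classify(model: ClassifierModel, X_new: np.ndarray,
             true_labels: np.ndarray | None = None):
    """Predict labels; with truth given, also the confusion matrix panel.

    Returns predictions alone, or (predictions, confusion DataFrame,
    percent correct, percent incorrect). Truth labels outside the
    model's class set raise rather than silently relabelling.
    """
    pred = model.predict(X_new)
    if true_labels is None:
        return pred
    true_labels = np.asarray(true_labels)
    unknown = set(np.unique(true_labels)) - set(model.classes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} unknown to the model")
    classes = list(model.classes)
    cm = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(true_labels, pred):
        cm.loc[t, p] += 1
    correct = float(np.mean(pred == true_labels) * 100.0)
    return pred, cm, correct, 100.0 - correct
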