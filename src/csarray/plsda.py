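"""PLS discriminant analysis with dummy coding and argmax assignment.

Classes are one-hot ("dummy") coded; a PLS2 regression of the dummy
matrix on autoscaled features is fitted by the classical NIPALS bilinear
decomposition (X-score deflation of X only), and a new sample is assigned
to the class whose predicted dummy entry is largest.  The number of
latent variables is chosen by leave-one-out cross-validation on the
misclassification count, with a parsimony tie-break (the smallest LV
count attaining the minimum).  At full rank the fit coincides with
multivariate least squares of the dummy matrix on [1, X], which the test
suite uses as an oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_NIPALS_TOL = 1e-12
_RANK_TOL = 1e-10


@dataclass
class DummyCodeMatrix:
    codes: np.ndarray  # m x k one-hot
    class_names: list[str]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        rows = self.codes.sum(axis=1)
        if not (np.all(np.isin(self.codes, (0.0, 1.0))) and np.all(rows == 1.0)):
            raise ValueError("each dummy row must contain exactly one 1")


def encode_dummy(labels: Sequence) -> DummyCodeMatrix:
    """One-hot encode labels; class order is first appearance."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    class_names = list(dict.fromkeys(labels))
    index = {c: j for j, c in enumerate(class_names)}
    codes = np.zeros((len(labels), len(class_names)))
    for i, lab in enumerate(labels):
        codes[i, index[lab]] = 1.0
    return DummyCodeMatrix(codes, class_names)


@dataclass
class PLSDAModel:
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # p x A  (W)
    x_loadings: np.ndarray  # p x A  (P)
    y_loadings: np.ndarray  # k x A  (Q)
    scores: np.ndarray  # m x A  (T, training)
    rotations: np.ndarray  # p x A  (R = W (P'W)^-1)
    n_lv: int
    class_names: list[str]

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        """p x k regression matrix using the first ``n_lv`` latent variables."""
        A = self.n_lv if n_lv is None else n_lv
        return self.rotations[:, :A] @ self.y_loadings[:, :A].T

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_scale
        return Xs @ self.rotations

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Predicted dummy matrix for new samples."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"feature dimension mismatch: model has {self.x_mean.size}, got {X.shape[1]}"
            )
        Xs = (X - self.x_mean) / self.x_scale
        return Xs @ self.coefficients(n_lv) + self.y_mean


def pls2_fit(
    X: np.ndarray, Y: np.ndarray | DummyCodeMatrix, n_lv: int, scale: bool = True
) -> PLSDAModel:
    """NIPALS PLS2 of a dummy matrix on autoscaled features.

    Components maximize X-Y covariance; X is deflated by its score-loading
    rank-1 term after each component, so successive X-scores are mutually
    orthogonal.  Requesting more components than the data's effective rank
    raises with the achievable maximum.
    """
    class_names = None
    if isinstance(Y, DummyCodeMatrix):
        class_names = Y.class_names
        Y = Y.codes
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, p = X.shape
    if n_lv < 1 or n_lv > min(m - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(m - 1, p)}]")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0) if scale else np.ones(p)
    x_scale[x_scale == 0] = 1.0
    y_mean = Y.mean(axis=0)
    E = (X - x_mean) / x_scale
    F = Y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((m, n_lv))
    x_ss = float((E ** 2).sum())
    for a in range(n_lv):
        u = F[:, int(np.argmax(F.var(axis=0)))]
        if np.allclose(u, 0):
            raise ValueError(f"n_lv={n_lv} exceeds the data rank; at most {a} components")
        w = t = None
        for _ in range(1000):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(f"n_lv={n_lv} exceeds the data rank; at most {a} components")
            w = w / nw
            t = E @ w
            q = F.T @ t / (t @ t)
            u_new = F @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= _NIPALS_TOL * max(np.linalg.norm(u_new), 1.0):
                u = u_new
                break
            u = u_new
        tt = float(t @ t)
        if tt <= _RANK_TOL * x_ss:
            raise ValueError(f"n_lv={n_lv} exceeds the data rank; at most {a} components")
        p_a = E.T @ t / tt
        q_a = F.T @ t / tt
        E = E - np.outer(t, p_a)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t

    R = W @ np.linalg.inv(P.T @ W)
    return PLSDAModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        rotations=R,
        n_lv=n_lv,
        class_names=class_names or [f"class{j}" for j in range(Y.shape[1])],
    )


def classify(model: PLSDAModel, X_new: np.ndarray, n_lv: int | None = None) -> list:
    """Assign each sample to the class with the highest predicted dummy entry.

    Exact ties go to the lowest class index and are logged.
    """
    pred = model.predict(X_new, n_lv)
    out = []
    for i, row in enumerate(pred):
        j = int(np.argmax(row))
        if np.sum(row == row[j]) > 1:
            log.info("argmax tie on sample %d; assigned lowest class index %d", i, j)
        out.append(model.class_names[j])
    return out


def loo_select_lv(X: np.ndarray, labels: Sequence, max_lv: int) -> int:
    """Leave-one-out latent-variable count selection by misclassification.

    For each candidate count A the left-out sample is classified by argmax;
    the smallest A attaining the minimum error count is returned.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    m, p = X.shape
    if m < 3:
        raise ValueError("need at least 3 samples for leave-one-out selection")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    cap = min(m - 2, p)
    if max_lv > cap:
        warnings.warn(f"max_lv={max_lv} capped at {cap}")
        max_lv = cap
    dummy = encode_dummy(labels)
    label_idx = {c: j for j, c in enumerate(dummy.class_names)}
    errors = np.zeros(max_lv, dtype=int)
    for i in range(m):
        keep = np.arange(m) != i
        model = pls2_fit(X[keep], DummyCodeMatrix(dummy.codes[keep], dummy.class_names), max_lv)
        pred = np.vstack([model.predict(X[i:i + 1], A)[0] for A in range(1, max_lv + 1)])
        guesses = pred.argmax(axis=1)
        errors += guesses != label_idx[labels[i]]
    return int(np.argmin(errors)) + 1  # argmin ties -> smallest A (parsimony)


@dataclass
class ClassificationReport:
    accuracy: float  # percent correct
    sensitivity: dict  # per class, percent (NaN when class absent from truth)
    specificity: dict  # per class, percent
    macro_sensitivity: float
    macro_specificity: float
    confusion: pd.DataFrame  # true x predicted counts

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "macro_sensitivity_pct": self.macro_sensitivity,
            "macro_specificity_pct": self.macro_specificity,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }


def classification_metrics(y_true: Sequence, y_pred: Sequence) -> ClassificationReport:
    """Accuracy plus one-vs-rest sensitivity/specificity per class, in percent."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    classes = list(dict.fromkeys(y_true + y_pred))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, q in zip(y_true, y_pred):
        conf.loc[t, q] += 1
    m = len(y_true)
    acc = 100.0 * np.trace(conf.to_numpy()) / m
    sens, spec = {}, {}
    for c in classes:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = m - tp - fn - fp
        sens[c] = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        spec[c] = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return ClassificationReport(
        accuracy=float(acc),
        sensitivity=sens,
        specificity=spec,
        macro_sensitivity=float(np.nanmean(list(sens.values()))),
        macro_specificity=float(np.nanmean(list(spec.values()))),
        confusion=conf,
    )
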