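"""One-class PLS (OCPLS) authentication.

The genuine class alone is modeled by a PLS regression of a unit target
(a vector of ones) on the UNcentered feature matrix.  A query sample is
summarized by two diagnostics:

* score distance (SD): Mahalanobis-type distance of its latent scores
  from the training score cloud, standardized by the per-LV training
  score variance (scores are centered at the training score mean so the
  chi-square calibration of the limit is coherent);
* absolute central residual (ACR): |residual - mean training residual|
  of the unit target.

The (SD, ACR) pair places the sample in one of four categories —
regular, good leverage, class outlier, bad leverage — and only regular
points are called genuine.  Model complexity is chosen by Monte Carlo
cross-validation with a one-standard-error parsimony rule.  Threshold
defaults: SD limit sqrt(chi2(A, conf)); ACR limit mean + z(conf) * sd of
training ACR under a normal approximation, confidence 97.5%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

CATEGORIES = ("regular", "good_leverage", "class_outlier", "bad_leverage")
_RANK_TOL = 1e-12


@dataclass
class OCPLSModel:
    weights: np.ndarray  # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    rotations: np.ndarray  # p x A
    score_mean: np.ndarray  # A
    score_var: np.ndarray  # A (ddof=1)
    resid_center: float
    resid_sd: float
    sd_limit: float
    acr_limit: float
    n_lv: int
    confidence: float

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.rotations

    def predict_target(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) @ self.y_loadings


@dataclass
class Diagnostics:
    sd: float
    acr: float
    category: str


def _uncentered_pls1(X: np.ndarray, y: np.ndarray, n_lv: int):
    """NIPALS PLS1 without centering; returns (W, P, q, T)."""
    E = X.copy()
    f = y.astype(float).copy()
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    x_ss = float((E ** 2).sum())
    for a in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"n_lv={n_lv} exceeds the data rank; at most {a} components")
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL * max(x_ss, 1.0):
            raise ValueError(f"n_lv={n_lv} exceeds the data rank; at most {a} components")
        p_a = E.T @ t / tt
        q_a = float(f @ t / tt)
        E = E - np.outer(t, p_a)
        f = f - t * q_a
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    return W, P, q, T


def ocpls_fit(X_genuine: np.ndarray, n_lv: int, confidence: float = 0.975) -> OCPLSModel:
    """Fit OCPLS on genuine-class samples (uncentered, unit target)."""
    X = np.asarray(X_genuine, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 genuine training samples")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")

    W, P, q, T = _uncentered_pls1(X, np.ones(n), n_lv)
    R = W @ np.linalg.inv(P.T @ W)
    resid = 1.0 - (X @ R) @ q
    score_mean = T.mean(axis=0)
    score_var = T.var(axis=0, ddof=1)
    if np.any(score_var == 0):
        log.warning("zero training score variance in some LV; its SD term will be skipped")
    resid_center = float(resid.mean())
    acr_train = np.abs(resid - resid_center)
    resid_sd = float(acr_train.std(ddof=1))
    if resid_sd == 0:
        log.warning("degenerate residual spread (all training residuals equal)")
    sd_limit = float(np.sqrt(stats.chi2.ppf(confidence, df=n_lv)))
    acr_limit = float(acr_train.mean() + stats.norm.ppf(confidence) * acr_train.std(ddof=1))
    return OCPLSModel(
        weights=W,
        x_loadings=P,
        y_loadings=q,
        rotations=R,
        score_mean=score_mean,
        score_var=score_var,
        resid_center=resid_center,
        resid_sd=resid_sd,
        sd_limit=sd_limit,
        acr_limit=max(acr_limit, 0.0),
        n_lv=n_lv,
        confidence=confidence,
    )


def categorize(sd: float, acr: float, sd_limit: float, acr_limit: float) -> str:
    """Four-way diagnostic table; exhaustive and mutually exclusive."""
    small_sd = sd <= sd_limit
    small_acr = acr <= acr_limit
    if small_sd and small_acr:
        return "regular"
    if not small_sd and small_acr:
        return "good_leverage"
    if small_sd and not small_acr:
        return "class_outlier"
    return "bad_leverage"


def diagnose(model: OCPLSModel, X_new: np.ndarray) -> list[Diagnostics]:
    """Score distance, absolute central residual and category per query sample."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.size and X_new.shape[1] != model.rotations.shape[0]:
        raise ValueError("feature dimension mismatch")
    out = []
    if X_new.shape[0] == 0:
        return out
    T = model.scores(X_new)
    resid = 1.0 - model.predict_target(X_new)
    ok = model.score_var > 0
    for i in range(X_new.shape[0]):
        dev = (T[i] - model.score_mean)[ok]
        sd = float(np.sqrt(np.sum(dev ** 2 / model.score_var[ok])))
        acr = float(abs(resid[i] - model.resid_center))
        out.append(Diagnostics(sd=sd, acr=acr, category=categorize(sd, acr, model.sd_limit, model.acr_limit)))
    return out


def authenticate(model: OCPLSModel, X_new: np.ndarray) -> tuple[list[bool], list[Diagnostics]]:
    """Genuine verdict per sample: genuine iff the sample is a regular point."""
    diags = diagnose(model, X_new)
    return [d.category == "regular" for d in diags], diags


def mccv_select_lv(
    X_genuine: np.ndarray,
    max_lv: int,
    n_splits: int = 100,
    calibration_fraction: float = 0.8,
    seed: int = 0,
) -> int:
    """Monte Carlo CV over random calibration/validation splits.

    For each candidate LV count the mean squared validation residual of the
    unit target is averaged over splits; the smallest count within one
    standard error of the minimum is returned.
    """
    X = np.asarray(X_genuine, dtype=float)
    n = X.shape[0]
    if n_splits < 10:
        raise ValueError("n_splits must be >= 10")
    if not 0 < calibration_fraction < 1:
        raise ValueError("calibration_fraction must be in (0, 1)")
    n_cal = max(int(round(calibration_fraction * n)), 2)
    if n_cal >= n:
        n_cal = n - 1
    max_lv = min(max_lv, n_cal - 1, X.shape[1])
    rng = np.random.default_rng(seed)
    press = np.full((n_splits, max_lv), np.nan)
    for s in range(n_splits):
        perm = rng.permutation(n)
        cal, val = perm[:n_cal], perm[n_cal:]
        try:
            W, P, q, _ = _uncentered_pls1(X[cal], np.ones(n_cal), max_lv)
        except ValueError:
            # rank ran out on this split; evaluate what exists
            for a in range(1, max_lv + 1):
                try:
                    W, P, q, _ = _uncentered_pls1(X[cal], np.ones(n_cal), a)
                except ValueError:
                    break
            max_a = W.shape[1]
            W, P, q = W[:, :max_a], P[:, :max_a], q[:max_a]
        A_avail = W.shape[1]
        for a in range(1, A_avail + 1):
            R = W[:, :a] @ np.linalg.inv(P[:, :a].T @ W[:, :a])
            resid = 1.0 - (X[val] @ R) @ q[:a]
            press[s, a - 1] = float(np.mean(resid ** 2))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN/short columns
        mean = np.nanmean(press, axis=0)
        se = np.nanstd(press, axis=0, ddof=1) / np.sqrt(n_splits)
    best = int(np.nanargmin(mean))
    threshold = mean[best] + se[best]
    for a in range(len(mean)):
        if mean[a] <= threshold:
            return a + 1
    return best + 1
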