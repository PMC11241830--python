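"""Variable-weighted LS-SVM quantitation and its figures of merit.

The calibration model is a least-squares support vector machine with a
radial kernel whose squared distances carry one learned weight per
feature:

    K(x, z) = exp( - sum_k w_k (x_k - z_k)^2 / sigma2 )

Fitting solves the LS-SVM dual as one bordered linear system

    [ 0    1^T          ] [ b     ]   [ 0 ]
    [ 1    K + I/gamma  ] [ alpha ] = [ y ]

by a direct dense solve.  The weights w (0..1 per feature) and the two
hyperparameters (kernel width sigma2, error-term weight gamma) are tuned
by particle swarm optimization against a held-out monitoring set; the
swarm position is (w_1..w_p, ln sigma2, ln gamma).

Because the calibration spans four decades of concentration, targets are
log10-transformed by default (configurable); features are autoscaled on
training statistics.  Figures of merit follow analytical-chemistry
conventions: per-sample recovery (predicted/true x 100%), squared Pearson
correlation, RMSEP, and 3-sigma / 10-sigma detection and quantification
limits from blank replicates converted to g/L by molar mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .datasets import LabeledResponseSet, MOLAR_MASS_G_PER_MOL, N_FEATURES
from .pso import PSOConfig, pso_optimize

log = logging.getLogger(__name__)

__all__ = [
    "WeightedKernelSpec",
    "VWLSSVMModel",
    "FiguresOfMerit",
    "weighted_kernel_matrix",
    "lssvm_fit",
    "lssvm_predict",
    "train_pso_vwls_svm",
    "default_pso_bounds",
    "figures_of_merit",
    "lod_loq",
    "MOLAR_MASS_G_PER_MOL",
]


@dataclass(frozen=True)
class WeightedKernelSpec:
    """Per-feature kernel weights in [0,1], kernel width sigma2 > 0, error weight gamma > 0."""

    weights: np.ndarray
    kernel_width: float
    reg_weight: float

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width (sigma2) must be strictly positive")
        if self.reg_weight <= 0:
            raise ValueError("reg_weight (gamma) must be strictly positive")


def weighted_kernel_matrix(
    X: np.ndarray, Z: np.ndarray, spec: WeightedKernelSpec
) -> np.ndarray:
    """K_ij = exp(-sum_k w_k (X_ik - Z_jk)^2 / sigma2); unit diagonal when Z is X."""
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    if X.shape[1] != Z.shape[1] or X.shape[1] != spec.weights.size:
        raise ValueError("feature dimensions of X, Z and the weight vector must agree")
    sw = np.sqrt(spec.weights)
    d2 = cdist(X * sw, Z * sw, metric="sqeuclidean")
    return np.exp(-d2 / spec.kernel_width)


@dataclass
class VWLSSVMModel:
    """A fitted variable-weighted LS-SVM with its preprocessing statistics."""

    spec: WeightedKernelSpec
    support_data: np.ndarray  # training features, autoscaled
    dual_coefficients: np.ndarray  # alpha
    bias: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    log_target: bool = False
    monitoring_rmse: float | None = None
    pso_trace: list = field(default_factory=list)


def _scale_features(X, x_mean, x_scale):
    return (np.asarray(X, float) - x_mean) / x_scale


def lssvm_fit(
    X: np.ndarray, y: np.ndarray, spec: WeightedKernelSpec, log_target: bool = False
) -> VWLSSVMModel:
    """Solve the LS-SVM dual system directly; errors on a singular system.

    Features are autoscaled and targets standardized (after optional log10
    transform) on the training data; both transforms are stored in the
    model and undone at prediction time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least 1 training sample")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if log_target:
        if np.any(y <= 0):
            raise ValueError("log-target mode requires strictly positive targets")
        y = np.log10(y)

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = _scale_features(X, x_mean, x_scale)
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    ys = (y - y_mean) / y_scale

    K = weighted_kernel_matrix(Xs, Xs, spec)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / spec.reg_weight
    rhs = np.concatenate([[0.0], ys])
    with warnings.catch_warnings():
        warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
        try:
            sol = scipy.linalg.solve(A, rhs)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgWarning, ValueError) as exc:
            raise np.linalg.LinAlgError(
                f"LS-SVM system is singular or ill-conditioned: {exc}"
            ) from None
    return VWLSSVMModel(
        spec=spec,
        support_data=Xs,
        dual_coefficients=sol[1:],
        bias=float(sol[0]),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        log_target=log_target,
    )


def lssvm_predict(model: VWLSSVMModel, X_new: np.ndarray) -> np.ndarray:
    """yhat(x) = sum_i alpha_i K(x_i, x) + b, back-transformed to concentration units."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.support_data.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model has {model.support_data.shape[1]}, "
            f"got {X_new.shape[1]}"
        )
    Xs = _scale_features(X_new, model.x_mean, model.x_scale)
    K = weighted_kernel_matrix(Xs, model.support_data, model.spec)
    ys = K @ model.dual_coefficients + model.bias
    y = ys * model.y_scale + model.y_mean
    return 10.0 ** y if model.log_target else y


_LN10 = np.log(10.0)


def default_pso_bounds(n_features: int = N_FEATURES) -> tuple[np.ndarray, np.ndarray]:
    """Search box: w in [0,1] per feature, log10 sigma2 in [-6,6], log10 gamma in [-2,8].

    The swarm works on the natural-log scale internally; the gamma range
    reaches 1e8 so the near-interpolation regime of low-noise calibrations
    stays inside the box.
    """
    lo = np.concatenate([np.zeros(n_features), [-6.0 * _LN10, -2.0 * _LN10]])
    hi = np.concatenate([np.ones(n_features), [6.0 * _LN10, 8.0 * _LN10]])
    return lo, hi


def _position_to_spec(position: np.ndarray, n_features: int) -> WeightedKernelSpec:
    return WeightedKernelSpec(
        weights=np.clip(position[:n_features], 0.0, 1.0),
        kernel_width=float(np.exp(position[n_features])),
        reg_weight=float(np.exp(position[n_features + 1])),
    )


def train_pso_vwls_svm(
    train: LabeledResponseSet | tuple[np.ndarray, np.ndarray],
    monitor: LabeledResponseSet | tuple[np.ndarray, np.ndarray],
    pso: PSOConfig | None = None,
    log_target: bool = True,
    target_column: str = "concentration",
) -> VWLSSVMModel:
    """Tune (weights, sigma2, gamma) by PSO on monitoring-set RMSE; refit at the optimum.

    The objective is the root-mean-square monitoring error in
    concentration units.  In log-target mode the *fit* is performed on
    log10 concentrations (anchoring the low decades of a multi-decade
    calibration) while the objective stays in original units.  Ties keep
    the first-found position.
    """
    X_tr, y_tr = _unpack(train, target_column)
    X_mo, y_mo = _unpack(monitor, target_column)
    if len(y_mo) < 2:
        raise ValueError("monitoring set must contain at least 2 samples")
    if X_tr.shape[1] != X_mo.shape[1]:
        raise ValueError("train and monitor must share a feature space")
    if X_tr.shape == X_mo.shape and np.array_equal(X_tr, X_mo):
        log.warning("monitoring set equals training set; objective degenerates to training RMSE")

    p = X_tr.shape[1]
    if pso is None:
        lo, hi = default_pso_bounds(p)
        pso = PSOConfig(bounds_lo=lo, bounds_hi=hi)

    def objective(position: np.ndarray) -> float:
        spec = _position_to_spec(position, p)
        try:
            model = lssvm_fit(X_tr, y_tr, spec, log_target=log_target)
        except np.linalg.LinAlgError:
            return np.inf
        pred = lssvm_predict(model, X_mo)
        return float(np.sqrt(np.mean((pred - y_mo) ** 2)))

    best_pos, best_val, trace = pso_optimize(objective, pso)
    model = lssvm_fit(X_tr, y_tr, _position_to_spec(best_pos, p), log_target=log_target)
    model.monitoring_rmse = best_val
    model.pso_trace = trace
    return model


def _unpack(data, target_column: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, LabeledResponseSet):
        return data.features, data.labels[target_column].to_numpy(float)
    X, y = data
    return np.asarray(X, float), np.asarray(y, float).ravel()


@dataclass
class FiguresOfMerit:
    recovery_pct: np.ndarray  # per-sample predicted/true x 100
    recovery_mean: float
    recovery_sd: float
    r2: float
    rmsep: float
    lod_g_per_l: float | None = None
    loq_g_per_l: float | None = None
    blank_sigma_mmol_l: float | None = None

    def to_dict(self) -> dict:
        return {
            "recovery_mean_pct": self.recovery_mean,
            "recovery_sd_pct": self.recovery_sd,
            "r2": self.r2,
            "rmsep_mmol_l": self.rmsep,
            "lod_g_per_l": self.lod_g_per_l,
            "loq_g_per_l": self.loq_g_per_l,
        }


def figures_of_merit(
    model: VWLSSVMModel,
    predict: LabeledResponseSet | tuple[np.ndarray, np.ndarray],
    target_column: str = "concentration",
) -> FiguresOfMerit:
    """Recovery, r^2 and RMSEP on the prediction set.

    r^2 is the squared Pearson correlation of predicted vs true.  Samples
    with a true concentration of zero are excluded from recovery (ratio
    undefined) but kept in r^2 and RMSEP.
    """
    X, y = _unpack(predict, target_column)
    if len(y) == 0:
        raise ValueError("prediction set is empty")
    yhat = lssvm_predict(model, X)
    nz = y != 0
    recovery = 100.0 * yhat[nz] / y[nz]
    r = np.corrcoef(yhat, y)[0, 1]
    return FiguresOfMerit(
        recovery_pct=recovery,
        recovery_mean=float(recovery.mean()),
        recovery_sd=float(recovery.std(ddof=1)) if len(recovery) > 1 else 0.0,
        r2=float(r ** 2),
        rmsep=float(np.sqrt(np.mean((yhat - y) ** 2))),
    )


def lod_loq(
    blank_features: np.ndarray, model: VWLSSVMModel, molar_mass_g_per_mol: float
) -> tuple[float, float, float]:
    """3-sigma / 10-sigma limits from blank replicates, in g/L.

    sigma is the standard deviation of the model-predicted concentration
    over >= 3 blank replicate rows; LOD = 3 sigma and LOQ = 10 sigma are
    converted from mmol/L via the analyte molar mass.
    """
    blank_features = np.atleast_2d(np.asarray(blank_features, float))
    if blank_features.shape[0] < 3:
        raise ValueError("at least 3 blank replicates required")
    preds = lssvm_predict(model, blank_features)
    sigma = float(preds.std(ddof=1))
    if sigma == 0:
        log.warning("identical blank replicates: sigma = 0, LOD = LOQ = 0")
    to_g_per_l = molar_mass_g_per_mol / 1000.0  # mmol/L -> g/L
    return 3.0 * sigma * to_g_per_l, 10.0 * sigma * to_g_per_l, sigma
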