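"""Class-weighted RBF-kernel SVM with Platt-calibrated probabilities.

The classifier is a soft-margin SVM with kernel k(u, v) = exp(-gamma
||u - v||^2) and per-class penalty C * w_class; the cohort is imbalanced
(roughly 70% IDH mutant), so the minority wildtype class carries a larger
weight (default mutant:1, wildtype:3).  Decision values are mapped to
posterior probabilities by Platt's sigmoid p = 1 / (1 + exp(A f + B)),
fitted on out-of-inner-fold decision values with the smoothed targets
t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2) that regularise the
maximum-likelihood fit.

Hyperparameters (C, gamma) are chosen by grid search over a logarithmic
libsvm-style grid, scored by stratified inner cross-validation.  Feature
columns are z-scored with statistics fitted on the training part only.

The quadratic-programming solver is scikit-learn's SVC (libsvm); the
surrounding standardisation, calibration, selection and ensembling logic
lives here.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

POSITIVE_LABEL = 1  # IDH mutant

DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))  # 2^-5 .. 2^15
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-15, 4, 2))  # 2^-15 .. 2^3


class CalibrationError(ValueError):
    """Raised when the sigmoid fit is degenerate (all-equal decision values)."""


@dataclasses.dataclass(frozen=True)
class SVMConfig:
    """Grid, class weights and selection metric for the nested search."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    class_weights: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {1: 1.0, 0: 3.0}  # mutant majority 1, wildtype 3
    )
    selection_metric: str = "f1"
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")
        if self.selection_metric not in ("f1", "recall"):
            raise ValueError("selection_metric must be 'f1' or 'recall'")


@dataclasses.dataclass
class TrainedModel:
    """A fitted SVM with its standardisation and calibration parameters.

    The decision function is carried explicitly as support vectors, dual
    coefficients and intercept, so a model deserialised from its JSON
    container evaluates identically to the freshly fitted one.
    """

    svc: SVC | None
    C: float
    gamma: float
    platt_a: float
    platt_b: float
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    n_features: int
    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    intercept: float = 0.0

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature schema mismatch: model expects {self.n_features} "
                f"columns, got {X.shape[1]}"
            )
        Xs = (X - self.feat_mean) / self.feat_scale
        if self.svc is not None:
            return self.svc.decision_function(Xs)
        # f(x) = sum_i alpha_i k(sv_i, x) + b with the RBF kernel
        d2 = (
            (Xs**2).sum(axis=1)[:, None]
            - 2.0 * Xs @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Calibrated probability of the positive (mutant) class, in (0,1)."""
        return platt_probability(self.decision_values(X), self.platt_a, self.platt_b)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns pass through centred
    return mean, scale


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    weights: Mapping[int, float] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the weighted soft-margin RBF-SVM at fixed (C, gamma).

    Columns are z-scored with training statistics; the per-class penalty is
    C * w_class.  The returned model carries placeholder sigmoid parameters
    until :func:`platt_calibrate` is applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_training_inputs(X, y)
    mean, scale = _standardize_fit(X)
    svc = SVC(
        C=C,
        gamma=gamma,
        kernel="rbf",
        class_weight=dict(weights) if weights else None,
        tol=1e-8,  # tight stopping criterion: label-swap symmetric solutions
        random_state=seed,
    )
    svc.fit((X - mean) / scale, y)
    return TrainedModel(
        svc=svc, C=C, gamma=gamma, platt_a=-1.0, platt_b=0.0,
        feat_mean=mean, feat_scale=scale, n_features=X.shape[1],
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
    )


MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Serialise a trained model to a versioned JSON container."""
    import json

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "C": model.C,
        "gamma": model.gamma,
        "platt_a": model.platt_a,
        "platt_b": model.platt_b,
        "feat_mean": model.feat_mean.tolist(),
        "feat_scale": model.feat_scale.tolist(),
        "n_features": model.n_features,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model container version {d.get('format_version')}")
    return TrainedModel(
        svc=None, C=d["C"], gamma=d["gamma"],
        platt_a=d["platt_a"], platt_b=d["platt_b"],
        feat_mean=np.asarray(d["feat_mean"]), feat_scale=np.asarray(d["feat_scale"]),
        n_features=d["n_features"],
        support_vectors=np.asarray(d["support_vectors"]),
        dual_coef=np.asarray(d["dual_coef"]), intercept=d["intercept"],
    )


# ---------------------------------------------------------------------------
# Platt calibration


def platt_probability(f: np.ndarray, a: float, b: float) -> np.ndarray:
    """Sigmoid map p = 1 / (1 + exp(a f + b)), numerically stable."""
    z = a * np.asarray(f, dtype=float) + b
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
    return out


def fit_platt_sigmoid(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit (A, B) minimising the negative log-likelihood of the sigmoid with
    Platt's smoothed targets."""
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise CalibrationError("calibration needs both classes")
    if np.ptp(f) == 0:
        raise CalibrationError("all decision values equal; sigmoid is degenerate")
    n_pos = int((y == POSITIVE_LABEL).sum())
    n_neg = y.size - n_pos
    t = np.where(y == POSITIVE_LABEL, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * f + b
        # -[t log p + (1-t) log(1-p)] with p = sigma(-z), stable via logaddexp
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="BFGS")
    a, b = res.x
    return float(a), float(b)


def platt_calibrate(
    model: TrainedModel, f_values: np.ndarray, y: np.ndarray
) -> TrainedModel:
    """Return a copy of the model with fitted sigmoid parameters.

    ``f_values`` should be out-of-fold decision values for the same subjects
    as ``y`` — calibrating on training-set decision values is optimistically
    biased.
    """
    a, b = fit_platt_sigmoid(f_values, y)
    return dataclasses.replace(model, platt_a=a, platt_b=b)


def cross_val_decision_values(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float,
    weights: Mapping[int, float] | None, folds: int, seed: int,
) -> np.ndarray:
    """Out-of-fold decision values from a stratified K-fold refit at fixed
    hyperparameters (the calibration inputs)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    f = np.empty(len(y), dtype=float)
    for tr, te in skf.split(X, y):
        m = train_svm(X[tr], y[tr], C, gamma, weights, seed)
        f[te] = m.decision_values(X[te])
    return f


# ---------------------------------------------------------------------------
# Grid search


def _score(y_true: np.ndarray, y_pred: np.ndarray, metric: str) -> float:
    """F1 or recall on the minority (wildtype, label 0) class."""
    pos = 0  # minority class of interest for selection
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    fn = int(np.sum((y_pred != pos) & (y_true == pos)))
    fp = int(np.sum((y_pred == pos) & (y_true != pos)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    if metric == "recall":
        return recall
    precision = tp / (tp + fp) if tp + fp else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def grid_search(
    X: np.ndarray, y: np.ndarray, cfg: SVMConfig, inner_folds: int | None = None
) -> tuple[float, float]:
    """Pick (C*, gamma*) by stratified inner CV over the full grid.

    Scores are the selection metric averaged over inner folds; ties break
    toward smaller C, then smaller gamma.
    """
    folds = inner_folds if inner_folds is not None else cfg.inner_folds
    if folds < 2:
        raise ValueError("inner_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold inner CV impossible: a class has "
            f"{counts.min()} members"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))
    best = None
    for C in sorted(cfg.C_grid):
        for gamma in sorted(cfg.gamma_grid):
            scores = []
            for tr, te in splits:
                m = train_svm(X[tr], y[tr], C, gamma, cfg.class_weights, cfg.seed)
                Xs = (X[te] - m.feat_mean) / m.feat_scale
                scores.append(_score(y[te], m.svc.predict(Xs), cfg.selection_metric))
            mean_score = float(np.mean(scores))
            if best is None or mean_score > best[0] + 1e-12:
                best = (mean_score, C, gamma)
    return best[1], best[2]


def fit_calibrated(
    X: np.ndarray, y: np.ndarray, cfg: SVMConfig,
    C: float | None = None, gamma: float | None = None,
) -> TrainedModel:
    """Full training path: grid search (unless (C, gamma) given), Platt fit on
    out-of-inner-fold decision values, final refit on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if C is None or gamma is None:
        C, gamma = grid_search(X, y, cfg)
    f_oof = cross_val_decision_values(
        X, y, C, gamma, cfg.class_weights, cfg.inner_folds, cfg.seed
    )
    model = train_svm(X, y, C, gamma, cfg.class_weights, cfg.seed)
    return platt_calibrate(model, f_oof, y)


def ensemble_predict(models: Sequence[TrainedModel], X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of calibrated mutant probabilities across models."""
    if not models:
        raise ValueError("need at least one model")
    n_feat = {m.n_features for m in models}
    if len(n_feat) > 1:
        raise ValueError(f"models disagree on the feature schema: {sorted(n_feat)}")
    return np.mean([m.predict_proba(X) for m in models], axis=0)
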