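"""Nested five-fold cross-validated evaluation.

Outer folds estimate generalisation; inner folds (inside ``svmclf``) select
(C, gamma).  Out-of-fold calibrated probabilities are pooled across outer
folds into one confusion-count / ROC / AUC computation — the reading under
which the per-modality confusion counts sum to the cohort size.  The
decision threshold on the calibrated mutant probability is 0.5.

Model comparisons use DeLong's paired test on the pooled out-of-fold
probabilities (with a seeded permutation fallback for tiny strata) and
Benjamini-Hochberg false-discovery-rate adjustment across the requested
pairs.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, KFold
from statsmodels.stats.multitest import multipletests

from .svmclf import SVMConfig, TrainedModel, ensemble_predict, fit_calibrated
from .volio import DegenerateInputError

DECISION_THRESHOLD = 0.5


class LeakageError(ValueError):
    """Raised when held-out subjects overlap the training cohort."""


# ---------------------------------------------------------------------------
# Fold plans


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Subject-to-outer-fold assignment (fold indices 1..K)."""

    assignments: tuple[int, ...]
    K: int
    seed: int
    stratified: bool

    def fold_indices(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(self.assignments)
        return np.where(a != k)[0], np.where(a == k)[0]


def make_fold_plan(
    labels: Sequence[int], K: int = 5, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Seeded, reproducible K-fold partition, stratified by label by default."""
    y = np.asarray(labels, dtype=int)
    if K < 2:
        raise ValueError("K must be >= 2")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < K:
            raise ValueError(
                f"stratified {K}-fold needs >= {K} members per class, "
                f"smallest class has {counts.min()}"
            )
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
    assign = np.empty(len(y), dtype=int)
    for k, (_, te) in enumerate(splitter.split(np.zeros((len(y), 1)), y), start=1):
        assign[te] = k
    return FoldPlan(tuple(int(a) for a in assign), K, seed, stratified)


# ---------------------------------------------------------------------------
# Metrics


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, precision) from confusion counts."""
    if tp + fn == 0 or tn + fp == 0:
        raise DegenerateInputError("confusion counts lack one of the classes")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else float("nan")
    return sens, spec, prec


def roc_auc(
    probabilities: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC points by threshold sweep and the AUC as pairwise concordance
    P(p_pos > p_neg) + 0.5 P(p_pos = p_neg).

    Returns (roc_points, auc) with roc_points an (n_thresholds, 2) array of
    (FPR, TPR) pairs including the (0,0) and (1,1) endpoints.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC needs both classes")
    # midrank formulation of the concordance statistic (ties count 1/2)
    ranks = sps.rankdata(p)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-p, kind="stable")
    ps, ys = p[order], y[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    last = np.r_[np.where(np.diff(ps))[0], len(ps) - 1]  # one point per threshold
    points = np.column_stack([fps[last] / n_neg, tps[last] / n_pos])
    points = np.vstack([[0.0, 0.0], points])
    return points, float(auc)


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclasses.dataclass
class CVReport:
    """Pooled out-of-fold results of one nested-CV run."""

    subject_ids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray  # pooled out-of-fold mutant probabilities
    fold_plan: FoldPlan
    chosen_params: list[tuple[float, float]]  # per-fold (C, gamma)
    models: list[TrainedModel]
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    auc: float = float("nan")
    roc_points: np.ndarray | None = None

    def finalize(self) -> "CVReport":
        pred = (self.probabilities >= DECISION_THRESHOLD).astype(int)
        y = self.labels
        self.tp = int(np.sum((pred == 1) & (y == 1)))
        self.fp = int(np.sum((pred == 1) & (y == 0)))
        self.tn = int(np.sum((pred == 0) & (y == 0)))
        self.fn = int(np.sum((pred == 0) & (y == 1)))
        self.sensitivity, self.specificity, _ = confusion_metrics(
            self.tp, self.fp, self.tn, self.fn
        )
        self.roc_points, self.auc = roc_auc(self.probabilities, self.labels)
        return self

    def to_json(self, path) -> None:
        payload = {
            "subject_ids": self.subject_ids,
            "labels": self.labels.tolist(),
            "probabilities": self.probabilities.tolist(),
            "fold_assignments": list(self.fold_plan.assignments),
            "chosen_params": self.chosen_params,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "roc_points": None if self.roc_points is None else self.roc_points.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def run_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SVMConfig,
    plan: FoldPlan,
    subject_ids: Sequence[str] | None = None,
) -> CVReport:
    """Nested K-fold CV: per outer fold, grid-search on the training part,
    train and calibrate on it, predict held-out probabilities; pool all
    out-of-fold probabilities into one metric computation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if len(plan.assignments) != len(y):
        raise ValueError("fold plan does not cover the cohort")
    if subject_ids is None:
        subject_ids = [f"s{i:04d}" for i in range(len(y))]
    probs = np.empty(len(y), dtype=float)
    chosen, models = [], []
    for k in range(1, plan.K + 1):
        tr, te = plan.fold_indices(k)
        if np.unique(y[tr]).size < 2:
            raise ValueError(f"outer fold {k}: training part is single-class")
        model = fit_calibrated(X[tr], y[tr], cfg)
        probs[te] = model.predict_proba(X[te])
        chosen.append((model.C, model.gamma))
        models.append(model)
    report = CVReport(
        subject_ids=list(subject_ids), labels=y, probabilities=probs,
        fold_plan=plan, chosen_params=chosen, models=models,
    )
    return report.finalize()


# ---------------------------------------------------------------------------
# Paired model comparison (DeLong + FDR)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def delong_paired_test(
    p1: np.ndarray, p2: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong's paired test for the difference of two correlated AUCs.

    Returns (auc1 - auc2, two-sided p).  The covariance of the placement
    values of the two score vectors on the same subjects accounts for the
    pairing.
    """
    y = np.asarray(labels, dtype=int)
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise DegenerateInputError("DeLong needs both classes")
    aucs = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for i, p in enumerate((np.asarray(p1, float), np.asarray(p2, float))):
        tx = _midrank(p[pos])
        ty = _midrank(p[neg])
        tz = _midrank(p)
        aucs[i] = (tz[pos].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[i] = (tz[pos] - tx) / n
        v01[i] = 1.0 - (tz[neg] - ty) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        return float(diff), 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    p_val = 2.0 * sps.norm.sf(abs(z))
    return float(diff), float(min(p_val, 1.0))


def permutation_auc_test(
    p1: np.ndarray, p2: np.ndarray, labels: np.ndarray,
    n_permutations: int = 2000, seed: int = 0,
) -> tuple[float, float]:
    """Sign-flip permutation test on the paired AUC difference: per subject
    the two model scores are swapped with probability 1/2."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    y = np.asarray(labels, int)
    _, a1 = roc_auc(p1, y)
    _, a2 = roc_auc(p2, y)
    observed = a1 - a2
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        swap = rng.random(len(y)) < 0.5
        q1 = np.where(swap, p2, p1)
        q2 = np.where(swap, p1, p2)
        _, b1 = roc_auc(q1, y)
        _, b2 = roc_auc(q2, y)
        if abs(b1 - b2) >= abs(observed) - 1e-12:
            count += 1
    return float(observed), (count + 1) / (n_permutations + 1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


@dataclasses.dataclass
class ComparisonResult:
    pair: tuple[str, str]
    auc_difference: float
    p_value: float
    p_adjusted: float = float("nan")


def compare_models(
    reports: Sequence[CVReport],
    pairs: Sequence[tuple[int, int]],
    names: Sequence[str] | None = None,
    method: str = "delong",
    seed: int = 0,
) -> list[ComparisonResult]:
    """Paired AUC-difference tests between CV reports sharing one fold plan,
    with BH adjustment across the requested pairs."""
    if names is None:
        names = [f"model{i}" for i in range(len(reports))]
    ref = reports[0]
    for r in reports[1:]:
        if r.subject_ids != ref.subject_ids or r.fold_plan.assignments != ref.fold_plan.assignments:
            raise ValueError("reports are not paired (subjects/fold plan differ)")
    results = []
    for i, j in pairs:
        ri, rj = reports[i], reports[j]
        if method == "delong":
            diff, p = delong_paired_test(ri.probabilities, rj.probabilities, ri.labels)
        elif method == "permutation":
            diff, p = permutation_auc_test(
                ri.probabilities, rj.probabilities, ri.labels, seed=seed
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(ComparisonResult((names[i], names[j]), diff, p))
    adj = bh_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


# ---------------------------------------------------------------------------
# Sweeps and held-out evaluation


def layer_sweep(
    feature_matrices: dict[int, np.ndarray],
    y: np.ndarray,
    cfg: SVMConfig,
    plan: FoldPlan,
    subject_ids: Sequence[str] | None = None,
) -> list[dict]:
    """One nested-CV row per conv-depth L, all rows sharing the fold plan.

    ``feature_matrices`` maps L -> the cohort feature matrix extracted with
    ``n_layers_used=L``.
    """
    rows = []
    for L in sorted(feature_matrices):
        rep = run_nested_cv(feature_matrices[L], y, cfg, plan, subject_ids)
        rows.append(
            {
                "L": L,
                "n_features": feature_matrices[L].shape[1],
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "auc": rep.auc,
                "report": rep,
            }
        )
    return rows


def holdout_ensemble_eval(
    models: Sequence[TrainedModel],
    X: np.ndarray,
    y: np.ndarray,
    holdout_ids: Sequence[str],
    training_ids: Sequence[str],
) -> dict:
    """Average the K fold models on a disjoint held-out cohort and report
    confusion metrics and AUC."""
    overlap = set(holdout_ids) & set(training_ids)
    if overlap:
        raise LeakageError(f"held-out subjects overlap training: {sorted(overlap)}")
    probs = ensemble_predict(models, np.asarray(X, float))
    pred = (probs >= DECISION_THRESHOLD).astype(int)
    y = np.asarray(y, int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens, spec, prec = confusion_metrics(tp, fp, tn, fn)
    _, auc = roc_auc(probs, y)
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens, "specificity": spec, "precision": prec,
        "auc": auc, "probabilities": probs,
    }
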