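"""Tenfold double cross-validation model comparison.

Outer folds estimate test performance; the inner loop (5-fold grid
search maximising AUC, training rows only) picks hyperparameters.  The
point-wise linear network is compared against logistic-regression,
random-forest and SVM baselines on the metabolomic, clinical and
combined design matrices.

Leakage discipline: standardisation statistics of every scaled column
are refit on the outer training rows (via
:meth:`EncodedMatrix.values_for_rows`), and the inner search never sees
the outer test rows.  Outer folds are drawn randomly, not stratified;
with ~10 % positives a positive-free test fold is possible -- such folds
are skipped in the AUC aggregation with a warning, and the fold maker
redraws once if any test fold lacks positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .encoding import EncodedMatrix
from .errors import DomainError
from .pairsearch import max_f1_threshold, rank_auc
from .pwlnet import PWLNetConfig, fit_pwl_net, predict_proba as pwl_predict_proba

logger = logging.getLogger(__name__)

MODEL_NAMES = ("pwl_net", "logistic", "random_forest", "svm")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"max_depth": [2, 4, None], "n_estimators": [200]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "pwl_net": {"weight_decay": [1e-3, 1e-2]},
}


@dataclass
class FoldPlan:
    k: int
    assignment: np.ndarray  # sample index -> fold id
    seed: int

    def folds(self) -> Iterable[tuple[np.ndarray, np.ndarray]]:
        idx = np.arange(self.assignment.size)
        for f in range(self.k):
            test = idx[self.assignment == f]
            yield idx[self.assignment != f], test

    def check_partition(self) -> None:
        sizes = np.bincount(self.assignment, minlength=self.k)
        if sizes.sum() != self.assignment.size or sizes.max() - sizes.min() > 1:
            raise AssertionError("fold sizes must partition the samples and differ by at most 1")


def make_dcv_folds(
    n: int, k: int = 10, seed: int = 0, y: np.ndarray | None = None
) -> FoldPlan:
    """Random partition of ``n`` samples into ``k`` folds of near-equal size.

    If ``y`` is given and any test fold lacks a positive sample, the plan
    is redrawn once (same generator) before being returned as-is.
    """
    if n < k:
        raise DomainError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)

    def draw() -> np.ndarray:
        perm = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        sizes = [n // k + (1 if f < n % k else 0) for f in range(k)]
        start = 0
        for f, s in enumerate(sizes):
            assignment[perm[start : start + s]] = f
            start += s
        return assignment

    assignment = draw()
    if y is not None:
        y = np.asarray(y).astype(bool)
        if any(y[assignment == f].sum() == 0 for f in range(k)):
            logger.warning("a test fold lacks positives; redrawing the fold plan once")
            assignment = draw()
    plan = FoldPlan(k, assignment, seed)
    plan.check_partition()
    return plan


# ---------------------------------------------------------------------------
# model factories


def _make_estimator(name: str, params: dict, seed: int):
    if name == "logistic":
        return LogisticRegression(
            C=params.get("C", 1.0), max_iter=5000, class_weight=params.get("class_weight")
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 200),
            max_depth=params.get("max_depth"),
            random_state=seed,
        )
    if name == "svm":
        return _PlattSVM(
            C=params.get("C", 1.0), gamma=params.get("gamma", "scale"), seed=seed
        )
    raise DomainError(f"unknown model {name!r}")


class _PlattSVM:
    """SVC with probability outputs via an explicit logistic (Platt)
    calibration of the training margins.

    The built-in probability estimate cross-validates internally and can
    come out anti-calibrated on cohorts this small; a direct 1-D
    logistic fit on the training decision values is deterministic and
    monotone in the margin.
    """

    def __init__(self, C: float, gamma, seed: int):
        self.svc = SVC(C=C, gamma=gamma, random_state=seed)
        self.platt = None

    def fit(self, X, y):
        from .pairsearch import _newton_logistic

        self.svc.fit(X, y)
        margin = self.svc.decision_function(X)
        self.platt = _newton_logistic(margin[:, None], np.asarray(y, dtype=float))
        return self

    def predict_proba(self, X):
        from scipy.special import expit

        margin = self.svc.decision_function(X)
        p1 = expit(margin * self.platt[0] + self.platt[1])
        return np.column_stack([1 - p1, p1])


class _PWLNetEstimator:
    """Adapter giving the point-wise linear net the fit/predict_proba surface."""

    def __init__(self, params: dict, seed: int):
        self.cfg = PWLNetConfig(
            hidden_layers=params.get("hidden_layers", 2),
            width=params.get("width", 16),
            weight_decay=params.get("weight_decay", 1e-3),
            max_epochs=params.get("max_epochs", 200),
        )
        self.seed = seed
        self.model = None

    def fit(self, X, y):
        self.model = fit_pwl_net(X, y, hyper=self.cfg, seed=self.seed)
        return self

    def predict_proba(self, X):
        p1 = pwl_predict_proba(self.model, X)
        return np.column_stack([1 - p1, p1])


def model_factory(name: str, seed: int = 0) -> Callable[[dict], object]:
    """Factory closure for one of the four model families."""
    if name == "pwl_net":
        return lambda params: _PWLNetEstimator(params, seed)
    return lambda params: _make_estimator(name, params, seed)


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


# ---------------------------------------------------------------------------
# metrics


def metrics_at_threshold(
    probabilities: np.ndarray, y: np.ndarray, rule: str | float = "max_f1"
) -> dict:
    """Confusion-matrix metrics at a probability threshold.

    ``rule`` is either ``"max_f1"`` (threshold maximising F1 over the
    observed probabilities) or a fixed numeric cut; ``p >= threshold``
    is called positive.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=bool)
    if p.size == 0:
        raise DomainError("empty probability vector")
    if np.any((p < 0) | (p > 1)):
        raise DomainError("probabilities must lie in [0, 1]")
    t = max_f1_threshold(p, y) if rule == "max_f1" else float(rule)
    pred = p >= t
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "threshold": t,
        "f1": 2 * precision * recall / (precision + recall) if precision + recall else 0.0,
        "accuracy": (tp + tn) / p.size,
        "precision": precision,
        "recall": recall,
        "fpr": fp / (fp + tn) if fp + tn else 0.0,
        "fnr": fn / (fn + tp) if fn + tp else 0.0,
    }


# ---------------------------------------------------------------------------
# the harness


@dataclass
class DCVResult:
    model: str
    dataset_tag: str
    per_fold: pd.DataFrame
    chosen_params: list = field(default_factory=list)

    def summary(self) -> dict:
        ok = self.per_fold[~self.per_fold["skipped"]]
        return {
            "model": self.model,
            "dataset": self.dataset_tag,
            "train_auc_mean": float(ok["train_auc"].mean()),
            "train_auc_sd": float(ok["train_auc"].std(ddof=0)),
            "test_auc_mean": float(ok["test_auc"].mean()),
            "test_auc_sd": float(ok["test_auc"].std(ddof=0)),
            "n_folds_used": int(len(ok)),
        }


def _inner_select(
    factory, grid_pts: list[dict], X_rows: np.ndarray, y: np.ndarray, inner_k: int, seed: int
) -> dict:
    if len(grid_pts) == 1:
        return grid_pts[0]
    plan = make_dcv_folds(len(y), min(inner_k, len(y)), seed=seed, y=y)
    best, best_auc = grid_pts[0], -np.inf
    for params in grid_pts:
        aucs = []
        for tr, te in plan.folds():
            if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
                continue
            est = factory(params)
            est.fit(X_rows[tr], y[tr])
            aucs.append(rank_auc(est.predict_proba(X_rows[te])[:, 1], y[te]))
        mean = np.mean(aucs) if aucs else -np.inf
        if mean > best_auc:
            best, best_auc = params, mean
    return best


def run_dcv(
    model,
    X: EncodedMatrix | np.ndarray,
    y: np.ndarray,
    plan: FoldPlan,
    inner_grid: dict[str, list] | None = None,
    inner_k: int = 5,
    seed: int = 0,
    threshold_rule: str | float = "max_f1",
) -> DCVResult:
    """One model family through the double cross-validation.

    ``model`` is a registered name or a callable ``params -> estimator``.
    Per outer fold: inner grid search on the training rows only, refit on
    the full training set, AUC on the train and test partitions plus
    secondary metrics at the threshold rule.
    """
    if isinstance(model, str):
        name, factory = model, model_factory(model, seed)
        grid = inner_grid if inner_grid is not None else DEFAULT_GRIDS[model]
    else:
        name, factory = getattr(model, "__name__", "custom"), model
        grid = inner_grid or {}
    grid_pts = _grid_points(grid) if grid else [{}]
    y = np.asarray(y, dtype=int).ravel()
    if isinstance(X, EncodedMatrix) and X.n_samples != plan.assignment.size:
        raise DomainError("fold plan does not cover the samples of X")

    rows, chosen = [], []
    for fold, (tr, te) in enumerate(plan.folds()):
        vals = X.values_for_rows(tr) if isinstance(X, EncodedMatrix) else np.asarray(X, float)
        params = _inner_select(factory, grid_pts, vals[tr], y[tr], inner_k, seed * 1000 + fold)
        chosen.append(params)
        est = factory(params)
        est.fit(vals[tr], y[tr])
        p_tr = est.predict_proba(vals[tr])[:, 1]
        p_te = est.predict_proba(vals[te])[:, 1]
        train_auc = rank_auc(p_tr, y[tr])
        if np.unique(y[te]).size < 2:
            logger.warning("outer fold %d has a single-class test set; AUC skipped", fold)
            rows.append({"fold": fold, "train_auc": train_auc, "test_auc": np.nan,
                         "skipped": True})
            continue
        sec = metrics_at_threshold(p_te, y[te], threshold_rule)
        rows.append({"fold": fold, "train_auc": train_auc,
                     "test_auc": rank_auc(p_te, y[te]), "skipped": False, **sec})
    return DCVResult(name, getattr(X, "dataset_tag", "array"), pd.DataFrame(rows), chosen)


def compare_models(
    datasets: dict[str, EncodedMatrix],
    y: np.ndarray,
    models: Sequence[str] = MODEL_NAMES,
    k: int = 10,
    seed: int = 0,
    inner_grids: dict[str, dict] | None = None,
) -> tuple[pd.DataFrame, list[DCVResult]]:
    """All model families on all datasets under one shared fold plan.

    Returns a comparison table (rows = models, columns = dataset x
    train/test mean +- SD) and the full per-fold results.
    """
    y = np.asarray(y, dtype=int).ravel()
    n = next(iter(datasets.values())).n_samples
    plan = make_dcv_folds(n, k, seed=seed, y=y)
    results = []
    for model in models:
        for tag, em in datasets.items():
            grid = (inner_grids or {}).get(model)
            results.append(run_dcv(model, em, y, plan, inner_grid=grid, seed=seed))
    rows = []
    for model in models:
        row = {"model": model}
        for tag in datasets:
            s = next(r for r in results if r.model == model and r.dataset_tag == tag).summary()
            row[f"{tag}_train"] = f"{s['train_auc_mean']:.3f} ± {s['train_auc_sd']:.3f}"
            row[f"{tag}_test"] = f"{s['test_auc_mean']:.3f} ± {s['test_auc_sd']:.3f}"
        rows.append(row)
    return pd.DataFrame(rows), results
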