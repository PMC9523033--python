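"""Exhaustive two-feature model search.

Two model families probe whether biomarker *combinations* beat single
markers:

* PWL -- a two-dimensional classifier over a pair of continuous features
  whose decision boundary is built from 2-4 hinge ("boundary line")
  units: ``sigmoid(v0 + sum_k v_k * relu(a_k x1 + b_k x2 + c_k))``.
  Missing-flag (and other discrete) columns are ineligible.
* HCLR -- handcrafted-arithmetic logistic regression: from every
  unordered feature pair {A, B} five derived columns are formed
  (A+B, A-B, A*B, A/B, B/A; A-B and B-A are collinear so only one
  survives, while the two quotients are genuinely different), and every
  unordered pair of pool members feeds a 2-input logistic regression.
  Flags participate here.

Every candidate model is evaluated exactly once, in-sample, and the
search streams per-feature aggregates (model counts, mean AUC, high-AUC
"single frequency") plus the fully materialised results for models whose
AUC clears the high-AUC threshold (0.8 PWL / 0.9 HCLR by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .encoding import EncodedMatrix
from .errors import DegenerateFeatureError, DomainError

logger = logging.getLogger(__name__)

PWL_HIGH_AUC = 0.8
HCLR_HIGH_AUC = 0.9
PWL_ELIGIBLE_KINDS = ("continuous", "ordinal")

# denominator clamp and winsor quantiles for quotient features over
# z-scored (zero-crossing) inputs
DIV_CLAMP = 1e-3
WINSOR_Q = (0.5, 99.5)

_PAIR_OPS = ("sum", "diff", "prod", "div_ab", "div_ba")
_OP_SYMBOL = {"sum": "+", "diff": "-", "prod": "*", "div_ab": "/", "div_ba": "\\"}


@dataclass(frozen=True)
class HandcraftedFeature:
    """One pool member: a raw feature or an arithmetic combination.

    For the symmetric ops (sum, diff, prod) the parent pair is stored
    sorted -- the sign of a difference is absorbed by the downstream
    logistic coefficient.  ``div_ab`` is parents[0]/parents[1] and
    ``div_ba`` the reverse, and the two are distinct pool members.
    """

    op: str
    parents: tuple[str, ...]

    def __post_init__(self):
        if self.op == "raw":
            if len(self.parents) != 1:
                raise DomainError("raw handcrafted feature needs exactly 1 parent")
        elif self.op in _PAIR_OPS:
            if len(self.parents) != 2:
                raise DomainError(f"{self.op} handcrafted feature needs exactly 2 parents")
        else:
            raise DomainError(f"unknown handcrafted op {self.op!r}")

    @property
    def label(self) -> str:
        if self.op == "raw":
            return self.parents[0]
        a, b = self.parents
        if self.op == "div_ba":
            return f"({b}/{a})"
        return f"({a}{_OP_SYMBOL[self.op]}{b})"


@dataclass
class PairModelResult:
    kind: str  # "PWL" | "HCLR"
    inputs: tuple  # feature names (PWL) or HandcraftedFeature pair (HCLR)
    auc: float
    params: dict
    involved: tuple[str, ...]  # deduplicated raw feature names


def enumerate_pool(features: Sequence[str], include_raw: bool = True) -> list[HandcraftedFeature]:
    """All handcrafted pool members over ``features``.

    Five combinations per unordered pair plus (optionally) the raw
    features; pool size = n*[include_raw] + 5*C(n, 2).
    """
    names = list(features)
    if len(names) < 2:
        raise DomainError("need >= 2 features to build a handcrafted pool")
    pool: list[HandcraftedFeature] = []
    if include_raw:
        pool.extend(HandcraftedFeature("raw", (f,)) for f in names)
    for a, b in combinations(names, 2):
        key = tuple(sorted((a, b)))
        pool.append(HandcraftedFeature("sum", key))
        pool.append(HandcraftedFeature("diff", key))
        pool.append(HandcraftedFeature("prod", key))
        pool.append(HandcraftedFeature("div_ab", (a, b)))
        pool.append(HandcraftedFeature("div_ba", (a, b)))
    return pool


def pool_size(n: int, include_raw: bool = True) -> int:
    if n < 2:
        raise DomainError("need >= 2 features")
    return (n if include_raw else 0) + 5 * math.comb(n, 2)


def count_models(n: int, include_raw: bool = True) -> int:
    """Total number of candidate HCLR models: C(pool_size, 2)."""
    return math.comb(pool_size(n, include_raw), 2)


def _clamp_denominator(d: np.ndarray) -> np.ndarray:
    sign = np.where(d >= 0, 1.0, -1.0)
    return sign * np.maximum(np.abs(d), DIV_CLAMP)


def _winsorize(col: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(col, WINSOR_Q)
    return np.clip(col, lo, hi)


def handcrafted_values(feat: HandcraftedFeature, columns: dict[str, np.ndarray]) -> np.ndarray:
    """Materialise one pool member; quotients are clamp-guarded and
    winsorised against blow-ups near zero-crossing denominators."""
    if feat.op == "raw":
        return columns[feat.parents[0]].copy()
    a, b = (columns[p] for p in feat.parents)
    if feat.op == "sum":
        return a + b
    if feat.op == "diff":
        return a - b
    if feat.op == "prod":
        return a * b
    if feat.op == "div_ab":
        return _winsorize(a / _clamp_denominator(b))
    return _winsorize(b / _clamp_denominator(a))


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC = P(score_pos > score_neg), ties counting one half."""
    from scipy.stats import rankdata

    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise DomainError("both classes must be non-empty")
    r = rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# HCLR: two-input logistic regression by damped Newton (IRLS)


def _newton_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8,
                     max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Deterministic logistic fit (columns of X, intercept appended last).

    A vanishing ridge keeps the Hessian invertible under separation; the
    Newton step is halved until the penalised deviance decreases.
    """
    n, d = X.shape
    Z = np.column_stack([X, np.ones(n)])
    beta = np.zeros(d + 1)

    def nll(b):
        z = Z @ b
        return float(np.sum(np.logaddexp(0.0, z) - y * z) + 0.5 * ridge * b @ b)

    from scipy.special import expit

    cur = nll(beta)
    for _ in range(max_iter):
        p = expit(Z @ beta)
        g = Z.T @ (p - y) + ridge * beta
        if np.max(np.abs(g)) < tol:
            break
        W = np.maximum(p * (1 - p), 1e-12)
        H = (Z * W[:, None]).T @ Z + ridge * np.eye(d + 1)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(12):
            new = nll(beta - t * step)
            if new <= cur + 1e-15:
                break
            t *= 0.5
        beta = beta - t * step
        if abs(cur - new) < tol * (1 + abs(cur)):
            cur = new
            break
        cur = new
    return beta


def fit_hclr_model(f1: np.ndarray, f2: np.ndarray, y: np.ndarray,
                   inputs: tuple | None = None) -> PairModelResult:
    """2-input logistic regression with intercept; in-sample AUC."""
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise DomainError("both classes must be present")
    for k, col in (("f1", f1), ("f2", f2)):
        if np.unique(col).size < 2:
            raise DegenerateFeatureError(f"{k} is constant")
    X = np.column_stack([f1, f2])
    beta = _newton_logistic(X, y)
    scores = X @ beta[:2] + beta[2]
    auc = rank_auc(scores, y.astype(bool))
    if inputs is None:
        inputs = ("f1", "f2")
    involved = _involved(inputs)
    return PairModelResult("HCLR", tuple(inputs), auc,
                           {"coef": beta[:2].tolist(), "intercept": float(beta[2])}, involved)


def _involved(inputs: tuple) -> tuple[str, ...]:
    feats: set[str] = set()
    for item in inputs:
        if isinstance(item, HandcraftedFeature):
            feats.update(item.parents)
        else:
            feats.add(str(item))
    return tuple(sorted(feats))


# ---------------------------------------------------------------------------
# PWL pair models: hinge-sum boundary, manual gradients


@dataclass
class PWLPairConfig:
    epochs: int = 300
    learning_rate: float = 0.08
    restarts: int = 3
    class_weight: str | None = "balanced"
    n_lines: tuple[int, ...] = (2, 3, 4)


def _fit_pwl_once(X2: np.ndarray, y: np.ndarray, sw: np.ndarray, K: int,
                  rng: np.random.Generator, cfg: PWLPairConfig):
    n = X2.shape[0]
    A = rng.normal(0.0, 1.0, size=(K, 2))
    c = rng.normal(0.0, 0.5, size=K)
    v = rng.normal(0.0, 0.5, size=K)
    v0 = 0.0
    m = [np.zeros_like(p) for p in (A, c, v)]
    vel = [np.zeros_like(p) for p in (A, c, v)]
    m0 = v0m = 0.0
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate
    for t in range(1, cfg.epochs + 1):
        z = X2 @ A.T + c  # n x K
        r = np.maximum(z, 0.0)
        logit = r @ v + v0
        p = 0.5 * (1.0 + np.tanh(0.5 * logit))
        dl = sw * (p - y) / n
        dv = r.T @ dl
        dv0 = dl.sum()
        dz = (dl[:, None] * v[None, :]) * (z > 0)
        dA = dz.T @ X2
        dc = dz.sum(axis=0)
        grads = [dA, dc, dv]
        params = [A, c, v]
        for i in range(3):
            m[i] = b1 * m[i] + (1 - b1) * grads[i]
            vel[i] = b2 * vel[i] + (1 - b2) * grads[i] ** 2
            params[i] -= lr * (m[i] / (1 - b1**t)) / (np.sqrt(vel[i] / (1 - b2**t)) + eps)
        m0 = b1 * m0 + (1 - b1) * dv0
        v0m = b2 * v0m + (1 - b2) * dv0**2
        v0 -= lr * (m0 / (1 - b1**t)) / (np.sqrt(v0m / (1 - b2**t)) + eps)
    logit = np.maximum(X2 @ A.T + c, 0.0) @ v + v0
    return {"A": A, "c": c, "v": v, "v0": v0}, logit


def fit_pwl_pair(
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    n_lines: int | Sequence[int] = (2, 3, 4),
    seed: int = 0,
    config: PWLPairConfig | None = None,
    kinds: tuple[str, str] | None = None,
    names: tuple[str, str] = ("x1", "x2"),
) -> PairModelResult:
    """Fit the 2-4-boundary-line pair classifier; best K by in-sample AUC.

    ``kinds`` (if given) enforces eligibility: the missing flag and other
    discrete columns cannot be used in a PWL model.
    """
    if kinds is not None:
        bad = [n for n, k in zip(names, kinds) if k not in PWL_ELIGIBLE_KINDS]
        if bad:
            raise DomainError(f"columns {bad} are not PWL-eligible (flag/discrete)")
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise DomainError("both classes must be present")
    cfg = config or PWLPairConfig()
    Ks = [n_lines] if isinstance(n_lines, int) else list(n_lines)
    if any(k < 1 for k in Ks):
        raise DomainError("n_lines must be >= 1")
    X2 = np.column_stack([x1, x2])
    if cfg.class_weight == "balanced":
        pos = y.mean()
        sw = np.where(y == 1, 0.5 / max(pos, 1e-12), 0.5 / max(1 - pos, 1e-12))
    else:
        sw = np.ones(y.shape)
    rng = np.random.default_rng(seed)
    best = None
    for K in Ks:
        for _ in range(cfg.restarts):
            params, logit = _fit_pwl_once(X2, y, sw, K, rng, cfg)
            auc = rank_auc(logit, y.astype(bool))
            if best is None or auc > best[0]:
                best = (auc, K, params)
    auc, K, params = best
    params = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in params.items()}
    params["n_lines"] = K
    return PairModelResult("PWL", tuple(names), auc, params, _involved(tuple(names)))


def pwl_predict_logit(params: dict, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    A = np.asarray(params["A"])
    c = np.asarray(params["c"])
    v = np.asarray(params["v"])
    X2 = np.column_stack([x1, x2])
    return np.maximum(X2 @ A.T + c, 0.0) @ v + params["v0"]


def pwl_eligible(em: EncodedMatrix) -> list[str]:
    """Features usable in a PWL model: continuous/ordinal, never flags."""
    return [n for n, k in zip(em.feature_names, em.feature_kinds) if k in PWL_ELIGIBLE_KINDS]


# ---------------------------------------------------------------------------
# streaming search


@dataclass
class _FeatureAgg:
    model_count: int = 0
    auc_sum: float = 0.0
    aucs: list = field(default_factory=list)
    high_count: int = 0  # "single frequency"


@dataclass
class PairSearchAggregate:
    kind: str
    high_auc_threshold: float
    evaluated: int = 0
    skipped: int = 0
    overall_auc_sum: float = 0.0
    per_feature: dict = field(default_factory=dict)  # name -> _FeatureAgg
    retained: list = field(default_factory=list)  # high-AUC PairModelResult
    cooccurrence: dict = field(default_factory=dict)  # (a, b) sorted -> count
    pwl_pair_auc: dict = field(default_factory=dict)  # (a, b) sorted -> auc

    @property
    def overall_mean_auc(self) -> float:
        return self.overall_auc_sum / self.evaluated if self.evaluated else float("nan")

    def _feat(self, name: str) -> _FeatureAgg:
        return self.per_feature.setdefault(name, _FeatureAgg())

    def record(self, result: PairModelResult) -> None:
        self.evaluated += 1
        self.overall_auc_sum += result.auc
        for f in result.involved:
            agg = self._feat(f)
            agg.model_count += 1
            agg.auc_sum += result.auc
            agg.aucs.append(result.auc)
        if self.kind == "PWL":
            self.pwl_pair_auc[tuple(sorted(result.involved))] = result.auc
        if result.auc > self.high_auc_threshold:
            self.retained.append(result)
            for f in result.involved:
                self._feat(f).high_count += 1
            for a, b in combinations(sorted(set(result.involved)), 2):
                self.cooccurrence[(a, b)] = self.cooccurrence.get((a, b), 0) + 1


def run_pair_search(
    X: EncodedMatrix,
    y: np.ndarray,
    kind: str,
    high_auc_threshold: float | None = None,
    include_raw: bool = True,
    model_ceiling: int = 2_000_000,
    seed: int = 0,
    pwl_config: PWLPairConfig | None = None,
) -> PairSearchAggregate:
    """Evaluate every candidate pair model of the given kind once.

    PWL runs over unordered pairs of eligible (continuous) features; HCLR
    over unordered pairs of handcrafted-pool members (all features,
    flags included).  Refuses to start if the candidate count exceeds
    ``model_ceiling``.
    """
    y = np.asarray(y, dtype=int).ravel()
    kind = kind.upper()
    if kind not in ("PWL", "HCLR"):
        raise DomainError("kind must be PWL or HCLR")
    if high_auc_threshold is None:
        high_auc_threshold = PWL_HIGH_AUC if kind == "PWL" else HCLR_HIGH_AUC
    agg = PairSearchAggregate(kind, high_auc_threshold)

    if kind == "PWL":
        names = pwl_eligible(X)
        if len(names) < 2:
            raise DomainError("PWL search needs >= 2 eligible continuous features")
        total = math.comb(len(names), 2)
        if total > model_ceiling:
            raise DomainError(f"{total} PWL models exceed the ceiling of {model_ceiling}")
        cols = {n: X.column(n) for n in names}
        for i, (a, b) in enumerate(combinations(names, 2)):
            res = fit_pwl_pair(cols[a], cols[b], y, seed=seed + i,
                               config=pwl_config, names=(a, b))
            agg.record(res)
        logger.info("PWL search: %d models evaluated", agg.evaluated)
        return agg

    names = list(X.feature_names)
    total = count_models(len(names), include_raw)
    if total > model_ceiling:
        raise DomainError(f"{total} HCLR models exceed the ceiling of {model_ceiling}")
    pool = enumerate_pool(names, include_raw)
    columns = {n: X.column(n) for n in names}
    mats = []
    usable = []
    for feat in pool:
        col = handcrafted_values(feat, columns)
        sd = col.std()
        if sd < 1e-12 or not np.all(np.isfinite(col)):
            usable.append(False)
            mats.append(col)
            continue
        usable.append(True)
        mats.append((col - col.mean()) / sd)  # affine rescale; AUC-invariant
    for i, j in combinations(range(len(pool)), 2):
        if not (usable[i] and usable[j]):
            agg.evaluated += 1
            agg.skipped += 1
            continue
        res = fit_hclr_model(mats[i], mats[j], y, inputs=(pool[i], pool[j]))
        agg.record(res)
    # skipped degenerate models still count as evaluated-once candidates
    logger.info("HCLR search: %d candidates (%d degenerate skipped), %d high-AUC",
                agg.evaluated, agg.skipped, len(agg.retained))
    return agg


def frequency_table(agg: PairSearchAggregate, feature_names: Sequence[str] | None = None):
    """Per-feature single frequency and mean-AUC summary.

    PWL mean = mean AUC over all models containing the feature; HCLR mean
    = mean of the top 10 % of the feature's model AUCs (a good difference
    marker A-B necessarily spawns a bad sibling A+B, which would drag a
    plain mean down).  ``diff_from_overall_mean`` subtracts the mean AUC
    over all evaluated models of that kind.
    """
    import pandas as pd

    names = list(feature_names) if feature_names is not None else sorted(agg.per_feature)
    overall = agg.overall_mean_auc
    rows = []
    for name in names:
        fa = agg.per_feature.get(name, _FeatureAgg())
        if fa.model_count == 0:
            mean = float("nan")
        elif agg.kind == "PWL":
            mean = fa.auc_sum / fa.model_count
        else:
            k = max(1, math.ceil(0.1 * len(fa.aucs)))
            mean = float(np.mean(np.sort(fa.aucs)[-k:]))
        rows.append(
            {
                "feature": name,
                "single_frequency": fa.high_count,
                "mean_auc": mean,
                "diff_from_overall_mean": mean - overall,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["single_frequency", "feature"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def max_f1_threshold(probabilities: np.ndarray, y: np.ndarray) -> float:
    """Probability cut maximising F1, from the observed candidate set.

    Classification rule: p >= threshold is called positive.  Ties on F1
    resolve to the lowest threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=bool)
    if p.size == 0:
        raise DomainError("empty probability vector")
    best_t, best_f1 = None, -1.0
    for t in np.unique(p):
        pred = p >= t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(t), f1
    return best_t
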