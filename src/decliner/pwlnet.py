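"""Explainable point-wise linear classifier.

The model predicts ``sigmoid(sum_j w_j(x) * x_j + b(x))``: a weighted sum
of the input features in which the weights themselves are functions of
the input, produced by a small densely skip-connected ("mesh-like")
neural network.  Because the prediction is exactly linear in the inputs
point-wise, each feature owns a signed contribution
``c_ij = w_j(x_i) * x_ij`` and the logit decomposes exactly as
``logit_i = sum_j c_ij + b_i``.  A zero input (the missing-value
encoding) therefore contributes exactly nothing.

With zero hidden layers the weights cannot depend on x and the model is
plain L2-penalised logistic regression; ``weight_decay`` lambda matches a
logistic regression with C = 1/lambda (biases unpenalised).

Feature selection uses the quantile-based importance score built on the
per-sample weights: feature j is "top-decile" for sample i when its
weight magnitude |w_j(x_i)| reaches the 90th percentile of that sample's
weight magnitudes (the weight value is what the network computes as each
feature's importance; ranking contributions w*x instead would let
constant-magnitude columns such as missing flags crowd the decile purely
through their inputs).  The unsigned score is the mean of the two
class-wise top-decile fractions, so a feature ranked top-decile by half
of one class and never by the other scores exactly 0.25; the sign is the
direction in which the feature's contributions move the predicted
probability.

Implemented in numpy with hand-written gradients and a full-batch Adam
optimiser; training is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import EncodedMatrix
from .errors import DomainError, SchemaError

TOP_DECILE_PERCENTILE = 90.0


@dataclass
class PWLNetConfig:
    """Architecture and optimisation hyperparameters.

    ``hidden_layers`` hidden layers of ``width`` ReLU units; each layer
    sees the raw input concatenated with every previous layer's output,
    and the weight/bias heads read the concatenation of all hidden
    outputs.  ``hidden_layers=0`` collapses the model to logistic
    regression.
    """

    hidden_layers: int = 3
    width: int = 32
    weight_decay: float = 1e-3
    learning_rate: float = 0.01
    max_epochs: int = 500
    patience: int = 20
    validation_fraction: float = 0.2
    class_weight: str | None = "balanced"
    init_scale: float = 0.1


@dataclass
class PointwiseLinearModel:
    config: PWLNetConfig
    params: dict  # W{l}, b{l}, Vw, w0, Vb, b0
    feature_names: list[str]
    seed: int = 0
    train_history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _init_params(d: int, cfg: PWLNetConfig, rng: np.random.Generator) -> dict:
    params: dict[str, np.ndarray] = {}
    in_dim = d
    for layer in range(cfg.hidden_layers):
        scale = cfg.init_scale / np.sqrt(max(in_dim, 1))
        params[f"W{layer}"] = rng.normal(0.0, scale, size=(in_dim, cfg.width))
        params[f"b{layer}"] = np.zeros(cfg.width)
        in_dim += cfg.width
    stack = cfg.hidden_layers * cfg.width
    params["Vw"] = rng.normal(0.0, cfg.init_scale / np.sqrt(max(stack, 1)), size=(stack, d))
    params["w0"] = np.zeros(d)
    params["Vb"] = rng.normal(0.0, cfg.init_scale / np.sqrt(max(stack, 1)), size=(stack, 1))
    params["b0"] = np.zeros(1)
    return params


def _forward(params: dict, cfg: PWLNetConfig, X: np.ndarray):
    """Returns (weights n x d, bias n, logit n, cache for backprop)."""
    inp = X
    pre, hidden = [], []
    for layer in range(cfg.hidden_layers):
        a = inp @ params[f"W{layer}"] + params[f"b{layer}"]
        h = np.maximum(a, 0.0)
        pre.append(a)
        hidden.append(h)
        inp = np.concatenate([inp, h], axis=1)
    stack = np.concatenate(hidden, axis=1) if hidden else np.zeros((X.shape[0], 0))
    w = stack @ params["Vw"] + params["w0"]
    bvec = (stack @ params["Vb"]).ravel() + params["b0"][0]
    logit = np.sum(w * X, axis=1) + bvec
    return w, bvec, logit, (pre, hidden, stack)


def _loss_and_grads(params, cfg, X, y, sample_w):
    n, d = X.shape
    w, bvec, logit, (pre, hidden, stack) = _forward(params, cfg, X)
    p = _sigmoid(logit)
    eps = 1e-12
    ce = -np.mean(sample_w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    reg = 0.0
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dlogit = sample_w * (p - y) / n
    dw = dlogit[:, None] * X
    dstack = dw @ params["Vw"].T + dlogit[:, None] @ params["Vb"].T
    grads["Vw"] = stack.T @ dw
    grads["w0"] = dw.sum(axis=0)
    grads["Vb"] = stack.T @ dlogit[:, None]
    grads["b0"] = np.array([dlogit.sum()])

    # backprop through the dense-skip hidden layers
    H = cfg.width
    dh = [dstack[:, l * H : (l + 1) * H].copy() for l in range(cfg.hidden_layers)]
    for layer in range(cfg.hidden_layers - 1, -1, -1):
        da = dh[layer] * (pre[layer] > 0)
        inp = np.concatenate([X] + hidden[:layer], axis=1) if layer else X
        grads[f"W{layer}"] = inp.T @ da
        grads[f"b{layer}"] = da.sum(axis=0)
        dinp = da @ params[f"W{layer}"].T
        for prev in range(layer):
            dh[prev] += dinp[:, d + prev * H : d + (prev + 1) * H]

    lam = cfg.weight_decay / n
    for k in params:
        if k.startswith(("W", "V")) or k == "w0":  # weights penalised, biases not
            reg += 0.5 * lam * float(np.sum(params[k] ** 2))
            grads[k] = grads[k] + lam * params[k]
    return ce + reg, grads


def fit_pwl_net(
    X: EncodedMatrix | np.ndarray,
    y: np.ndarray,
    hyper: PWLNetConfig | None = None,
    seed: int = 0,
) -> PointwiseLinearModel:
    """Train by full-batch Adam on weighted cross-entropy with weight decay
    and early stopping on an internal held-out slice of the training data."""
    cfg = hyper or PWLNetConfig()
    if isinstance(X, EncodedMatrix):
        values, names = X.values, list(X.feature_names)
    else:
        values = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(values.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise DomainError("design matrix contains non-finite entries")
    if np.unique(y).size < 2:
        raise DomainError("both outcome classes must be present")

    n, d = values.shape
    rng = np.random.default_rng(seed)
    params = _init_params(d, cfg, rng)

    if cfg.class_weight == "balanced":
        pos = y.mean()
        sw = np.where(y == 1, 0.5 / max(pos, 1e-12), 0.5 / max(1 - pos, 1e-12))
    else:
        sw = np.ones(n)

    # internal early-stopping split (training data only)
    val_idx = np.array([], dtype=int)
    if cfg.validation_fraction > 0:
        n_val = int(round(cfg.validation_fraction * n))
        perm = rng.permutation(n)
        cand = perm[:n_val]
        rest = perm[n_val:]
        if n_val >= 2 and np.unique(y[rest]).size == 2:
            val_idx = cand
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    Xt, yt, swt = values[train_idx], y[train_idx], sw[train_idx]

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_val, best_params, patience_left = np.inf, None, cfg.patience
    history = {"loss": [], "val_loss": []}

    for t in range(1, cfg.max_epochs + 1):
        loss, grads = _loss_and_grads(params, cfg, Xt, yt, swt)
        history["loss"].append(float(loss))
        for k in params:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
            mhat = m[k] / (1 - beta1**t)
            vhat = v2[k] / (1 - beta2**t)
            params[k] = params[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if val_idx.size:
            # early stopping watches the unpenalised CE: the decay term
            # depends only on the weights and would mask val improvement
            _, _, vlogit, _ = _forward(params, cfg, values[val_idx])
            pv = _sigmoid(vlogit)
            yv, swv = y[val_idx], sw[val_idx]
            vloss = -np.mean(
                swv * (yv * np.log(pv + 1e-12) + (1 - yv) * np.log(1 - pv + 1e-12))
            )
            history["val_loss"].append(float(vloss))
            if vloss < best_val - 1e-7:
                best_val, best_params = vloss, {k: p.copy() for k, p in params.items()}
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:
        params = best_params
    return PointwiseLinearModel(cfg, params, names, seed=seed, train_history=history)


def _check_binding(model: PointwiseLinearModel, X) -> np.ndarray:
    if isinstance(X, EncodedMatrix):
        if list(X.feature_names) != model.feature_names:
            raise SchemaError("feature binding mismatch between model and matrix")
        return X.values
    values = np.asarray(X, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != model.n_features:
        raise SchemaError(
            f"expected {model.n_features} columns, got {values.shape[1]}"
        )
    return values


def predict_logit(model: PointwiseLinearModel, X) -> np.ndarray:
    values = _check_binding(model, X)
    _, _, logit, _ = _forward(model.params, model.config, values)
    return logit


def predict_proba(model: PointwiseLinearModel, X) -> np.ndarray:
    """Rapid-decliner probability per sample."""
    return _sigmoid(predict_logit(model, X))


def pointwise_weights(model: PointwiseLinearModel, X) -> tuple[np.ndarray, np.ndarray]:
    values = _check_binding(model, X)
    w, bvec, _, _ = _forward(model.params, model.config, values)
    return w, bvec


def contributions(model: PointwiseLinearModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-feature signed contributions c_ij = w_j(x_i) * x_ij.

    Returns (c, bias); rows of c plus bias reconstruct the logit exactly.
    """
    values = _check_binding(model, X)
    w, bvec, _, _ = _forward(model.params, model.config, values)
    return w * values, bvec


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # feature, score, unsigned, f_rapid, f_non, sign_rapid, sign_non

    def scores(self) -> pd.Series:
        return self.table.set_index("feature")["score"]


def importance_from_contributions(
    c: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    sign_source: np.ndarray | None = None,
) -> ImportanceReport:
    """Quantile-based signed importance from a per-sample importance matrix.

    Per sample, a feature is top-decile when its magnitude |c_ij| reaches
    the sample's 90th percentile; f_c(j) is the fraction of class-c
    samples ranking j top-decile; unsigned score = (f_rapid + f_non) / 2.
    The sign comes from the column means of ``sign_source`` (defaults to
    ``c`` itself); model-level scoring passes the signed contributions
    there so the sign reflects the direction of the effect on the output.
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=bool).ravel()
    if y.sum() == 0 or (~y).sum() == 0:
        raise DomainError("both outcome classes must be present")
    names = feature_names or [f"x{j}" for j in range(c.shape[1])]
    s = c if sign_source is None else np.asarray(sign_source, dtype=float)
    abs_c = np.abs(c)
    thresh = np.percentile(abs_c, TOP_DECILE_PERCENTILE, axis=1, keepdims=True)
    top = abs_c >= thresh  # ties at the percentile count as top-decile
    f_rapid = top[y].mean(axis=0)
    f_non = top[~y].mean(axis=0)
    unsigned = (f_rapid + f_non) / 2.0
    sign = np.sign(s.mean(axis=0))
    sign[sign == 0] = 1.0
    table = pd.DataFrame(
        {
            "feature": names,
            "score": sign * unsigned,
            "unsigned": unsigned,
            "f_rapid": f_rapid,
            "f_non": f_non,
            "sign_rapid": np.sign(s[y].mean(axis=0)),
            "sign_non": np.sign(s[~y].mean(axis=0)),
        }
    )
    table = table.reindex(table["score"].abs().sort_values(ascending=False).index)
    return ImportanceReport(table.reset_index(drop=True))


def importance_scores(model: PointwiseLinearModel, X, y: np.ndarray) -> ImportanceReport:
    """Importance report for a fitted model over a dataset.

    The decile ranking uses the per-sample weight magnitudes |w_j(x_i)|;
    the sign of each score is the direction of the feature's mean signed
    contribution to the logit.
    """
    w, _ = pointwise_weights(model, X)
    c, _ = contributions(model, X)
    return importance_from_contributions(w, y, model.feature_names, sign_source=c)


def select_features(
    report: ImportanceReport,
    auto_threshold: float = 0.25,
    curated: list[str] | None = None,
    curated_threshold: float = 0.06,
    cap: int = 50,
) -> pd.DataFrame:
    """Biomarker-candidate selection from the importance report.

    Auto picks are features with |score| > ``auto_threshold``; curated
    names additionally qualify when |score| > ``curated_threshold``.  The
    union is ranked by |score| and truncated to ``cap``; the returned
    table records the origin of each pick.
    """
    curated = curated or []
    tab = report.table
    known = set(tab["feature"])
    unknown = [c for c in curated if c not in known]
    if unknown:
        raise SchemaError(f"curated names not in report: {unknown}")
    out = []
    for _, row in tab.iterrows():
        a = abs(row["score"])
        if a > auto_threshold:
            out.append({"feature": row["feature"], "score": row["score"], "origin": "auto"})
        elif row["feature"] in curated and a > curated_threshold:
            out.append({"feature": row["feature"], "score": row["score"], "origin": "curated"})
    df = pd.DataFrame(out, columns=["feature", "score", "origin"])
    df = df.reindex(df["score"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return df.head(cap)


def save_model(model: PointwiseLinearModel, path: str | Path) -> None:
    """Single-file serialization: architecture + parameters + binding."""
    path = Path(path)
    doc = {
        "config": asdict(model.config),
        "feature_names": model.feature_names,
        "seed": model.seed,
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    path.write_text(json.dumps(doc))


def load_model(path: str | Path) -> PointwiseLinearModel:
    doc = json.loads(Path(path).read_text())
    return PointwiseLinearModel(
        config=PWLNetConfig(**doc["config"]),
        params={k: np.asarray(v, dtype=float) for k, v in doc["params"].items()},
        feature_names=doc["feature_names"],
        seed=doc["seed"],
    )
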