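"""Conventional per-metabolite screening.

Half-minimum imputation for undetected cells, a detection-frequency
filter (a marker useful in the clinic must actually be measurable in most
patients), Mann-Whitney U comparison of rapid vs non-rapid decliners with
Benjamini-Hochberg q-values, and the single-marker ROC AUC via the
rank-sum identity AUC = U / (n1 * n2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable, Missing
from .errors import CannotImputeError, DomainError

# exact null enumeration is feasible and tie-free below this class size
_EXACT_MAX = 7


@dataclass
class ScreenResult:
    feature: str
    detection_fraction: float
    p_value: float
    q_value: float
    auc: float
    direction: int  # sign of (median rapid - median non-rapid)


def half_min_impute(column: np.ndarray) -> np.ndarray:
    """Replace missing cells (either type) with half the detected minimum."""
    col = np.asarray(column, dtype=float)
    detected = col[~np.isnan(col)]
    if detected.size == 0:
        raise CannotImputeError("no detected values to impute from")
    out = col.copy()
    out[np.isnan(out)] = detected.min() / 2.0
    return out


def detection_filter(matrix: pd.DataFrame, min_fraction: float = 0.5) -> list[str]:
    """Features detected in at least ``min_fraction`` of all samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise DomainError("min_fraction must lie in (0, 1]")
    frac = 1.0 - matrix.isna().mean(axis=0)
    return [c for c in matrix.columns if frac[c] >= min_fraction]


def _mw_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for small tie-free
    samples, normal approximation with tie and continuity correction
    otherwise."""
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= _EXACT_MAX and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def single_marker_auc(column: np.ndarray, rapid: np.ndarray) -> float:
    """Rank AUC of one column, oriented so auc >= 0.5.

    Equals P(random rapid sample ranks above random non-rapid sample),
    ties counting one half, computed via the U identity.
    """
    col = np.asarray(column, dtype=float)
    y = np.asarray(rapid, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise DomainError("both classes must be non-empty")
    ranks = stats.rankdata(col)
    u1 = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n0)
    return float(max(auc, 1.0 - auc))


def mann_whitney_bh(
    matrix: pd.DataFrame, rapid: np.ndarray, impute: bool = True
) -> list[ScreenResult]:
    """Screen every column: MW p, BH q over the tested set, oriented AUC.

    ``matrix`` holds raw metabolite columns (NaN = missing, either type).
    With ``impute=True`` (default) columns are half-minimum imputed before
    testing; otherwise the test uses detected cells only.
    """
    y = np.asarray(rapid, dtype=bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise DomainError("both classes must be non-empty")
    results = []
    pvals = []
    for c in matrix.columns:
        raw = matrix[c].to_numpy(dtype=float)
        det_frac = float(np.mean(~np.isnan(raw)))
        col = half_min_impute(raw) if impute else raw
        if impute:
            a, b = col[y], col[~y]
        else:
            a, b = raw[y], raw[~y]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            continue
        p = _mw_pvalue(a, b)
        auc = single_marker_auc(col if impute else np.nan_to_num(raw, nan=-np.inf), y)
        direction = int(np.sign(np.median(a) - np.median(b))) or 0
        results.append(ScreenResult(c, det_frac, p, np.nan, auc, direction))
        pvals.append(p)
    if results:
        q = multipletests(pvals, method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def run_screen(
    cohort: CohortTable,
    rapid: np.ndarray,
    min_fraction: float = 0.5,
    impute: bool = True,
) -> pd.DataFrame:
    """Full conventional analysis over all metabolite matrices.

    Detection-filters each matrix, imputes, tests, and returns a table
    (feature, detection_fraction, p, q, auc, direction) sorted by auc
    descending.  Feature names carry the P-/U- matrix prefix.  The BH
    correction runs once over the union of retained features.
    """
    from .encoding import matrix_prefix

    frames = []
    for m, table in cohort.metabolites.items():
        kept = detection_filter(table, min_fraction)
        sub = table[kept].copy()
        sub.columns = [f"{matrix_prefix(m)}-{c}" for c in kept]
        frames.append(sub)
    merged = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=range(cohort.n_samples))
    res = mann_whitney_bh(merged, rapid, impute=impute)
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in res],
            "detection_fraction": [r.detection_fraction for r in res],
            "p": [r.p_value for r in res],
            "q": [r.q_value for r in res],
            "auc": [r.auc for r in res],
            "direction": [r.direction for r in res],
        }
    )
    return df.sort_values("auc", ascending=False).reset_index(drop=True)
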