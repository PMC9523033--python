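"""Outcome derivation from eGFR trajectories.

The outcome of interest is the annual eGFR change rate expressed as a
percentage of the baseline eGFR per year.  The rate is the ordinary
least-squares slope of eGFR against visit month (eGFR units per month),
annualised (x12) and normalised by the baseline value (x100/baseline).
Patients are binned into four decline groups; group 4 -- an annual change
below -10 % of baseline -- defines the rapid decliner, the binary
prediction target of every downstream model.

Boundary convention (the interval wording is ambiguous in prose): the
rapid cut is strict (rate < -10) and each interval is closed on its right
edge, so -10 itself falls in group 3, -3.3 in group 2 and 0 in group 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

RAPID_CUT = -10.0  # %/yr, strict
MODERATE_CUT = -3.3  # %/yr
STABLE_CUT = 0.0  # %/yr


@dataclass(frozen=True)
class OutcomeLabels:
    sample_id: str
    annual_rate: float  # % of baseline eGFR per year
    group: int  # 1..4
    rapid: bool


def fit_annual_rate(series: Sequence[tuple[float, float]], baseline: float) -> float:
    """OLS slope of an eGFR series, as % of baseline per year.

    ``series`` is a list of (month, eGFR) pairs; ``baseline`` is the
    measured eGFR at the baseline visit (month 0), not the fitted
    intercept.
    """
    if baseline <= 0:
        raise DomainError(f"baseline eGFR must be positive, got {baseline}")
    months = np.asarray([m for m, _ in series], dtype=float)
    values = np.asarray([v for _, v in series], dtype=float)
    if len(months) < 2 or np.unique(months).size < 2:
        raise InsufficientDataError("need >= 2 distinct time points to fit a rate")
    slope = np.polyfit(months, values, 1)[0]  # eGFR units per month
    return float(slope * 12.0 / baseline * 100.0)


def classify(annual_rate: float) -> tuple[int, bool]:
    """Map an annual rate (%/yr) to its decline group and rapid flag.

    Group 4 (rapid): rate < -10; group 3: -10 <= rate < -3.3;
    group 2: -3.3 <= rate < 0; group 1: rate >= 0.
    """
    if not math.isfinite(annual_rate):
        raise DomainError(f"annual rate must be finite, got {annual_rate}")
    if annual_rate < RAPID_CUT:
        return 4, True
    if annual_rate < MODERATE_CUT:
        return 3, False
    if annual_rate < STABLE_CUT:
        return 2, False
    return 1, False


def window_rates(series: Sequence[tuple[float, float]], baseline: float) -> list[float]:
    """Diagnostic: the rate refit on each prefix window of >= 2 visits."""
    pts = sorted(series)
    return [fit_annual_rate(pts[: k + 1], baseline) for k in range(1, len(pts))]


def derive_outcomes(egfr: pd.DataFrame) -> pd.DataFrame:
    """Label every sample in a long-format eGFR table.

    ``egfr`` has columns sample_id, month, egfr; baseline is the value at
    the earliest visit.  Returns a table (sample_id, annual_rate, group,
    rapid) in first-appearance order of the samples.
    """
    out = []
    for sid, grp in egfr.groupby("sample_id", sort=False):
        grp = grp.sort_values("month")
        baseline = float(grp["egfr"].iloc[0])
        rate = fit_annual_rate(list(zip(grp["month"], grp["egfr"])), baseline)
        group, rapid = classify(rate)
        out.append({"sample_id": sid, "annual_rate": rate, "group": group, "rapid": rapid})
    return pd.DataFrame(out)


def rapid_labels(outcomes: pd.DataFrame, sample_ids: Iterable[str]) -> np.ndarray:
    """Rapid flags as a 0/1 vector aligned to ``sample_ids``."""
    lookup = dict(zip(outcomes["sample_id"], outcomes["rapid"]))
    return np.asarray([int(lookup[s]) for s in sample_ids])
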