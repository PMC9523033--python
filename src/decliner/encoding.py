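"""Numeric design-matrix construction with three-state missing flags.

Encoding rules:

* binary variables -> one column in {+1, -1}, missing -> 0 (levels are
  assigned +1/-1 by lexicographic label order so the map is reproducible);
* multi-categorical variables of K categories -> K one-hot-style columns,
  member category +1, the others -1, missing row -> 0 in all K columns;
* continuous variables -> z-score over the observed entries (population
  SD), missing -> 0 after normalisation;
* ordinal variables -> integer rank in the declared order, then z-scored
  like a continuous variable;
* every metabolite additionally receives a three-state missing flag
  column: +1 below-sensitivity (type-1), 0 unmeasured (type-2), -1
  observed.

Missing cells therefore always encode to exactly 0, so they contribute
nothing to any weighted sum a downstream model computes -- the point of
the whole scheme.  Standardisation statistics can be refit on a subset of
rows (a training fold) through :meth:`EncodedMatrix.values_for_rows`,
which is how the cross-validation harness stays leakage-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, Missing, VariableSchema
from .errors import DegenerateFeatureError, SchemaError

logger = logging.getLogger(__name__)

DATASET_TAGS = ("metabolomic", "clinical", "combined")
SCALED_KINDS = ("continuous", "ordinal")


@dataclass
class EncodedColumn:
    values: np.ndarray  # fully encoded
    missing_mask: np.ndarray  # True where the cell was missing
    raw: np.ndarray | None = None  # pre-standardisation numeric values (NaN at missing)
    meta: dict = field(default_factory=dict)


def _missing_mask(values: Sequence) -> np.ndarray:
    return pd.isna(np.asarray(values, dtype=object))


def encode_binary(values: Sequence) -> EncodedColumn:
    """Encode a two-level variable to {+1, -1}, missing to 0."""
    miss = _missing_mask(values)
    arr = np.asarray(values, dtype=object)
    levels = sorted({str(v) for v in arr[~miss]})
    if len(levels) > 2:
        raise SchemaError(f"binary variable has {len(levels)} observed levels: {levels}")
    level_map = {lev: (+1.0 if i == 0 else -1.0) for i, lev in enumerate(levels)}
    out = np.zeros(len(arr))
    for i in np.flatnonzero(~miss):
        out[i] = level_map[str(arr[i])]
    return EncodedColumn(out, miss, meta={"level_map": level_map})


def decode_binary(column: EncodedColumn) -> list:
    """Invert :func:`encode_binary` for non-missing cells (missing -> None)."""
    inverse = {v: k for k, v in column.meta["level_map"].items()}
    return [None if m else inverse[v] for v, m in zip(column.values, column.missing_mask)]


def encode_multicategorical(values: Sequence, categories: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """K columns: member category +1, others -1; missing row -> all-zero.

    Returns (n x K matrix, missing mask).
    """
    miss = _missing_mask(values)
    arr = np.asarray(values, dtype=object)
    cats = list(categories)
    unseen = {str(v) for v in arr[~miss]} - set(cats)
    if unseen:
        raise SchemaError(f"levels {sorted(unseen)} not in declared categories {cats}")
    out = np.zeros((len(arr), len(cats)))
    for i in np.flatnonzero(~miss):
        out[i, :] = -1.0
        out[i, cats.index(str(arr[i]))] = +1.0
    return out, miss


def _zscore_observed(raw: np.ndarray, miss: np.ndarray, name: str = "") -> np.ndarray:
    obs = raw[~miss]
    if obs.size == 0 or np.unique(obs).size < 2:
        raise DegenerateFeatureError(f"feature {name!r} has no usable variation")
    mean = obs.mean()
    sd = obs.std()  # population SD (ddof=0)
    out = np.zeros(raw.shape)
    out[~miss] = (raw[~miss] - mean) / sd
    return out


def encode_continuous(values: Sequence) -> EncodedColumn:
    """Z-score over observed entries only (population SD); missing -> 0."""
    miss = _missing_mask(values)
    raw = np.full(len(values), np.nan)
    idx = np.flatnonzero(~miss)
    raw[idx] = np.asarray([float(np.asarray(values, dtype=object)[i]) for i in idx])
    out = _zscore_observed(np.nan_to_num(raw, nan=0.0), miss)
    return EncodedColumn(out, miss, raw=raw)


def encode_ordinal(values: Sequence, ordinal_order: Sequence[str]) -> EncodedColumn:
    """Rank each level by its position in ``ordinal_order``, then z-score."""
    miss = _missing_mask(values)
    arr = np.asarray(values, dtype=object)
    order = [str(x) for x in ordinal_order]
    unseen = {str(v) for v in arr[~miss]} - set(order)
    if unseen:
        raise SchemaError(f"levels {sorted(unseen)} not in ordinal order {order}")
    raw = np.full(len(arr), np.nan)
    for i in np.flatnonzero(~miss):
        raw[i] = float(order.index(str(arr[i])))
    out = _zscore_observed(np.nan_to_num(raw, nan=0.0), miss)
    return EncodedColumn(out, miss, raw=raw)


def make_missing_flag(codes: Sequence[int]) -> np.ndarray:
    """Three-state flag: type-1 -> +1, type-2 -> 0, present -> -1."""
    arr = np.asarray(codes, dtype=int)
    out = np.full(arr.shape, -1.0)
    out[arr == int(Missing.TYPE1)] = 1.0
    out[arr == int(Missing.TYPE2)] = 0.0
    return out


@dataclass
class EncodedMatrix:
    """Fully numeric design matrix plus per-column provenance.

    ``raw`` keeps the pre-standardisation numbers for the scaled column
    kinds (continuous/ordinal) so fold-local statistics can be refit.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]  # binary | onehot | ordinal | continuous | flag
    source_variables: list[str]
    dataset_tag: str
    missing_mask: np.ndarray
    raw: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def values_for_rows(self, train_idx: np.ndarray | None = None) -> np.ndarray:
        """Encoded values with scaling statistics refit on ``train_idx`` rows.

        Scaled kinds are re-z-scored using only the observed entries of the
        given rows; a column constant within those rows is zero-filled.
        With ``train_idx=None`` this reproduces ``values``.
        """
        if train_idx is None:
            return self.values.copy()
        out = self.values.copy()
        for j, kind in enumerate(self.feature_kinds):
            if kind not in SCALED_KINDS:
                continue
            raw = self.raw[:, j]
            obs = raw[train_idx]
            obs = obs[~np.isnan(obs)]
            col = np.zeros(raw.shape)
            if obs.size >= 2 and np.unique(obs).size >= 2:
                z = (raw - obs.mean()) / obs.std()
                keep = ~np.isnan(raw)
                col[keep] = z[keep]
            out[:, j] = col
        return out

    def select(self, names: Sequence[str]) -> "EncodedMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return EncodedMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            feature_kinds=[self.feature_kinds[i] for i in idx],
            source_variables=[self.source_variables[i] for i in idx],
            dataset_tag=self.dataset_tag,
            missing_mask=self.missing_mask[:, idx],
            raw=self.raw[:, idx],
            sample_ids=list(self.sample_ids),
        )

    def check_invariants(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise AssertionError("non-finite entries in encoded matrix")
        kinds = np.asarray(self.feature_kinds)
        for kind, allowed in (("binary", {-1.0, 0.0, 1.0}), ("flag", {-1.0, 0.0, 1.0})):
            cols = self.values[:, kinds == kind]
            if cols.size and not set(np.unique(cols)) <= allowed:
                raise AssertionError(f"{kind} columns outside {allowed}")


def matrix_prefix(matrix: str) -> str:
    """Display prefix for a metabolite matrix (plasma -> P, urine -> U)."""
    return {"plasma": "P", "urine": "U"}.get(matrix, matrix[:1].upper())


def flag_name(feature: str) -> str:
    return f"Missing flag for {feature}"


def build_design_matrix(
    cohort: CohortTable,
    schema: dict[str, VariableSchema] | None = None,
    dataset_tag: str = "combined",
) -> EncodedMatrix:
    """Assemble the metabolomic / clinical / combined design matrix.

    The metabolomic dataset holds, per metabolite, its z-scored abundance
    column followed by its three-state missing flag; the clinical dataset
    holds the encoded clinical variables (no flags); combined is their
    union.  Degenerate (constant) quantitative columns are dropped with a
    warning; a metabolite's flag column survives even if its value column
    is degenerate.
    """
    if dataset_tag not in DATASET_TAGS:
        raise SchemaError(f"dataset_tag must be one of {DATASET_TAGS}, got {dataset_tag!r}")
    schema = schema if schema is not None else cohort.schema
    declared = set(schema)
    present = set(cohort.clinical.columns) | {
        c for m in cohort.metabolites.values() for c in m.columns
    }
    unmatched = sorted(present ^ declared)
    if unmatched:
        raise SchemaError(f"schema/table mismatch for variables: {unmatched}")

    cols: list[np.ndarray] = []
    raws: list[np.ndarray] = []
    misses: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    sources: list[str] = []
    n = cohort.n_samples

    def push(name: str, kind: str, source: str, col: EncodedColumn | np.ndarray, miss=None):
        if isinstance(col, EncodedColumn):
            values, miss_arr = col.values, col.missing_mask
            raw = col.raw if col.raw is not None else values.copy()
        else:
            values = col
            miss_arr = miss if miss is not None else np.zeros(n, dtype=bool)
            raw = values.copy()
        cols.append(values)
        raws.append(raw)
        misses.append(np.asarray(miss_arr, dtype=bool))
        names.append(name)
        kinds.append(kind)
        sources.append(source)

    if dataset_tag in ("metabolomic", "combined"):
        for matrix, table in cohort.metabolites.items():
            pfx = matrix_prefix(matrix)
            codes = cohort.missing_codes[matrix]
            for var in table.columns:
                display = f"{pfx}-{var}"
                code_col = codes[var].to_numpy()
                miss = code_col != int(Missing.PRESENT)
                raw = table[var].to_numpy(dtype=float)
                try:
                    z = _zscore_observed(np.nan_to_num(raw, nan=0.0), miss, display)
                    push(display, "continuous", display, EncodedColumn(z, miss, raw=raw))
                except DegenerateFeatureError:
                    logger.warning("dropping degenerate metabolite column %s", display)
                push(flag_name(display), "flag", display, make_missing_flag(code_col))
        if not cohort.metabolites:
            logger.warning("no metabolite matrices present; metabolomic block is empty")

    if dataset_tag in ("clinical", "combined"):
        for var in cohort.clinical.columns:
            vs = schema[var]
            series = cohort.clinical[var].tolist()
            try:
                if vs.kind == "binary":
                    push(var, "binary", var, encode_binary(series))
                elif vs.kind == "multicategorical":
                    mat, miss = encode_multicategorical(series, vs.categories)
                    for k, cat in enumerate(vs.categories):
                        push(f"{var}={cat}", "onehot", var, mat[:, k], miss)
                elif vs.kind == "ordinal":
                    push(var, "ordinal", var, encode_ordinal(series, vs.ordinal_order))
                else:  # continuous (incl. quantitative clinical)
                    push(var, "continuous", var, encode_continuous(series))
            except DegenerateFeatureError:
                logger.warning("dropping degenerate clinical column %s", var)

    if not cols:
        values = np.zeros((n, 0))
        return EncodedMatrix(values, [], [], [], dataset_tag, values.astype(bool), values.copy(),
                             list(cohort.sample_ids))
    em = EncodedMatrix(
        values=np.column_stack(cols),
        feature_names=names,
        feature_kinds=kinds,
        source_variables=sources,
        dataset_tag=dataset_tag,
        missing_mask=np.column_stack(misses),
        raw=np.column_stack(raws),
        sample_ids=list(cohort.sample_ids),
    )
    em.check_invariants()
    return em


def write_encoded(em: EncodedMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with a column-metadata sidecar TSV."""
    path = Path(path)
    df = pd.DataFrame(em.values, columns=em.feature_names)
    df.insert(0, "sample_id", em.sample_ids or range(em.n_samples))
    df.to_csv(path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "feature": em.feature_names,
            "kind": em.feature_kinds,
            "source_variable": em.source_variables,
            "dataset_tag": em.dataset_tag,
        }
    )
    meta.to_csv(path.with_suffix(".columns.tsv"), sep="\t", index=False)
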