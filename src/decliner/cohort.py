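"""Cohort container, variable schema, and the on-disk TSV/YAML dialect.

A cohort is one clinical table plus one or more metabolite matrices
(samples x features, relative MS areas), each metabolite cell carrying a
three-way missingness code:

* ``PRESENT`` -- measured value available;
* ``TYPE1``  -- value fell below the assay's sensitivity (written ``<LOD``);
* ``TYPE2``  -- value not measured at all (written as an empty field).

Per-sample eGFR series travel alongside as a long-format table
(sample_id, month, egfr).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError

LOD_SENTINEL = "<LOD"

CLINICAL_MATRIX = "clinical"


class Missing(enum.IntEnum):
    """Cell-level missingness code."""

    PRESENT = 0
    TYPE1 = 1  # below measurement sensitivity
    TYPE2 = 2  # not measured


@dataclass
class VariableSchema:
    """Declared kind and metadata of one cohort variable.

    ``kind`` is one of ``binary``, ``multicategorical``, ``ordinal``,
    ``continuous``, ``metabolite``; ``matrix`` names the table the variable
    lives in (``plasma``, ``urine`` or ``clinical``).
    """

    name: str
    kind: str
    matrix: str = CLINICAL_MATRIX
    categories: list[str] | None = None
    ordinal_order: list[str] | None = None

    KINDS = ("binary", "multicategorical", "ordinal", "continuous", "metabolite")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "multicategorical":
            if not self.categories or len(self.categories) < 2:
                raise SchemaError(f"multicategorical {self.name!r} needs >= 2 categories")
        if self.kind == "ordinal" and not self.ordinal_order:
            raise SchemaError(f"ordinal {self.name!r} needs an ordinal_order")

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "kind": self.kind, "matrix": self.matrix}
        if self.categories is not None:
            d["categories"] = list(self.categories)
        if self.ordinal_order is not None:
            d["ordinal_order"] = list(self.ordinal_order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(
            name=d["name"],
            kind=d["kind"],
            matrix=d.get("matrix", CLINICAL_MATRIX),
            categories=d.get("categories"),
            ordinal_order=d.get("ordinal_order"),
        )


@dataclass
class CohortTable:
    """Raw samples x variables container.

    ``clinical`` holds object-dtype columns (labels for categorical kinds,
    floats for quantitative ones) with ``None``/NaN marking missing cells.
    Each entry of ``metabolites`` maps a matrix name (``plasma``, ``urine``)
    to a float DataFrame (NaN where missing) and ``missing_codes`` to the
    matching integer code frame.  ``egfr`` is the long-format series table.
    """

    sample_ids: list[str]
    clinical: pd.DataFrame
    metabolites: dict[str, pd.DataFrame]
    missing_codes: dict[str, pd.DataFrame]
    schema: dict[str, VariableSchema]
    egfr: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["sample_id", "month", "egfr"]))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def metabolite_names(self, matrix: str | None = None) -> list[str]:
        if matrix is not None:
            return list(self.metabolites[matrix].columns)
        return [c for m in self.metabolites.values() for c in m.columns]

    def clinical_names(self) -> list[str]:
        return list(self.clinical.columns)

    def validate(self) -> None:
        """Cross-check the schema against the tables."""
        declared = set(self.schema)
        present = set(self.clinical.columns) | {c for m in self.metabolites.values() for c in m.columns}
        missing = sorted(present - declared)
        extra = sorted(declared - present)
        if missing or extra:
            raise SchemaError(
                f"schema/table mismatch: undeclared columns {missing}, dangling schema entries {extra}"
            )
        for name, values in self.metabolites.items():
            codes = self.missing_codes[name]
            if not values.columns.equals(codes.columns) or len(values) != len(codes):
                raise SchemaError(f"matrix {name!r}: value/code shape mismatch")
            nan_mask = values.isna().to_numpy()
            code_missing = codes.to_numpy() != int(Missing.PRESENT)
            if not np.array_equal(nan_mask, code_missing):
                raise SchemaError(f"matrix {name!r}: NaN cells disagree with missingness codes")

    def equals(self, other: "CohortTable") -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        if not _frames_equal(self.clinical, other.clinical):
            return False
        if set(self.metabolites) != set(other.metabolites):
            return False
        for k in self.metabolites:
            if not _frames_equal(self.metabolites[k], other.metabolites[k]):
                return False
            if not self.missing_codes[k].equals(other.missing_codes[k]):
                return False
        if {k: v.to_dict() for k, v in self.schema.items()} != {
            k: v.to_dict() for k, v in other.schema.items()
        }:
            return False
        return _frames_equal(self.egfr.reset_index(drop=True), other.egfr.reset_index(drop=True))


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for c in a.columns:
        xa, xb = a[c].to_numpy(), b[c].to_numpy()
        try:
            fa = xa.astype(float)
            fb = xb.astype(float)
        except (TypeError, ValueError):
            if not np.array_equal(pd.isna(xa), pd.isna(xb)):
                return False
            ok = pd.isna(xa) | (xa == xb)
            if not ok.all():
                return False
            continue
        if not np.allclose(fa, fb, rtol=0, atol=1e-12, equal_nan=True):
            return False
    return True


# ---------------------------------------------------------------------------
# on-disk dialect: TSV tables + YAML schema sidecar


def _metabolite_cell(value: float, code: int) -> str:
    if code == Missing.TYPE1:
        return LOD_SENTINEL
    if code == Missing.TYPE2:
        return ""
    return repr(float(value))


def write_cohort(cohort: CohortTable, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as TSV tables with a YAML schema sidecar.

    Metabolite cells use ``<LOD`` for below-sensitivity (type-1) and an
    empty field for unmeasured (type-2) values so the two missingness types
    survive the round trip.  Returns the mapping of logical table name to
    file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    clin = cohort.clinical.copy()
    clin.insert(0, "sample_id", cohort.sample_ids)
    p = directory / "clinical.tsv"
    clin.to_csv(p, sep="\t", index=False, na_rep="")
    paths["clinical"] = p

    for name, values in cohort.metabolites.items():
        codes = cohort.missing_codes[name].to_numpy()
        vals = values.to_numpy()
        rows = []
        for i, sid in enumerate(cohort.sample_ids):
            rows.append(
                [sid] + [_metabolite_cell(vals[i, j], codes[i, j]) for j in range(vals.shape[1])]
            )
        p = directory / f"metabolites_{name}.tsv"
        with open(p, "w") as fh:
            fh.write("\t".join(["sample_id"] + list(values.columns)) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths[f"metabolites_{name}"] = p

    p = directory / "egfr.tsv"
    cohort.egfr.to_csv(p, sep="\t", index=False)
    paths["egfr"] = p

    p = directory / "schema.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(
            {"variables": [cohort.schema[k].to_dict() for k in sorted(cohort.schema)]},
            fh,
            sort_keys=False,
        )
    paths["schema"] = p
    return paths


def read_cohort(directory: str | Path) -> CohortTable:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "schema.yaml") as fh:
        schema_doc = yaml.safe_load(fh)
    schema = {d["name"]: VariableSchema.from_dict(d) for d in schema_doc["variables"]}

    clin = pd.read_csv(directory / "clinical.tsv", sep="\t", dtype=object, keep_default_na=False)
    sample_ids = clin.pop("sample_id").tolist()
    clinical = pd.DataFrame(index=range(len(sample_ids)))
    for c in clin.columns:
        col = clin[c].replace("", None)
        if schema[c].kind in ("continuous", "metabolite"):
            clinical[c] = pd.to_numeric(col, errors="raise")
        else:
            clinical[c] = col
    clinical.index = range(len(sample_ids))

    metabolites: dict[str, pd.DataFrame] = {}
    missing_codes: dict[str, pd.DataFrame] = {}
    for p in sorted(directory.glob("metabolites_*.tsv")):
        matrix = p.stem.removeprefix("metabolites_")
        raw = pd.read_csv(p, sep="\t", dtype=object, keep_default_na=False)
        raw = raw.drop(columns=["sample_id"])
        vals = np.full(raw.shape, np.nan)
        codes = np.zeros(raw.shape, dtype=np.int8)
        arr = raw.to_numpy()
        for j in range(arr.shape[1]):
            for i in range(arr.shape[0]):
                cell = arr[i, j]
                if cell == LOD_SENTINEL:
                    codes[i, j] = Missing.TYPE1
                elif cell == "":
                    codes[i, j] = Missing.TYPE2
                else:
                    vals[i, j] = float(cell)
        metabolites[matrix] = pd.DataFrame(vals, columns=raw.columns)
        missing_codes[matrix] = pd.DataFrame(codes, columns=raw.columns)

    egfr = pd.read_csv(directory / "egfr.tsv", sep="\t")
    cohort = CohortTable(
        sample_ids=sample_ids,
        clinical=clinical,
        metabolites=metabolites,
        missing_codes=missing_codes,
        schema=schema,
        egfr=egfr,
    )
    cohort.validate()
    return cohort


def clinical_missing_mask(cohort: CohortTable) -> pd.DataFrame:
    """Boolean mask of missing clinical cells (all clinical missingness is type-2)."""
    return cohort.clinical.isna()
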