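"""Record-level phenotype data and the candidate-term design-matrix algebra.

A dataset is a table of single-plant observations: four predictors
(SPAD chlorophyll index, stomatal conductance Gs, shoot sap Na+ and K+)
and the response, shoot dry weight (SDW, g/plant).  The modeling
vocabulary is the full quadratic polynomial in the four predictors:
intercept, four linear terms, four squares and six pairwise products —
fifteen candidate terms in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTOR_NAMES",
    "CSV_COLUMNS",
    "SchemaError",
    "ValidationError",
    "Term",
    "full_quadratic_terms",
    "PhenotypeRecord",
    "Dataset",
    "DesignMatrix",
    "read_dataset",
    "write_dataset",
    "build_design",
    "select_terms",
]

#: Predictor attribute names in index order X1..X4.
PREDICTOR_NAMES = ("spad", "gs", "shoot_na", "shoot_k")

#: Canonical CSV header: record field -> column name.
CSV_COLUMNS = {
    "genotype": "genotype",
    "salinity": "salinity_mM",
    "spad": "spad",
    "gs": "gs_mmol_m2_s",
    "shoot_na": "shoot_na_mM",
    "shoot_k": "shoot_k_mM",
    "sdw": "sdw_g",
}

#: Fields that must be non-negative.
_NONNEG = ("gs", "shoot_na", "shoot_k", "sdw")


class SchemaError(ValueError):
    """The input table does not have the expected columns."""


class ValidationError(ValueError):
    """A cell value violates the data contract."""


@dataclass(frozen=True, order=True)
class Term:
    """One candidate regression term over predictors X1..X4.

    ``kind`` is one of ``intercept``, ``linear``, ``square``, ``cross``;
    ``indices`` holds the 1-based predictor indices involved (empty for
    the intercept, one index for linear/square, an ordered pair i<j for
    cross products).
    """

    kind: str
    indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("intercept", "linear", "square", "cross"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        n_expected = {"intercept": 0, "linear": 1, "square": 1, "cross": 2}[self.kind]
        if len(self.indices) != n_expected:
            raise ValueError(f"{self.kind} term takes {n_expected} indices, got {self.indices}")
        if any(i < 1 or i > 4 for i in self.indices):
            raise ValueError(f"predictor indices must be in 1..4, got {self.indices}")
        if self.kind == "cross" and not self.indices[0] < self.indices[1]:
            raise ValueError("cross terms require ordered distinct indices i<j")

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return f"X{self.indices[0]}"
        if self.kind == "square":
            return f"X{self.indices[0]}^2"
        i, j = self.indices
        return f"X{i}*X{j}"

    def evaluate(self, predictors: np.ndarray) -> np.ndarray:
        """Column of this term's values given an (n, 4) predictor matrix."""
        predictors = np.asarray(predictors, dtype=float)
        if self.kind == "intercept":
            return np.ones(predictors.shape[0])
        if self.kind == "linear":
            return predictors[:, self.indices[0] - 1].copy()
        if self.kind == "square":
            return predictors[:, self.indices[0] - 1] ** 2
        i, j = self.indices
        return predictors[:, i - 1] * predictors[:, j - 1]

    @classmethod
    def parse(cls, name: str) -> "Term":
        """Inverse of :attr:`name` (e.g. ``"X2^2"`` or ``"X3*X4"``)."""
        name = name.strip()
        if name == "1":
            return cls("intercept")
        if "*" in name:
            i, j = (int(p.lstrip("X")) for p in name.split("*"))
            return cls("cross", (i, j))
        if name.endswith("^2"):
            return cls("square", (int(name[:-2].lstrip("X")),))
        return cls("linear", (int(name.lstrip("X")),))


def full_quadratic_terms() -> list[Term]:
    """The 15 candidate terms in canonical order.

    Order: intercept, X1..X4, X1^2..X4^2, then cross products X_iX_j in
    lexicographic (i, j) order.
    """
    terms = [Term("intercept")]
    terms += [Term("linear", (i,)) for i in range(1, 5)]
    terms += [Term("square", (i,)) for i in range(1, 5)]
    terms += [Term("cross", (i, j)) for i in range(1, 4) for j in range(i + 1, 5)]
    return terms


@dataclass(frozen=True)
class PhenotypeRecord:
    """One plant observation: predictors X1..X4 and the response Y = SDW."""

    record_id: int
    genotype: str
    salinity: float
    spad: float      # X1, SPAD units
    gs: float        # X2, mmol m-2 s-1
    shoot_na: float  # X3, mM
    shoot_k: float   # X4, mM
    sdw: float       # Y, g/plant

    def __post_init__(self) -> None:
        for name in ("spad", "gs", "shoot_na", "shoot_k", "sdw", "salinity"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"record {self.record_id}: {name} is not finite ({v!r})")
        for name in _NONNEG:
            if getattr(self, name) < 0:
                raise ValidationError(f"record {self.record_id}: {name} must be >= 0")

    @property
    def predictors(self) -> tuple[float, float, float, float]:
        return (self.spad, self.gs, self.shoot_na, self.shoot_k)


class Dataset:
    """Ordered collection of :class:`PhenotypeRecord` with unique ids."""

    def __init__(self, records: Iterable[PhenotypeRecord]):
        self.records: list[PhenotypeRecord] = list(records)
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("record_id values must be unique within a dataset")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def record_ids(self) -> list[int]:
        return [r.record_id for r in self.records]

    def predictor_matrix(self) -> np.ndarray:
        """(n, 4) array of raw predictors in X1..X4 order."""
        return np.array([r.predictors for r in self.records], dtype=float)

    def response(self) -> np.ndarray:
        return np.array([r.sdw for r in self.records], dtype=float)

    def drop(self, record_ids: Iterable[int]) -> "Dataset":
        """A new dataset without the given records (purge operation)."""
        drop = set(record_ids)
        unknown = drop - set(self.record_ids)
        if unknown:
            raise KeyError(f"unknown record ids: {sorted(unknown)}")
        return Dataset(r for r in self.records if r.record_id not in drop)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"record_id": r.record_id, **{col: getattr(r, f) for f, col in CSV_COLUMNS.items()}}
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Dataset":
        missing = [c for c in CSV_COLUMNS.values() if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for pos, (_, row) in enumerate(frame.iterrows()):
            rid = int(row["record_id"]) if "record_id" in frame.columns else pos
            try:
                values = {f: float(row[col]) for f, col in CSV_COLUMNS.items() if f != "genotype"}
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {pos}: non-numeric cell ({exc})") from None
            try:
                records.append(PhenotypeRecord(record_id=rid, genotype=str(row["genotype"]), **values))
            except ValidationError as exc:
                raise ValidationError(f"row {pos}: {exc}") from None
        return cls(records)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Dataset(n={self.n})"


def read_dataset(path: str | Path) -> Dataset:
    """Read a phenotype table from CSV (canonical header, UTF-8)."""
    frame = pd.read_csv(path, encoding="utf-8")
    return Dataset.from_frame(frame)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a phenotype table in the same CSV dialect as :func:`read_dataset`."""
    dataset.to_frame().to_csv(path, index=False, encoding="utf-8")


@dataclass
class DesignMatrix:
    """An (n, p) design matrix with its ordered term list and response."""

    values: np.ndarray
    terms: list[Term]
    response: np.ndarray
    record_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.terms):
            raise ValueError("values must be (n, p) with p == len(terms)")
        if self.response.shape != (self.values.shape[0],):
            raise ValueError("response length must equal number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def has_intercept(self) -> bool:
        return any(t.kind == "intercept" for t in self.terms)


def build_design(dataset: Dataset, terms: Sequence[Term] | None = None) -> DesignMatrix:
    """Evaluate the given terms (default: full quadratic, canonical order)."""
    terms = list(terms) if terms is not None else full_quadratic_terms()
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate term descriptors in design")
    preds = dataset.predictor_matrix()
    if dataset.n == 0:
        values = np.empty((0, len(terms)))
    else:
        values = np.column_stack([t.evaluate(preds) for t in terms])
    return DesignMatrix(values, terms, dataset.response(), dataset.record_ids)


def select_terms(design: DesignMatrix, keep: Sequence[Term]) -> DesignMatrix:
    """Restrict (and reorder) columns to ``keep``; the response is unchanged."""
    keep = list(keep)
    index = {t: j for j, t in enumerate(design.terms)}
    unknown = [t for t in keep if t not in index]
    if unknown:
        raise KeyError(f"terms not in design: {[t.name for t in unknown]}")
    cols = [index[t] for t in keep]
    return DesignMatrix(design.values[:, cols], keep, design.response, design.record_ids)
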