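"""Readers and writers for metabolite matrices, sample metadata, pathway
annotations and serialized score models.

The on-disk matrix layout is a wide delimited table: one row per sample,
first three columns ``sample_id``, ``cohort``, ``batch``, then one column
per metabolite.  Empty cells and ``NA`` encode missing values.  All
observed raw intensities must be strictly positive; matrices carry a
``scale`` attribute so that log2-transformed data can flow through the
same container without tripping the positivity invariant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

MISSING_TOKENS = ("", "NA", "NaN", "nan")

#: columns reserved for sample annotations in the wide matrix layout
_META_COLS = ("sample_id", "cohort", "batch")


class MatrixFormatError(ValueError):
    """Raised when a matrix file violates the format contract."""


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity grid with per-sample batch/cohort labels.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per metabolite.
        ``NaN`` encodes a missing measurement.
    batch
        Per-sample batch label, aligned to ``data.index``.
    cohort
        Per-sample cohort label, aligned to ``data.index``.
    scale
        ``"intensity"`` for raw/normalized positive intensities (positivity
        enforced) or ``"log2"`` after log transformation.
    """

    data: pd.DataFrame
    batch: pd.Series
    cohort: pd.Series
    scale: str = "intensity"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate metabolite ids: {dups}")
        self.data = self.data.astype(float)
        self.batch = pd.Series(self.batch, index=self.data.index)
        self.cohort = pd.Series(self.cohort, index=self.data.index)
        if self.scale not in ("intensity", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "intensity":
            vals = self.data.to_numpy()
            bad = np.asarray(vals <= 0) & ~np.isnan(vals)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise MatrixFormatError(
                    "nonpositive intensity at sample "
                    f"{self.data.index[i]!r}, metabolite {self.data.columns[j]!r}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the measurement is missing."""
        return self.data.isna()

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of missing samples."""
        return self.data.isna().mean(axis=0)

    def select_metabolites(self, ids) -> "MetaboliteMatrix":
        missing = [m for m in ids if m not in self.data.columns]
        if missing:
            raise KeyError(f"metabolites not in matrix: {missing}")
        return MetaboliteMatrix(
            self.data.loc[:, list(ids)].copy(), self.batch.copy(),
            self.cohort.copy(), scale=self.scale,
        )

    def select_samples(self, ids) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.data.loc[list(ids)].copy(), self.batch.loc[list(ids)].copy(),
            self.cohort.loc[list(ids)].copy(), scale=self.scale,
        )

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.data.copy(), self.batch.copy(), self.cohort.copy(), scale=self.scale
        )


def read_metabolite_matrix(path, dialect: str | None = None) -> MetaboliteMatrix:
    """Parse a wide-format metabolite table.

    ``dialect`` is ``"tsv"`` or ``"csv"``; inferred from the suffix when
    omitted.  Blank and ``NA`` cells become missing; any other non-numeric
    cell is an error naming its row and column, as is any nonpositive value.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in _META_COLS:
        if col not in raw.columns:
            raise MatrixFormatError(f"missing required column {col!r} in {path}")
    met_cols = [c for c in raw.columns if c not in _META_COLS]
    values = pd.DataFrame(index=raw["sample_id"], columns=met_cols, dtype=float)
    values.index.name = "sample_id"
    for col in met_cols:
        cells = raw[col].str.strip()
        is_missing = cells.isin(MISSING_TOKENS)
        try:
            # numpy's strtod is correctly rounded, so write/read round-trips
            # preserve values bit for bit
            parsed = cells.where(~is_missing).astype(float)
        except (ValueError, TypeError):
            for idx, cell in cells.items():
                if cell in MISSING_TOKENS:
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise MatrixFormatError(
                        f"non-numeric cell {cell!r} at sample "
                        f"{raw.loc[idx, 'sample_id']!r}, metabolite {col!r}"
                    ) from None
            raise
        values[col] = parsed.to_numpy()
    return MetaboliteMatrix(
        values,
        batch=pd.Series(raw["batch"].to_numpy(), index=values.index),
        cohort=pd.Series(raw["cohort"].to_numpy(), index=values.index),
    )


def write_metabolite_matrix(matrix: MetaboliteMatrix, path, dialect: str | None = None) -> None:
    """Write a matrix in the wide layout ``read_metabolite_matrix`` accepts.

    Floats are written with ``repr`` precision so a read/write round trip
    preserves values bit for bit.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = matrix.data.copy()
    out.insert(0, "batch", matrix.batch)
    out.insert(0, "cohort", matrix.cohort)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep="NA", float_format=lambda v: repr(float(v)))


@dataclass
class PathwayAnnotation:
    """Two-level (sub/super) pathway membership for metabolites.

    Metabolites without an annotation are kept and flagged rather than
    dropped; overrepresentation analysis excludes them from its universe.
    """

    sub_pathway: dict[str, str | None] = field(default_factory=dict)
    super_pathway: dict[str, str | None] = field(default_factory=dict)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.sub_pathway)

    def is_annotated(self, metabolite_id: str) -> bool:
        return self.sub_pathway.get(metabolite_id) is not None or \
            self.super_pathway.get(metabolite_id) is not None

    @property
    def n_unannotated(self) -> int:
        return sum(not self.is_annotated(m) for m in self.sub_pathway)

    def pathways(self, level: str) -> dict[str, set]:
        """Pathway id -> member metabolite set at ``level`` ("sub"|"super")."""
        table = {"sub": self.sub_pathway, "super": self.super_pathway}[level]
        out: dict[str, set] = {}
        for met, pw in table.items():
            if pw is not None:
                out.setdefault(pw, set()).add(met)
        return out


def read_pathway_annotations(path, sep: str | None = None) -> PathwayAnnotation:
    """Read a metabolite -> (sub_pathway, super_pathway) table.

    Accepts two or three columns: metabolite id, sub-pathway, and optionally
    super-pathway.  Blank pathway cells mean unannotated.  Duplicate
    metabolite rows and empty files are errors; annotations for metabolites
    absent from any particular matrix are retained (the join is permissive).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0:
        raise MatrixFormatError(f"empty annotation file: {path}")
    if raw.shape[1] not in (2, 3):
        raise MatrixFormatError(
            f"annotation table must have 2 or 3 columns, got {raw.shape[1]}"
        )
    ids = raw.iloc[:, 0].str.strip()
    if ids.duplicated().any():
        raise MatrixFormatError(
            f"duplicate metabolite annotation: {ids[ids.duplicated()].tolist()}"
        )

    def _clean(col: pd.Series) -> list[str | None]:
        vals = col.str.strip()
        return [None if v in MISSING_TOKENS else v for v in vals]

    sub = _clean(raw.iloc[:, 1])
    sup = _clean(raw.iloc[:, 2]) if raw.shape[1] == 3 else [None] * len(ids)
    return PathwayAnnotation(
        sub_pathway=dict(zip(ids, sub)), super_pathway=dict(zip(ids, sup))
    )


def read_sample_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read per-subject metadata (demographics, spirometry, comorbidities).

    Validates the spirometric invariants: FEV1 <= FVC where both present and
    FEV1/FVC within [0, 1].
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    tab = pd.read_csv(path, sep=sep, na_values=list(MISSING_TOKENS))
    if "subject_id" not in tab.columns:
        raise MatrixFormatError("sample table must contain a subject_id column")
    if tab["subject_id"].duplicated().any():
        raise MatrixFormatError("duplicate subject_id in sample table")
    tab = tab.set_index("subject_id", drop=False)
    if {"fev1", "fvc"} <= set(tab.columns):
        both = tab["fev1"].notna() & tab["fvc"].notna()
        if (tab.loc[both, "fev1"] > tab.loc[both, "fvc"] + 1e-9).any():
            raise MatrixFormatError("FEV1 exceeds FVC for at least one subject")
    if "fev1_fvc" in tab.columns:
        r = tab["fev1_fvc"].dropna()
        if ((r < 0) | (r > 1)).any():
            raise MatrixFormatError("fev1_fvc outside [0, 1]")
    return tab


def write_sample_table(table: pd.DataFrame, path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_csv(path, sep=sep, na_rep="NA", index=False)


# -- score-model serialization ------------------------------------------------

MODEL_SCHEMA_VERSION = 1
_MODEL_REQUIRED = (
    "schema_version", "outcome", "metabolite_ids", "coefficients", "intercept",
    "alpha", "lam", "feature_means", "feature_sds", "provenance",
)


def serialize_model(model, path) -> None:
    """Write a :class:`~metaboclock.scores.ScoreModel` as versioned JSON."""
    payload = model.to_dict()
    payload["schema_version"] = MODEL_SCHEMA_VERSION
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def deserialize_model(path):
    """Load a score model, validating schema version and required fields."""
    from .scores import ScoreModel  # deferred: scores imports io types

    payload = json.loads(Path(path).read_text())
    missing = [k for k in _MODEL_REQUIRED if k not in payload]
    if missing:
        raise MatrixFormatError(f"model file missing fields: {missing}")
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise MatrixFormatError(
            f"unsupported model schema version {payload['schema_version']!r}"
        )
    return ScoreModel.from_dict(payload)
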