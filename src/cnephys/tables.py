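"""Feature tables: cells x the 12 intrinsic-excitability measures.

The measure roster is fixed and ordered.  Missing values (e.g. the
interspike-interval CV of onset-only bushy cells) are ``NaN`` in memory and
the literal token ``NA`` in the on-disk TSV dialect.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recordings import CLASS_LABELS, PRINCIPAL_CLASSES

#: The 12 measures, in roster order.
MEASURES = (
    "RMP",
    "tau_m",
    "R_in",
    "tau_h",
    "BA_ratio",
    "AP_peak",
    "AP_halfwidth",
    "AHP",
    "adaptation",
    "rebound",
    "CV",
    "I_rate",
)

#: Metadata columns carried alongside the measures.
META_COLUMNS = ("class_label", "strain", "sex")

MISSING_TOKEN = "NA"
_FLOAT_FMT = "%.9g"


class TableError(ValueError):
    """Raised for malformed feature tables."""


@dataclass
class FeatureTable:
    """Cells x measures matrix with per-cell class labels.

    ``values`` is a float DataFrame indexed by cell id with exactly the
    columns of :data:`MEASURES` (in order); ``labels`` is a parallel Series
    of class labels; ``meta`` holds strain/sex metadata.
    """

    values: pd.DataFrame
    labels: pd.Series
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.values
        if list(vals.columns) != list(MEASURES):
            unknown = [c for c in vals.columns if c not in MEASURES]
            if unknown:
                raise TableError(f"unknown measure columns: {unknown}")
            missing = [c for c in MEASURES if c not in vals.columns]
            if missing:
                raise TableError(f"missing measure columns: {missing}")
            vals = vals[list(MEASURES)]
        self.values = vals.astype(float)
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate cell ids: {dups}")
        if not self.labels.index.equals(vals.index):
            self.labels = self.labels.reindex(vals.index)
        bad = set(self.labels.dropna()) - set(CLASS_LABELS)
        if bad:
            raise TableError(f"unknown class labels: {sorted(bad)}")
        if len(vals) and self.values.isna().all(axis=1).any():
            empty = self.values.index[self.values.isna().all(axis=1)].tolist()
            raise TableError(f"rows with no non-missing value: {empty}")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=vals.index, columns=["strain", "sex"], dtype=object)
        else:
            self.meta = self.meta.reindex(vals.index)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    def principal_subset(self) -> "FeatureTable":
        """Rows whose label is one of the six principal classes."""
        keep = self.labels.isin(PRINCIPAL_CLASSES)
        return FeatureTable(self.values[keep], self.labels[keep], self.meta[keep])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.labels.copy(), self.meta.copy())


def feature_table_from_rows(rows: list[dict]) -> FeatureTable:
    """Build a table from per-cell dicts (cell_id, class_label, measures...)."""
    df = pd.DataFrame(rows).set_index("cell_id")
    labels = df["class_label"]
    meta = df[[c for c in ("strain", "sex") if c in df.columns]]
    values = df[[c for c in MEASURES]]
    return FeatureTable(values, labels, meta)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a TSV with header: cell_id, class_label, strain, sex, 12 measures."""
    out = pd.concat(
        [
            table.labels.rename("class_label"),
            table.meta.reindex(columns=["strain", "sex"]),
            table.values,
        ],
        axis=1,
    )
    out.index.name = "cell_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format=_FLOAT_FMT)


def read_feature_table(path) -> FeatureTable:
    """Read a TSV written by :func:`write_feature_table`.

    Unknown columns and duplicate cell ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False)
    if "cell_id" not in df.columns:
        raise TableError("feature table lacks a cell_id column")
    known = {"cell_id", "class_label", "strain", "sex", *MEASURES}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise TableError(f"unknown columns in feature table: {unknown}")
    df = df.set_index("cell_id")
    labels = df.get("class_label", pd.Series("unknown", index=df.index))
    meta = df.reindex(columns=["strain", "sex"])
    try:
        values = df[list(MEASURES)]
    except KeyError as exc:
        raise TableError(f"feature table is missing measure columns: {exc}") from exc
    return FeatureTable(values.astype(float), labels, meta)
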