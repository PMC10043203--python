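"""Clinical cohort table: values, missingness mask, and class labels.

The central container is :class:`ClinicalTable`, a samples x features
matrix with an explicit boolean missingness mask and a binary label per
sample.  The two classes are the *majority* (incarcerated hernia without
necrosis) and the *minority* (intestinal necrosis).  Masked cells carry
no readable value: the dense matrix stores ``NaN`` there and
:meth:`ClinicalTable.dense` refuses to hand out a matrix while any cell
is still masked.

On disk a cohort is an RFC-4180 CSV with a header row: an optional
``sample_id`` column, one column per catalog feature (named by feature
id), and a ``label`` column holding ``hernia`` / ``necrosis``.  Missing
cells are empty strings, never sentinel numbers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_INCLUDE_AGE_IN, Design, FeatureCatalog

__all__ = ["ClassLabel", "ClinicalTable", "read_table", "write_table", "select_design"]

LABEL_COLUMN = "label"
SAMPLE_ID_COLUMN = "sample_id"


class ClassLabel(str, enum.Enum):
    """Discharge-diagnosis class.

    The majority class (hernia without necrosis) is the study's
    "positive" class; the minority class (necrosis) is its "negative"
    class.  The enum names keep the clinical meaning explicit so the
    positive/negative bookkeeping can never silently flip.
    """

    MAJORITY_HERNIA = "hernia"
    MINORITY_NECROSIS = "necrosis"

    @classmethod
    def coerce(cls, value: "ClassLabel | str") -> "ClassLabel":
        if isinstance(value, cls):
            return value
        return cls(str(value))


@dataclass(frozen=True)
class ClinicalTable:
    """Samples x features matrix with missingness mask and labels.

    ``values[i, j]`` is ``NaN`` wherever ``mask[i, j]`` is True; observed
    cells are finite.  ``feature_ids`` names the columns (a subset of the
    catalog, in catalog order); ``design`` records which panel design the
    columns realize.
    """

    values: np.ndarray  # float64, NaN at masked cells
    mask: np.ndarray  # bool, True = missing
    labels: np.ndarray  # object array of ClassLabel
    feature_ids: tuple[str, ...]
    catalog: FeatureCatalog
    design: Design = Design.M3
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.shape != mask.shape:
            raise ValueError("values and mask shapes differ")
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if values.shape[1] != len(self.feature_ids):
            raise ValueError("column count does not match feature_ids")
        if len(self.labels) != values.shape[0]:
            raise ValueError("label count does not match row count")
        unknown = [f for f in self.feature_ids if f not in self.catalog]
        if unknown:
            raise ValueError(f"unknown feature ids: {unknown}")
        order = {f: i for i, f in enumerate(self.catalog.feature_ids)}
        if list(self.feature_ids) != sorted(self.feature_ids, key=order.__getitem__):
            raise ValueError("feature_ids must be in catalog order")
        # masked cells carry no readable value
        values = values.copy()
        values[mask] = np.nan
        if not np.isfinite(values[~mask]).all():
            raise ValueError("observed cells must be finite numbers")
        labels = np.array([ClassLabel.coerce(l) for l in self.labels], dtype=object)
        if self.sample_ids is not None and len(self.sample_ids) != values.shape[0]:
            raise ValueError("sample_id count does not match row count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))

    # -- basic shape ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[ClassLabel, int]:
        return {c: int(np.sum(self.labels == c.value)) for c in ClassLabel}

    def indices_of(self, label: ClassLabel) -> np.ndarray:
        return np.flatnonzero(self.labels == ClassLabel.coerce(label).value)

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    # -- value access --------------------------------------------------

    def dense(self) -> np.ndarray:
        """The full value matrix; an error while any cell is masked."""
        if self.mask.any():
            raise ValueError("table has masked cells; impute before dense access")
        return self.values.copy()

    def value_at(self, row: int, feature_id: str) -> float:
        j = self.feature_ids.index(feature_id)
        if self.mask[row, j]:
            raise ValueError(f"cell ({row}, {feature_id}) is masked")
        return float(self.values[row, j])

    def column_observed(self, feature_id: str) -> np.ndarray:
        """Observed (unmasked) values of one feature column."""
        j = self.feature_ids.index(feature_id)
        return self.values[~self.mask[:, j], j]

    # -- derivation ----------------------------------------------------

    def take_rows(self, indices: Sequence[int]) -> "ClinicalTable":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            values=self.values[idx],
            mask=self.mask[idx],
            labels=self.labels[idx],
            sample_ids=None
            if self.sample_ids is None
            else tuple(self.sample_ids[i] for i in idx),
        )

    def take_features(self, feature_ids: Sequence[str]) -> "ClinicalTable":
        missing = [f for f in feature_ids if f not in self.feature_ids]
        if missing:
            raise ValueError(f"features not present in table: {missing}")
        ordered = self.catalog.catalog_order(feature_ids)
        cols = [self.feature_ids.index(f) for f in ordered]
        return replace(
            self,
            values=self.values[:, cols],
            mask=self.mask[:, cols],
            feature_ids=tuple(ordered),
        )

    def with_values(self, values: np.ndarray, mask: np.ndarray) -> "ClinicalTable":
        return replace(self, values=values, mask=mask)

    # -- frames --------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_ids))
        df[df.columns] = df[df.columns].mask(pd.DataFrame(self.mask, columns=df.columns))
        df[LABEL_COLUMN] = [l.value for l in self.labels]
        if self.sample_ids is not None:
            df.insert(0, SAMPLE_ID_COLUMN, list(self.sample_ids))
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        catalog: FeatureCatalog | None = None,
        design: Design | str = Design.M3,
    ) -> "ClinicalTable":
        catalog = catalog or FeatureCatalog.default()
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"missing label column {LABEL_COLUMN!r}")
        sample_ids = None
        if SAMPLE_ID_COLUMN in df.columns:
            ids = [str(v) for v in df[SAMPLE_ID_COLUMN]]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample identifier")
            sample_ids = tuple(ids)
        feature_cols = [c for c in df.columns if c not in (LABEL_COLUMN, SAMPLE_ID_COLUMN)]
        unknown = [c for c in feature_cols if c not in catalog]
        if unknown:
            raise ValueError(f"unknown column {unknown[0]!r}")
        ordered = catalog.catalog_order(feature_cols)
        vals = np.empty((len(df), len(ordered)), dtype=float)
        for j, col in enumerate(ordered):
            try:
                vals[:, j] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric value in column {col!r}: {exc}") from None
        mask = np.isnan(vals)
        labels = [ClassLabel.coerce(v) for v in df[LABEL_COLUMN]]
        return cls(
            values=vals,
            mask=mask,
            labels=np.array(labels, dtype=object),
            feature_ids=tuple(ordered),
            catalog=catalog,
            design=Design.coerce(design),
            sample_ids=sample_ids,
        )


def read_table(
    path: str | Path,
    catalog: FeatureCatalog | None = None,
    design: Design | str = Design.M3,
) -> ClinicalTable:
    """Read a cohort CSV; empty cells become masked entries."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    return ClinicalTable.from_dataframe(df, catalog=catalog, design=design)


def write_table(table: ClinicalTable, path: str | Path) -> None:
    """Write a cohort CSV; masked cells become empty strings.

    ``read_table(write_table(t))`` reproduces values, mask and labels
    exactly (floats are written in full round-trip precision).
    """
    df = table.to_dataframe()
    df.to_csv(path, index=False, na_rep="")


def select_design(
    table: ClinicalTable,
    design: Design | str,
    include_age_in: Sequence[Design] = DEFAULT_INCLUDE_AGE_IN,
) -> ClinicalTable:
    """Restrict a table's columns to one analysis design.

    ``M1`` keeps the blood-routine panel, ``M2`` the liver/kidney panel,
    ``M3`` both; age (``f0``) joins the designs listed in
    ``include_age_in``.  Labels are unchanged.  Selecting a design twice
    is idempotent.
    """
    design = Design.coerce(design)
    wanted = table.catalog.design_feature_ids(design, include_age_in=include_age_in)
    missing = [f for f in wanted if f not in table.feature_ids]
    if missing:
        raise ValueError(f"design {design.value} requires absent columns: {missing}")
    out = table.take_features(wanted)
    return replace(out, design=design)
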