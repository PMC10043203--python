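"""Missing-rate cohort filtering.

Sample selection trades per-row missingness against class preservation:
majority-class rows must be complete (no missing cell), while
minority-class rows are kept as long as *less than* 40% of the active
design's features are missing.  Keeping sparse minority rows preserves
as much of the rare necrosis class as possible instead of letting
row-deletion deepen the imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .table import ClassLabel, ClinicalTable

__all__ = ["FilterPolicy", "FilterReport", "missing_fraction", "filter_cohort"]


@dataclass(frozen=True)
class FilterPolicy:
    """Per-class caps on the row-wise missing fraction.

    Majority rows pass when their missing fraction is ``<=``
    ``majority_max_missing_fraction`` (default 0: complete rows only);
    minority rows pass when it is strictly ``<``
    ``minority_max_missing_fraction`` (default 0.40).
    """

    majority_max_missing_fraction: float = 0.0
    minority_max_missing_fraction: float = 0.40

    def __post_init__(self):
        for v in (self.majority_max_missing_fraction, self.minority_max_missing_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("missing-fraction thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class FilterReport:
    kept_majority: int
    dropped_majority: int
    kept_minority: int
    dropped_minority: int

    @property
    def kept_total(self) -> int:
        return self.kept_majority + self.kept_minority

    def to_dict(self) -> dict:
        return {
            "kept_majority": self.kept_majority,
            "dropped_majority": self.dropped_majority,
            "kept_minority": self.kept_minority,
            "dropped_minority": self.dropped_minority,
        }


def missing_fraction(mask_row: np.ndarray) -> float:
    """Fraction of the active feature columns that are masked in one row."""
    mask_row = np.asarray(mask_row, dtype=bool)
    if mask_row.size == 0:
        raise ValueError("no active feature columns")
    return float(mask_row.sum()) / mask_row.size


def filter_cohort(
    table: ClinicalTable, policy: FilterPolicy = FilterPolicy()
) -> tuple[ClinicalTable, FilterReport]:
    """Apply the per-class missing-rate rule; idempotent.

    The denominator of each row's missing fraction is the number of
    feature columns currently in the table, i.e. the active design's
    feature set (apply :func:`~necrotriage.table.select_design` first).
    """
    if table.n_samples == 0:
        raise ValueError("empty input table")
    fractions = table.mask.sum(axis=1) / table.n_features
    is_minority = table.labels == ClassLabel.MINORITY_NECROSIS.value
    keep = np.where(
        is_minority,
        fractions < policy.minority_max_missing_fraction,
        fractions <= policy.majority_max_missing_fraction,
    )
    report = FilterReport(
        kept_majority=int(np.sum(keep & ~is_minority)),
        dropped_majority=int(np.sum(~keep & ~is_minority)),
        kept_minority=int(np.sum(keep & is_minority)),
        dropped_minority=int(np.sum(~keep & is_minority)),
    )
    return table.take_rows(np.flatnonzero(keep)), report
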