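"""RIN-3M imputation: region-random interpolation over mode/mean/median.

For each feature the mode ``m``, mean ``n`` and median ``p`` of the
observed values are computed; a missing cell is replaced by

    I = (max(m, n, p) - min(m, n, p)) * rv + min(m, n, p),

with ``rv`` an independent uniform draw on ``[0, 1)``.  The imputed
value therefore lands inside the envelope spanned by the three location
statistics, and when the three coincide (symmetric, unimodal data) the
rule collapses exactly to mean imputation.

Clinical lab values are recorded at finite precision, so the mode is
taken over values rounded to the catalog's recorded number of decimal
places.  Multimodal columns are resolved deterministically: among the
most frequent rounded values, pick the one closest to the median,
breaking remaining ties toward the smaller value.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .table import ClinicalTable

__all__ = ["feature_stats", "rin3m_value", "ImputationStats", "impute_table"]


def feature_stats(observed: Iterable[float], precision: int = 2) -> tuple[float, float, float]:
    """Mode, mean and median of one feature's observed values.

    The mode is the most frequent value after rounding to ``precision``
    decimal places; ties go to the candidate closest to the median, then
    to the smaller candidate.  The median of an even count is the mean
    of the central pair.
    """
    x = np.asarray(list(observed), dtype=float)
    if x.size == 0:
        raise ValueError("feature_stats needs at least one observed value")
    if not np.isfinite(x).all():
        raise ValueError("observed values must be finite")
    mean = float(np.mean(x))
    median = float(np.median(x))
    rounded = np.round(x, precision)
    counts = Counter(rounded.tolist())
    top = max(counts.values())
    candidates = sorted(v for v, c in counts.items() if c == top)
    # closest to the median, then smaller
    mode = min(candidates, key=lambda v: (abs(v - median), v))
    return float(mode), mean, median


def rin3m_value(m: float, n: float, p: float, rv: float) -> float:
    """One region-random interpolation draw for a single cell."""
    if not (0.0 <= rv < 1.0):
        raise ValueError("rv must lie in [0, 1)")
    if not all(np.isfinite(v) for v in (m, n, p)):
        raise ValueError("mode/mean/median must be finite")
    lo = min(m, n, p)
    hi = max(m, n, p)
    return (hi - lo) * rv + lo


@dataclass(frozen=True)
class ImputationStats:
    """Fitted per-feature (mode, mean, median) triples.

    Statistics exist only for features with at least one observed value
    in the fitting data.  Fitting is label-blind; by default the
    pipeline fits on the training split only and applies the same stats
    to both splits, avoiding train/test leakage (a ``fit_on`` switch in
    the pipeline config allows fitting on all rows instead).
    """

    triples: Mapping[str, tuple[float, float, float]]  # fid -> (m, n, p)
    n_fit: int
    precisions: Mapping[str, int]

    def __post_init__(self):
        for fid, (m, n, p) in self.triples.items():
            if not all(np.isfinite(v) for v in (m, n, p)):
                raise ValueError(f"non-finite statistics for {fid}")

    @classmethod
    def fit(cls, table: ClinicalTable) -> "ImputationStats":
        triples: dict[str, tuple[float, float, float]] = {}
        precisions: dict[str, int] = {}
        for fid in table.feature_ids:
            obs = table.column_observed(fid)
            prec = table.catalog.precision(fid)
            precisions[fid] = prec
            if obs.size:
                triples[fid] = feature_stats(obs, precision=prec)
        return cls(triples=triples, n_fit=table.n_samples, precisions=precisions)

    def envelope(self, feature_id: str) -> tuple[float, float]:
        m, n, p = self.triples[feature_id]
        return min(m, n, p), max(m, n, p)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_fit": self.n_fit,
            "triples": {k: list(v) for k, v in self.triples.items()},
            "precisions": dict(self.precisions),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ImputationStats":
        payload = json.loads(Path(path).read_text())
        return cls(
            triples={k: tuple(v) for k, v in payload["triples"].items()},
            n_fit=int(payload["n_fit"]),
            precisions={k: int(v) for k, v in payload["precisions"].items()},
        )


def impute_table(table: ClinicalTable, stats: ImputationStats, seed: int) -> ClinicalTable:
    """Replace every masked cell by an independent RIN-3M draw.

    Cells are visited in row-major, catalog-column order and consume one
    uniform draw each from a single generator seeded with ``seed``, so a
    given seed reproduces the imputation exactly.  Observed cells are
    untouched; the output mask is all-false.
    """
    if not table.mask.any():
        return table
    missing_cols = {
        fid for j, fid in enumerate(table.feature_ids) if table.mask[:, j].any()
    }
    uncovered = sorted(missing_cols - set(stats.triples), key=table.feature_ids.index)
    if uncovered:
        raise ValueError(f"masked cells in features without fitted statistics: {uncovered}")
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    rows, cols = np.nonzero(table.mask)  # np.nonzero is row-major
    draws = rng.random(rows.size)
    for r, c, rv in zip(rows, cols, draws):
        m, n, p = stats.triples[table.feature_ids[c]]
        values[r, c] = rin3m_value(m, n, p, rv)
    return table.with_values(values, np.zeros_like(table.mask))
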