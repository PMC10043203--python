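"""Feature selection: Gini importance over CV folds, FI and FC_k sets.

A random forest's impurity-based (Gini) importances are recorded on
each of five stratified CV training folds and averaged; the mean is the
feature's importance score and descending score (ties broken by catalog
order) is the ranking.

Two named selections are built on top of the rankings:

* ``FI`` — take the top 15 features of the combined-panel design M3,
  intersect them with the top 10 of M1 and with the top 10 of M2, and
  union the two intersections (ordered by M3 rank).
* ``FC_k`` — sweep prefixes of the M3 ranking (k = 1..max_k), evaluate
  the full sub-balanced pipeline on each prefix, and keep the k with
  the best metric (ties to the smaller k).  An exhaustive subset mode
  is available for <= 12 candidates as a brute-force cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .catalog import FeatureCatalog, normalize_name
from .ensemble import LearnerSpec
from .table import ClinicalTable

__all__ = [
    "ImportanceTable",
    "FeatureSet",
    "gini_importance",
    "build_fi_set",
    "best_prefix_search",
]


@dataclass(frozen=True)
class ImportanceTable:
    """Per-feature mean Gini importance over CV folds."""

    feature_ids: tuple[str, ...]
    per_fold: np.ndarray  # folds x features, each row sums to 1
    catalog: FeatureCatalog

    def __post_init__(self):
        pf = np.asarray(self.per_fold, dtype=float)
        if pf.ndim != 2 or pf.shape[1] != len(self.feature_ids):
            raise ValueError("per_fold must be folds x features")
        object.__setattr__(self, "per_fold", pf)

    @property
    def folds(self) -> int:
        return self.per_fold.shape[0]

    @property
    def mean_importance(self) -> np.ndarray:
        return self.per_fold.mean(axis=0)

    @property
    def ranking(self) -> list[str]:
        """Feature ids by descending mean importance; ties by catalog order."""
        mean = self.mean_importance
        order = {f: i for i, f in enumerate(self.catalog.feature_ids)}
        return [
            f
            for f, _ in sorted(
                zip(self.feature_ids, mean), key=lambda t: (-t[1], order[t[0]])
            )
        ]

    def top(self, k: int) -> list[str]:
        if k > len(self.feature_ids):
            raise ValueError(f"top-{k} exceeds ranking length {len(self.feature_ids)}")
        return self.ranking[:k]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "name": [self.catalog.name_of(f) for f in self.feature_ids],
                "mean_importance": self.mean_importance,
                **{f"fold_{i}": self.per_fold[i] for i in range(self.folds)},
            }
        )


@dataclass(frozen=True)
class FeatureSet:
    """A named, ordered feature selection with its construction record."""

    name: str
    members: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("feature set members must be unique")

    def __len__(self) -> int:
        return len(self.members)


def gini_importance(
    table: ClinicalTable,
    spec: LearnerSpec = LearnerSpec.rf(),
    folds: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """Mean impurity-reduction importances over stratified CV folds.

    One forest is fitted per fold on that fold's training portion of the
    (fully imputed) table; each fold's normalized importances sum to 1.
    """
    if spec.algorithm != "rf":
        raise ValueError("Gini importance requires the rf learner")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if table.mask.any():
        raise ValueError("table has masked cells; impute first")
    counts = table.class_counts()
    if min(counts.values()) < folds:
        raise ValueError("folds exceed the smaller class count")
    X = table.values
    y = np.array([l.value for l in table.labels])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    rows = []
    for fold_i, (tr, _te) in enumerate(skf.split(X, y)):
        est = spec.make_estimator(seed=(seed + 7919 * (fold_i + 1)) % (2**31))
        est.fit(X[tr], y[tr])
        rows.append(est.feature_importances_)
    return ImportanceTable(
        feature_ids=table.feature_ids, per_fold=np.vstack(rows), catalog=table.catalog
    )


RankingLike = "ImportanceTable | Sequence[str]"


def _as_ranked_ids(ranking, catalog: FeatureCatalog) -> list[str]:
    """Accept an ImportanceTable or an ordered list of ids/names."""
    if isinstance(ranking, ImportanceTable):
        return ranking.ranking
    return [catalog.resolve(tok) for tok in ranking]


def build_fi_set(
    rank_m1,
    rank_m2,
    rank_m3,
    top_m1: int = 10,
    top_m2: int = 10,
    top_m3: int = 15,
    catalog: FeatureCatalog | None = None,
    name: str = "FI",
) -> FeatureSet:
    """FI = (top15(M3) ∩ top10(M1)) ∪ (top15(M3) ∩ top10(M2)).

    Rankings may be :class:`ImportanceTable` objects or ordered feature
    name/id lists (names are matched case/hyphen-insensitively).  The
    result is ordered by M3 rank and the provenance records both
    intersections.
    """
    catalog = catalog or FeatureCatalog.default()
    ids1 = _as_ranked_ids(rank_m1, catalog)
    ids2 = _as_ranked_ids(rank_m2, catalog)
    ids3 = _as_ranked_ids(rank_m3, catalog)
    for ids, k, label in ((ids1, top_m1, "M1"), (ids2, top_m2, "M2"), (ids3, top_m3, "M3")):
        if k > len(ids):
            raise ValueError(f"top-{k} exceeds the {label} ranking length {len(ids)}")
    t3 = ids3[:top_m3]
    inter_m1 = [f for f in t3 if f in set(ids1[:top_m1])]
    inter_m2 = [f for f in t3 if f in set(ids2[:top_m2])]
    union = [f for f in t3 if f in set(inter_m1) | set(inter_m2)]
    return FeatureSet(
        name=name,
        members=tuple(union),
        provenance={
            "construction": "union of (top15 M3 ∩ top10 M1) and (top15 M3 ∩ top10 M2), M3 rank order",
            "m1_m3_intersection": [catalog.name_of(f) for f in inter_m1],
            "m2_m3_intersection": [catalog.name_of(f) for f in inter_m2],
            "m1_m3_intersection_size": len(inter_m1),
            "m2_m3_intersection_size": len(inter_m2),
            "union_size": len(union),
        },
    )


def best_prefix_search(
    ranking,
    table: ClinicalTable,
    spec: LearnerSpec = LearnerSpec.rf(),
    max_k: int = 15,
    metric: Literal["auc", "acc"] = "auc",
    folds: int = 5,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[FeatureSet, list[tuple[int, float]]]:
    """Sweep top-k prefixes of a ranking and keep the best one.

    For each k = 1..max_k the full sub-balanced pipeline is evaluated by
    ``folds``-fold CV on the top-k features; the chosen k maximizes the
    metric, ties to the smaller k.  With ``exhaustive=True`` (allowed
    for max_k <= 12) every non-empty subset of the top-``max_k``
    features is tried instead, as a brute-force oracle.

    Returns the selected :class:`FeatureSet` and the metric trace
    ``[(k, value), ...]`` (for exhaustive mode the trace enumerates
    subsets as ``(len(subset), value)``).
    """
    from .metrics import cross_validate  # local import: avoid cycle

    catalog = table.catalog
    ranked = _as_ranked_ids(ranking, catalog)
    if max_k > len(ranked):
        raise ValueError(f"max_k={max_k} exceeds ranking length {len(ranked)}")

    def _score(feature_ids: Sequence[str]) -> float:
        sub = table.take_features(feature_ids)
        rep = cross_validate(sub, folds=folds, seed=seed, learner=spec)
        val = getattr(rep, metric)
        if val is None:
            raise ValueError(f"metric {metric} undefined on a fold")
        return float(val)

    if exhaustive:
        from itertools import combinations

        if max_k > 12:
            raise ValueError("exhaustive mode limited to max_k <= 12")
        pool = ranked[:max_k]
        best_set, best_val, trace = None, -np.inf, []
        for size in range(1, len(pool) + 1):
            for comb in combinations(pool, size):
                val = _score(comb)
                trace.append((size, val))
                if val > best_val:
                    best_set, best_val = comb, val
        return (
            FeatureSet(
                name=f"FC_exhaustive_{max_k}",
                members=tuple(best_set),
                provenance={"mode": "exhaustive", "metric": metric, "best": best_val},
            ),
            trace,
        )

    trace: list[tuple[int, float]] = []
    best_k, best_val = None, -np.inf
    for k in range(1, max_k + 1):
        val = _score(ranked[:k])
        trace.append((k, val))
        if val > best_val:  # strict: ties keep the smaller k
            best_k, best_val = k, val
    return (
        FeatureSet(
            name=f"FC_{max_k}",
            members=tuple(ranked[:best_k]),
            provenance={
                "mode": "prefix",
                "metric": metric,
                "selected_k": best_k,
                "best": best_val,
                "trace": trace,
            },
        ),
        trace,
    )
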