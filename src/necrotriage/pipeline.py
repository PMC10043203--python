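"""End-to-end pipeline wiring: filter -> impute -> partition -> ensemble -> metrics.

One master seed drives every stage; per-stage seeds are derived by
hashing the stage name with the master seed so that a single integer in
a config reproduces the whole run.
"""

from __future__ import annotations

import hashlib
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .ensemble import (
    CohortSplit,
    LearnerSpec,
    MajorityPartition,
    VotingEnsemble,
    partition_majority,
    stratified_split,
    train_ensemble,
)
from .filtering import FilterPolicy, FilterReport, filter_cohort
from .impute import ImputationStats, impute_table
from .table import ClassLabel, ClinicalTable

__all__ = ["derive_seed", "FitArtifacts", "fit_and_evaluate", "performance_context"]


@contextmanager
def performance_context():
    """Fast path for bulk runs (many ensembles in one process).

    Enables scikit-learn's trusted-input mode (inputs are validated by
    :class:`~necrotriage.table.ClinicalTable` before they reach any
    estimator) and memoizes per-class estimator parameter names, which
    dominates the cost of constructing thousands of small trees.  Global
    state is restored on exit; results are unchanged, only faster.
    """
    import functools

    import sklearn
    from sklearn.base import BaseEstimator

    original = BaseEstimator.__dict__["_get_param_names"]

    @functools.lru_cache(maxsize=None)
    def _cached(cls):
        return original.__func__(cls)

    BaseEstimator._get_param_names = classmethod(_cached)
    try:
        with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
            yield
    finally:
        BaseEstimator._get_param_names = original


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class FitArtifacts:
    """Everything a single train/evaluate run produced."""

    table: ClinicalTable  # imputed table the ensemble saw
    split: CohortSplit | None
    partition: MajorityPartition
    stats: ImputationStats | None
    ensemble: VotingEnsemble
    filter_report: FilterReport | None
    test_indices: np.ndarray  # includes leftover majority rows
    test_truth: np.ndarray
    test_predicted: np.ndarray
    test_scores: np.ndarray


def fit_and_evaluate(
    table: ClinicalTable,
    seed: int = 0,
    learner: LearnerSpec = LearnerSpec.rf(),
    test_fraction: float = 0.20,
    fusion: Literal["mean_score", "majority_vote"] = "mean_score",
    filter_policy: FilterPolicy | None = None,
    impute_fit_on: Literal["train", "all"] = "train",
    leftover_to_test: bool = True,
    train_indices: Sequence[int] | None = None,
    test_indices: Sequence[int] | None = None,
):
    """Run the full pipeline once and score the held-out rows.

    Either pass explicit ``train_indices``/``test_indices`` (e.g. CV
    folds) or let a stratified ``test_fraction`` hold-out be drawn.
    Imputation statistics are fitted label-blind on the training rows
    (``impute_fit_on="all"`` fits on every row instead) and applied to
    both splits.  Majority training rows left over by the partition are
    appended to the test set rather than discarded.

    Returns ``(MetricsReport, FitArtifacts)``.
    """
    from .metrics import evaluate_predictions  # local import: avoid cycle

    filter_report = None
    if filter_policy is not None:
        table, filter_report = filter_cohort(table, filter_policy)

    split = None
    if train_indices is None or test_indices is None:
        split = stratified_split(table, test_fraction, seed=derive_seed(seed, "split"))
        train_idx, test_idx = split.train_indices, split.test_indices
    else:
        train_idx = np.asarray(train_indices, dtype=int)
        test_idx = np.asarray(test_indices, dtype=int)

    stats = None
    if table.mask.any():
        fit_table = table if impute_fit_on == "all" else table.take_rows(train_idx)
        stats = ImputationStats.fit(fit_table)
        table = impute_table(table, stats, seed=derive_seed(seed, "impute"))

    labels = table.labels
    maj_train = train_idx[labels[train_idx] == ClassLabel.MAJORITY_HERNIA.value]
    min_train = train_idx[labels[train_idx] == ClassLabel.MINORITY_NECROSIS.value]
    partition = partition_majority(
        maj_train.size, min_train.size, seed=derive_seed(seed, "partition")
    )
    ensemble = train_ensemble(
        table,
        partition,
        spec=learner,
        seed=derive_seed(seed, "train"),
        fusion=fusion,
        majority_train_indices=maj_train,
        minority_train_indices=min_train,
    )

    if leftover_to_test and partition.leftover:
        leftover_rows = maj_train[np.asarray(partition.leftover, dtype=int)]
        test_idx = np.concatenate([test_idx, leftover_rows])

    X_test = table.values[test_idx]
    truth = labels[test_idx]
    predicted, scores = ensemble.predict(X_test)
    report = evaluate_predictions(truth, predicted, scores)
    artifacts = FitArtifacts(
        table=table,
        split=split,
        partition=partition,
        stats=stats,
        ensemble=ensemble,
        filter_report=filter_report,
        test_indices=test_idx,
        test_truth=truth,
        test_predicted=predicted,
        test_scores=scores,
    )
    return report, artifacts
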