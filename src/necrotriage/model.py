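"""Model/Results facade over the triage pipeline.

:class:`NecrosisTriageModel` is constructed from a cohort (a
:class:`~necrotriage.table.ClinicalTable` or a pandas DataFrame) plus
the modelling choices — design, base learner, filter policy, hold-out
fraction.  ``fit(seed)`` runs filter -> impute -> partition -> ensemble
-> hold-out evaluation and returns a :class:`NecrosisTriageResults`
carrying the fitted ensemble, the partition record, the hold-out
metrics and a ``summary()`` table; ``predict`` and ``plot_roc`` hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_INCLUDE_AGE_IN, Design, FeatureCatalog
from .ensemble import LearnerSpec
from .filtering import FilterPolicy
from .importance import ImportanceTable, gini_importance
from .metrics import MetricsReport, cross_validate
from .pipeline import FitArtifacts, fit_and_evaluate
from .table import ClinicalTable, select_design

__all__ = ["NecrosisTriageModel", "NecrosisTriageResults"]


class NecrosisTriageModel:
    """Sub-balanced voting-ensemble triage model for one cohort.

    Parameters
    ----------
    table:
        The labelled cohort (missing cells allowed).
    design:
        Panel design: ``"M1"`` (blood routine), ``"M2"`` (liver/kidney)
        or ``"M3"`` (both).
    learner:
        Base-learner recipe for the sub-models (default random forest).
    filter_policy:
        Missing-rate sample-selection rule applied before modelling
        (default: complete majority rows, minority rows < 40% missing).
        Pass ``None`` to skip filtering.
    test_fraction:
        Stratified hold-out fraction (default 0.20).
    features:
        Optional feature subset (ids or names) to restrict to after
        design selection, e.g. an FI or FC_k selection.
    """

    def __init__(
        self,
        table: ClinicalTable,
        design: Design | str = Design.M3,
        learner: LearnerSpec = LearnerSpec.rf(),
        filter_policy: FilterPolicy | None = FilterPolicy(),
        test_fraction: float = 0.20,
        fusion: Literal["mean_score", "majority_vote"] = "mean_score",
        features: Sequence[str] | None = None,
        include_age_in=DEFAULT_INCLUDE_AGE_IN,
        impute_fit_on: Literal["train", "all"] = "train",
    ):
        self.design = Design.coerce(design)
        table = select_design(table, self.design, include_age_in=include_age_in)
        if features is not None:
            ids = [table.catalog.resolve(tok) for tok in features]
            table = table.take_features(ids)
        self.table = table
        self.learner = learner
        self.filter_policy = filter_policy
        self.test_fraction = test_fraction
        self.fusion = fusion
        self.impute_fit_on = impute_fit_on

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        catalog: FeatureCatalog | None = None,
        **kwargs,
    ) -> "NecrosisTriageModel":
        """Build a model from a cohort DataFrame (see ``read_table``)."""
        return cls(ClinicalTable.from_dataframe(df, catalog=catalog), **kwargs)

    def fit(self, seed: int = 0) -> "NecrosisTriageResults":
        """Run the pipeline once; returns the results object."""
        report, artifacts = fit_and_evaluate(
            self.table,
            seed=seed,
            learner=self.learner,
            test_fraction=self.test_fraction,
            fusion=self.fusion,
            filter_policy=self.filter_policy,
            impute_fit_on=self.impute_fit_on,
        )
        return NecrosisTriageResults(model=self, seed=seed, holdout=report, artifacts=artifacts)

    def cross_validate(self, folds: int = 5, seed: int = 0) -> MetricsReport:
        """Stratified k-fold CV of the full pipeline (stability check)."""
        table = self.table
        if self.filter_policy is not None:
            from .filtering import filter_cohort

            table, _ = filter_cohort(table, self.filter_policy)
        return cross_validate(
            table,
            folds=folds,
            seed=seed,
            learner=self.learner,
            fusion=self.fusion,
            impute_fit_on=self.impute_fit_on,
        )

    def rank_features(self, folds: int = 5, seed: int = 0) -> ImportanceTable:
        """Mean Gini-importance ranking of this model's features."""
        from .filtering import filter_cohort
        from .impute import ImputationStats, impute_table
        from .pipeline import derive_seed

        table = self.table
        if self.filter_policy is not None:
            table, _ = filter_cohort(table, self.filter_policy)
        if table.mask.any():
            stats = ImputationStats.fit(table)
            table = impute_table(table, stats, seed=derive_seed(seed, "impute-rank"))
        return gini_importance(table, LearnerSpec.rf(), folds=folds, seed=seed)


@dataclass
class NecrosisTriageResults:
    """Fitted ensemble plus hold-out evaluation of one pipeline run."""

    model: NecrosisTriageModel
    seed: int
    holdout: MetricsReport
    artifacts: FitArtifacts

    # -- predictions ---------------------------------------------------

    def predict(self, data: ClinicalTable | pd.DataFrame | np.ndarray):
        """Fused labels and minority-class scores for new complete rows."""
        ens = self.artifacts.ensemble
        if isinstance(data, pd.DataFrame):
            missing = [f for f in ens.feature_ids if f not in data.columns]
            if missing:
                raise ValueError(f"prediction data lacks features: {missing}")
            rows = data[list(ens.feature_ids)].to_numpy(dtype=float)
        elif isinstance(data, ClinicalTable):
            rows = data.take_features(ens.feature_ids).dense()
        else:
            rows = np.asarray(data, dtype=float)
        return ens.predict(rows)

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        """Human-readable run summary (counts, partition, metrics)."""
        a = self.artifacts
        h = self.holdout
        part = a.partition
        lines = [
            "Necrosis triage ensemble" + " " * 14 + f"design: {self.model.design.value}",
            "=" * 64,
            f"base learner:        {a.ensemble.learner.algorithm}"
            f"   fusion: {a.ensemble.fusion}   seed: {self.seed}",
            f"features:            {len(a.ensemble.feature_ids)}",
        ]
        if a.filter_report is not None:
            fr = a.filter_report
            lines.append(
                f"filter kept:         {fr.kept_majority} majority, {fr.kept_minority} minority"
                f" (dropped {fr.dropped_majority}/{fr.dropped_minority})"
            )
        lines += [
            f"majority partition:  k={part.k} subsets x {part.subset_size} rows"
            f" (+{len(part.leftover)} leftover -> test)",
            f"minority train:      {part.minority_train_count}",
            f"hold-out test rows:  {a.test_indices.size}",
            "-" * 64,
            f"ACC {h.acc:7.4f}   SN {_fmt(h.sn)}   SP {_fmt(h.sp)}   AUC {_fmt(h.auc)}",
            f"({h.orientation})",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        from .plotting import plot_roc

        return plot_roc(self.artifacts.test_truth, self.artifacts.test_scores, ax=ax)


def _fmt(v: float | None) -> str:
    return "  n/a " if v is None else f"{v:7.4f}"
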