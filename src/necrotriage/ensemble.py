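"""Sub-balanced voting ensembles for the imbalanced two-class cohort.

The imbalance is handled by undersampling-without-waste: after a
stratified 20% hold-out, the majority training rows are shuffled and
partitioned into ``k = floor(N_maj / N_min)`` disjoint subsets of size
``floor(N_maj / k)`` — each "almost equal" to the minority training
count.  Every subset, unioned with the full minority training set,
forms one sub-balanced training set; one base learner (random forest,
SVM or logistic regression) is fitted per subset and the k sub-models
are fused by averaging their minority-class probabilities (or by
majority vote).  Leftover majority rows (< k of them) are not wasted:
the pipeline appends them to the majority test set.

For a logistic-regression base learner the fitted object realizes the
linear score ``y = c0 + sum_i c_i x_i`` squashed through the sigmoid
``L = 1 / (1 + exp(-y))``; the SVM and random-forest learners are the
standard maximum-margin and bagged-tree classifiers.  Hyperparameter
defaults: RF 200 trees / Gini impurity / min_samples_split 2 /
min_samples_leaf 1 / sqrt features per split; SVM C=1, RBF gamma
"scale"; LR tol 1e-4, C=1, max_iter 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .table import ClassLabel, ClinicalTable

__all__ = [
    "round_half_up",
    "CohortSplit",
    "stratified_split",
    "MajorityPartition",
    "partition_majority",
    "LearnerSpec",
    "VotingEnsemble",
    "train_ensemble",
]

#: integer class codes used for the sklearn estimators
MINORITY_CODE = 1
MAJORITY_CODE = 0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# stratified hold-out
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSplit:
    """Index sets of a stratified train/test hold-out."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    seed: int

    @property
    def n_train(self) -> int:
        return self.train_indices.size

    @property
    def n_test(self) -> int:
        return self.test_indices.size


def stratified_split(table: ClinicalTable, test_fraction: float = 0.20, seed: int = 0) -> CohortSplit:
    """Per-class random hold-out with half-up rounding of train counts.

    For each class, ``round_half_up((1 - test_fraction) * N_class)``
    rows go to training and the rest to test; membership is a seeded
    shuffle.  With 121 minority rows and a 20% hold-out this yields the
    97/24 split; with 163 rows, 130/33.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must lie in [0, 1)")
    counts = table.class_counts()
    for cls, n in counts.items():
        if n == 0:
            raise ValueError(f"class {cls.value} has no samples")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in ClassLabel:  # fixed class order for determinism
        idx = table.indices_of(cls)
        perm = rng.permutation(idx)
        n_train = round_half_up((1.0 - test_fraction) * idx.size)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return CohortSplit(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        test_fraction=test_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# majority partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MajorityPartition:
    """Disjoint minority-sized subsets of the majority training rows.

    ``subsets[i]`` are positions into the majority training block
    (0 .. N_maj_train-1); ``leftover`` holds the < k unassigned
    positions.  ``k = floor(N_maj / N_min)`` and
    ``subset_size = floor(N_maj / k)``.
    """

    subsets: tuple[tuple[int, ...], ...]
    leftover: tuple[int, ...]
    minority_train_count: int
    seed: int

    @property
    def k(self) -> int:
        return len(self.subsets)

    @property
    def subset_size(self) -> int:
        return len(self.subsets[0]) if self.subsets else 0

    @property
    def majority_train_count(self) -> int:
        return self.k * self.subset_size + len(self.leftover)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "subset_size": self.subset_size,
            "leftover": list(self.leftover),
            "subsets": [list(s) for s in self.subsets],
            "minority_train_count": self.minority_train_count,
            "seed": self.seed,
        }


def partition_majority(
    majority_train_count: int, minority_train_count: int, seed: int = 0
) -> MajorityPartition:
    """Shuffle and cut the majority training rows into k subsets.

    With 1906 majority and 97 minority training rows this reproduces the
    19 subsets of 100 with 6 leftover; with 654 and 130, the 5 subsets
    of 130 with 4 leftover.
    """
    if minority_train_count < 1:
        raise ValueError("minority_train_count must be >= 1")
    if majority_train_count < minority_train_count:
        raise ValueError("majority_train_count must be >= minority_train_count")
    k = majority_train_count // minority_train_count
    subset_size = majority_train_count // k
    rng = np.random.default_rng(seed)
    perm = rng.permutation(majority_train_count)
    subsets = tuple(
        tuple(int(v) for v in perm[i * subset_size : (i + 1) * subset_size]) for i in range(k)
    )
    leftover = tuple(int(v) for v in perm[k * subset_size :])
    return MajorityPartition(
        subsets=subsets,
        leftover=leftover,
        minority_train_count=minority_train_count,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

_RF_DEFAULTS = dict(
    n_estimators=200,
    criterion="gini",
    min_samples_split=2,
    min_samples_leaf=1,
    max_features="sqrt",  # historical "auto" for classifiers
)
_SVM_DEFAULTS = dict(C=1.0, gamma="scale", kernel="rbf")
_LR_DEFAULTS = dict(tol=1e-4, C=1.0, max_iter=100)


@dataclass(frozen=True)
class LearnerSpec:
    """A base-learner recipe: algorithm name plus hyperparameters.

    ``standardize`` controls whether features are z-scored (fitted on
    the training rows) before the estimator; it defaults to True for the
    scale-sensitive svm/lr learners and False for rf.
    """

    algorithm: Literal["rf", "svm", "lr"] = "rf"
    hyperparameters: dict = field(default_factory=dict)
    standardize: bool | None = None

    def __post_init__(self):
        if self.algorithm not in ("rf", "svm", "lr"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def standardize_effective(self) -> bool:
        if self.standardize is not None:
            return self.standardize
        return self.algorithm in ("svm", "lr")

    @classmethod
    def rf(cls, **overrides) -> "LearnerSpec":
        return cls("rf", overrides)

    @classmethod
    def svm(cls, **overrides) -> "LearnerSpec":
        return cls("svm", overrides)

    @classmethod
    def lr(cls, **overrides) -> "LearnerSpec":
        return cls("lr", overrides)

    def make_estimator(self, seed: int):
        """A fresh (unfitted) sklearn estimator for one sub-model."""
        if self.algorithm == "rf":
            params = {**_RF_DEFAULTS, **self.hyperparameters}
            est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        elif self.algorithm == "svm":
            params = {**_SVM_DEFAULTS, **self.hyperparameters}
            est = SVC(random_state=seed, probability=True, **params)
        else:
            params = {**_LR_DEFAULTS, **self.hyperparameters}
            est = LogisticRegression(**params)
        if self.standardize_effective:
            return Pipeline([("scale", StandardScaler()), ("clf", est)])
        return est


# ---------------------------------------------------------------------------
# voting ensemble
# ---------------------------------------------------------------------------


@dataclass
class VotingEnsemble:
    """k sub-models fused by mean minority-probability or majority vote.

    Scores are always oriented as the probability of the minority
    (necrosis) class.  Exact ties — mean score exactly at the threshold,
    or an even vote split — go to the minority class, because missing a
    necrosis is the costly clinical error.
    """

    sub_models: list
    feature_ids: tuple[str, ...]
    fusion: Literal["mean_score", "majority_vote"] = "mean_score"
    threshold: float = 0.5
    learner: LearnerSpec = field(default_factory=LearnerSpec.rf)

    @property
    def k(self) -> int:
        return len(self.sub_models)

    def _check_rows(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        if rows.ndim == 1:
            rows = rows[None, :]
        if rows.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"feature-count mismatch: ensemble expects {len(self.feature_ids)}, got {rows.shape[1]}"
            )
        if np.isnan(rows).any():
            raise ValueError("prediction rows must be complete (no missing values)")
        return rows

    def sub_model_scores(self, rows: np.ndarray) -> np.ndarray:
        """(n_rows, k) matrix of per-sub-model minority probabilities."""
        rows = self._check_rows(rows)
        cols = []
        for mdl in self.sub_models:
            proba = mdl.predict_proba(rows)
            j = list(mdl.classes_).index(MINORITY_CODE)
            cols.append(proba[:, j])
        return np.column_stack(cols)

    def predict_scores(self, rows: np.ndarray) -> np.ndarray:
        """Fused minority-class score per row.

        Mean-score fusion averages sub-model probabilities; majority-vote
        fusion scores each row by the fraction of sub-models voting
        minority (an AUC-compatible score for hard voting).
        """
        per_model = self.sub_model_scores(rows)
        if self.fusion == "mean_score":
            return per_model.mean(axis=1)
        return (per_model >= self.threshold).mean(axis=1)

    def predict(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fused labels and scores; ties resolve to the minority class."""
        scores = self.predict_scores(rows)
        if self.fusion == "mean_score":
            is_minority = scores >= self.threshold
        else:
            votes = (self.sub_model_scores(rows) >= self.threshold).sum(axis=1)
            # strictly more than half of k votes, or an exact tie
            is_minority = votes * 2 >= self.k
        labels = np.array(
            [
                ClassLabel.MINORITY_NECROSIS if b else ClassLabel.MAJORITY_HERNIA
                for b in is_minority
            ],
            dtype=object,
        )
        return labels, scores

    # -- persistence ---------------------------------------------------

    ARCHIVE_VERSION = 1

    def save(self, path) -> None:
        """Serialize the trained ensemble (sub-models, learner spec,
        feature list, fusion rule) to a versioned archive."""
        import pickle

        payload = {
            "format": "necrotriage-ensemble",
            "version": self.ARCHIVE_VERSION,
            "feature_ids": self.feature_ids,
            "fusion": self.fusion,
            "threshold": self.threshold,
            "learner": self.learner,
            "sub_models": self.sub_models,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "VotingEnsemble":
        import pickle

        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if not isinstance(payload, dict) or payload.get("format") != "necrotriage-ensemble":
            raise ValueError("not a necrotriage ensemble archive")
        if payload.get("version") != cls.ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {payload.get('version')}")
        return cls(
            sub_models=payload["sub_models"],
            feature_ids=tuple(payload["feature_ids"]),
            fusion=payload["fusion"],
            threshold=payload["threshold"],
            learner=payload["learner"],
        )


def train_ensemble(
    table: ClinicalTable,
    partition: MajorityPartition,
    spec: LearnerSpec = LearnerSpec.rf(),
    seed: int = 0,
    fusion: Literal["mean_score", "majority_vote"] = "mean_score",
    majority_train_indices: Sequence[int] | None = None,
    minority_train_indices: Sequence[int] | None = None,
) -> VotingEnsemble:
    """Fit one sub-model per majority subset on S_maj_i ∪ S_min.

    ``majority_train_indices`` / ``minority_train_indices`` map the
    partition's positional indices onto rows of ``table``; by default
    they are the table's majority and minority rows in order (i.e. the
    table *is* the training split).  The table must be fully imputed.
    """
    if table.mask.any():
        raise ValueError("training table has masked cells; impute first")
    maj_idx = (
        np.asarray(majority_train_indices, dtype=int)
        if majority_train_indices is not None
        else table.indices_of(ClassLabel.MAJORITY_HERNIA)
    )
    min_idx = (
        np.asarray(minority_train_indices, dtype=int)
        if minority_train_indices is not None
        else table.indices_of(ClassLabel.MINORITY_NECROSIS)
    )
    if partition.majority_train_count != maj_idx.size:
        raise ValueError("partition does not match the majority training rows")
    if partition.minority_train_count != min_idx.size:
        raise ValueError("partition does not match the minority training rows")
    X = table.values
    minority_X = X[min_idx]
    sub_models = []
    rng = np.random.default_rng(seed)
    for i, subset in enumerate(partition.subsets):
        if not subset:
            raise ValueError("empty majority subset")
        rows_maj = X[maj_idx[np.asarray(subset, dtype=int)]]
        Xi = np.vstack([rows_maj, minority_X])
        yi = np.concatenate(
            [np.full(len(subset), MAJORITY_CODE), np.full(min_idx.size, MINORITY_CODE)]
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        mdl = spec.make_estimator(sub_seed)
        mdl.fit(Xi, yi)
        sub_models.append(mdl)
    return VotingEnsemble(
        sub_models=sub_models,
        feature_ids=table.feature_ids,
        fusion=fusion,
        learner=spec,
    )
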