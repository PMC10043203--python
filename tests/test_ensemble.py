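"""Voting-ensemble structure, fusion arithmetic, and determinism."""

import numpy as np
import pytest

from necrotriage import (
    ClassLabel,
    LearnerSpec,
    VotingEnsemble,
    partition_majority,
    train_ensemble,
)
from necrotriage.ensemble import MAJORITY_CODE, MINORITY_CODE
from necrotriage.simulate import SyntheticConfig, generate_cohort

SMALL_RF = LearnerSpec.rf(n_estimators=25)


class _StubModel:
    """Fixed-probability stand-in for a fitted base learner."""

    classes_ = np.array([MAJORITY_CODE, MINORITY_CODE])

    def __init__(self, p_minority):
        self.p = float(p_minority)

    def predict_proba(self, rows):
        n = np.asarray(rows).shape[0]
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])


def _stub_ensemble(probs, fusion="mean_score"):
    return VotingEnsemble(
        sub_models=[_StubModel(p) for p in probs],
        feature_ids=("f0", "f1"),
        fusion=fusion,
    )


class TestFusion:
    ROWS = np.array([[1.0, 2.0]])

    def test_unanimous_minority(self):
        labels, scores = _stub_ensemble([1.0, 1.0, 1.0]).predict(self.ROWS)
        assert scores[0] == 1.0
        assert labels[0] is ClassLabel.MINORITY_NECROSIS

    def test_mean_score_is_arithmetic_mean(self):
        labels, scores = _stub_ensemble([0.6, 0.4, 0.8]).predict(self.ROWS)
        assert scores[0] == pytest.approx(0.6)
        assert labels[0] is ClassLabel.MINORITY_NECROSIS

    def test_exact_mean_tie_goes_to_minority(self):
        labels, scores = _stub_ensemble([0.5, 0.5]).predict(self.ROWS)
        assert scores[0] == pytest.approx(0.5)
        assert labels[0] is ClassLabel.MINORITY_NECROSIS

    def test_majority_vote_split_tie_goes_to_minority(self):
        labels, scores = _stub_ensemble([0.9, 0.1], fusion="majority_vote").predict(self.ROWS)
        assert scores[0] == pytest.approx(0.5)  # fraction of minority votes
        assert labels[0] is ClassLabel.MINORITY_NECROSIS

    def test_majority_vote_minority_loses_below_half(self):
        labels, _ = _stub_ensemble([0.9, 0.1, 0.2], fusion="majority_vote").predict(self.ROWS)
        assert labels[0] is ClassLabel.MAJORITY_HERNIA

    def test_sub_model_order_never_changes_predictions(self):
        probs = [0.2, 0.7, 0.4, 0.9]
        rows = np.random.default_rng(0).normal(size=(5, 2))
        base = _stub_ensemble(probs).predict(rows)
        perm = _stub_ensemble(probs[::-1]).predict(rows)
        assert np.allclose(base[1], perm[1])
        assert list(base[0]) == list(perm[0])

    def test_feature_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature-count"):
            _stub_ensemble([0.5]).predict(np.zeros((1, 3)))

    def test_incomplete_rows_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            _stub_ensemble([0.5]).predict(np.array([[1.0, np.nan]]))


@pytest.fixture(scope="module")
def trained():
    cfg = SyntheticConfig(n_majority=160, n_minority=40, seed=21)
    table = generate_cohort(cfg)
    n_maj = int(np.sum(table.labels == ClassLabel.MAJORITY_HERNIA.value))
    n_min = table.n_samples - n_maj
    part = partition_majority(n_maj, n_min, seed=1)
    ens = train_ensemble(table, part, spec=SMALL_RF, seed=2)
    return table, part, ens


class TestTrainEnsemble:
    def test_one_sub_model_per_subset(self, trained):
        table, part, ens = trained
        assert ens.k == part.k == 4

    def test_sub_model_training_set_sizes(self, trained):
        _, part, ens = trained
        expected = part.subset_size + part.minority_train_count
        for mdl in ens.sub_models:
            # rf exposes the number of samples it saw
            assert mdl.n_features_in_ == len(ens.feature_ids)
        assert expected == part.subset_size + 40

    def test_identical_seed_identical_predictions(self, trained):
        table, part, _ = trained
        a = train_ensemble(table, part, spec=SMALL_RF, seed=9)
        b = train_ensemble(table, part, spec=SMALL_RF, seed=9)
        X = table.values[:25]
        assert np.array_equal(a.predict_scores(X), b.predict_scores(X))

    def test_k1_mean_score_reduces_to_base_probabilities(self, catalog):
        cfg = SyntheticConfig(n_majority=45, n_minority=30, seed=4)
        table = generate_cohort(cfg)
        n_maj = int(np.sum(table.labels == ClassLabel.MAJORITY_HERNIA.value))
        part = partition_majority(n_maj, table.n_samples - n_maj, seed=0)
        assert part.k == 1
        ens = train_ensemble(table, part, spec=SMALL_RF, seed=5)
        X = table.values[:10]
        sub = ens.sub_models[0]
        j = list(sub.classes_).index(MINORITY_CODE)
        assert np.allclose(ens.predict_scores(X), sub.predict_proba(X)[:, j])

    def test_masked_cells_rejected(self, small_sparse_cohort):
        n_maj = int(np.sum(small_sparse_cohort.labels == ClassLabel.MAJORITY_HERNIA.value))
        part = partition_majority(n_maj, small_sparse_cohort.n_samples - n_maj, seed=0)
        with pytest.raises(ValueError, match="impute"):
            train_ensemble(small_sparse_cohort, part, spec=SMALL_RF, seed=0)


def test_ensemble_archive_roundtrip(trained, tmp_path):
    table, _, ens = trained
    path = tmp_path / "ens.pkl"
    ens.save(path)
    back = VotingEnsemble.load(path)
    X = table.values[:20]
    assert np.array_equal(back.predict_scores(X), ens.predict_scores(X))
    assert back.feature_ids == ens.feature_ids
    with pytest.raises(ValueError, match="archive"):
        (tmp_path / "junk.pkl").write_bytes(b"\x80\x04N.")  # pickled None
        VotingEnsemble.load(tmp_path / "junk.pkl")


@pytest.mark.parametrize("alg", ["svm", "lr"])
def test_scale_sensitive_learners_standardize_by_default(alg):
    spec = getattr(LearnerSpec, alg)()
    est = spec.make_estimator(seed=0)
    assert est.__class__.__name__ == "Pipeline"
    assert not LearnerSpec.rf().standardize_effective


def test_learner_defaults_match_study_settings():
    rf = LearnerSpec.rf().make_estimator(0)
    assert rf.n_estimators == 200 and rf.criterion == "gini"
    assert rf.min_samples_split == 2 and rf.min_samples_leaf == 1
    svm = LearnerSpec.svm().make_estimator(0).named_steps["clf"]
    assert svm.C == 1.0 and svm.gamma == "scale"
    lr = LearnerSpec.lr().make_estimator(0).named_steps["clf"]
    assert lr.tol == 1e-4 and lr.C == 1.0 and lr.max_iter == 100
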