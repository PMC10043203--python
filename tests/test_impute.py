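"""RIN-3M imputation: statistics, envelope, determinism, distribution."""

import numpy as np
import pytest
from scipy.stats import kstest

from necrotriage import ImputationStats, feature_stats, impute_table, rin3m_value
from necrotriage.simulate import SyntheticConfig, generate_cohort, inject_missingness

from conftest import make_table


class TestFeatureStats:
    def test_symmetric_sample(self):
        assert feature_stats([1, 2, 2, 3]) == (2.0, 2.0, 2.0)

    def test_skewed_sample(self):
        m, n, p = feature_stats([1, 1, 2, 3, 13])
        assert (m, n, p) == (1.0, 4.0, 2.0)

    def test_bimodal_tie_goes_to_candidate_closest_to_median_then_smaller(self):
        # [1, 1, 2, 2]: median 1.5, both modes equidistant -> smaller wins
        m, _, p = feature_stats([1, 1, 2, 2])
        assert p == 1.5
        assert m == 1.0

    def test_tie_broken_by_median_proximity(self):
        # modes 1 and 10 tie on count; median 5.5 -> 1 is closer? no: |1-5.5|=4.5, |10-5.5|=4.5 -> smaller
        m, _, _ = feature_stats([1, 1, 10, 10])
        assert m == 1.0
        # modes 2 and 10, median 6.0 -> 2 is equidistant? |2-6|=4, |10-6|=4 -> smaller
        m2, _, _ = feature_stats([2, 2, 4, 8, 10, 10])
        assert m2 == 2.0
        # clear proximity case: modes 4 and 10, median 5 -> 4 closer
        m3, _, _ = feature_stats([4, 4, 5, 6, 10, 10])
        assert m3 == 4.0

    def test_mode_uses_recorded_precision(self):
        # at precision 1 the cluster 2.04, 2.01 collapses onto 2.0
        m, _, _ = feature_stats([2.04, 2.01, 3.4, 5.0], precision=1)
        assert m == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            feature_stats([])


class TestRin3mValue:
    def test_degenerate_envelope(self):
        for rv in (0.0, 0.3, 0.999):
            assert rin3m_value(5, 5, 5, rv) == 5.0

    def test_lower_bound_at_rv_zero(self):
        assert rin3m_value(2, 4, 3, 0.0) == 2.0

    def test_midpoint(self):
        assert rin3m_value(2, 4, 3, 0.5) == 3.0

    def test_rv_outside_unit_interval_rejected(self):
        for rv in (-0.01, 1.0, 1.5):
            with pytest.raises(ValueError):
                rin3m_value(2, 4, 3, rv)


class TestImputeTable:
    def _sparse(self, catalog, seed=5):
        cfg = SyntheticConfig(
            n_majority=40, n_minority=20, minority_cell_missing_rate=0.3,
            majority_cell_missing_rate=0.1, seed=seed,
        )
        return inject_missingness(generate_cohort(cfg), cfg)

    def test_no_masked_cells_is_identity(self, small_cohort):
        stats = ImputationStats.fit(small_cohort)
        out = impute_table(small_cohort, stats, seed=1)
        assert np.array_equal(out.values, small_cohort.values)

    def test_collapsed_envelope_equals_mean_imputation(self, catalog):
        t = make_table([[7.0, 1.0], [np.nan, 2.0], [7.0, 3.0]], ["hernia", "necrosis", "hernia"], catalog)
        stats = ImputationStats.fit(t)
        assert stats.triples["f0"] == (7.0, 7.0, 7.0)
        for seed in (0, 1, 99):
            out = impute_table(t, stats, seed=seed)
            assert out.values[1, 0] == 7.0

    def test_determinism_and_seed_sensitivity(self, catalog):
        t = self._sparse(catalog)
        stats = ImputationStats.fit(t)
        a = impute_table(t, stats, seed=42)
        b = impute_table(t, stats, seed=42)
        c = impute_table(t, stats, seed=43)
        assert np.array_equal(a.values, b.values)
        assert not a.mask.any()
        # different seeds differ only at the originally masked positions
        assert np.array_equal(a.values[~t.mask], c.values[~t.mask])
        assert not np.array_equal(a.values[t.mask], c.values[t.mask])

    def test_every_imputed_value_inside_envelope(self, catalog):
        t = self._sparse(catalog, seed=9)
        stats = ImputationStats.fit(t)
        out = impute_table(t, stats, seed=7)
        rows, cols = np.nonzero(t.mask)
        for r, c in zip(rows, cols):
            lo, hi = stats.envelope(t.feature_ids[c])
            assert lo <= out.values[r, c] <= hi
            if hi > lo:
                assert out.values[r, c] < hi  # rv < 1 keeps the top open

    def test_observed_cells_untouched(self, catalog):
        t = self._sparse(catalog, seed=3)
        stats = ImputationStats.fit(t)
        out = impute_table(t, stats, seed=0)
        assert np.array_equal(out.values[~t.mask], t.values[~t.mask])

    def test_missing_stats_for_masked_feature_rejected(self, catalog):
        t = make_table([[1.0, np.nan], [2.0, np.nan]], ["hernia", "necrosis"], catalog)
        # f1 has no observed values at all -> no stats -> impute must fail
        stats = ImputationStats.fit(t)
        assert "f1" not in stats.triples
        with pytest.raises(ValueError, match="f1"):
            impute_table(t, stats, seed=0)

    def test_repeated_imputation_of_one_cell_is_uniform_on_envelope(self, catalog):
        t = make_table([[1.0], [2.0], [6.0], [np.nan]], ["hernia", "hernia", "hernia", "necrosis"], catalog)
        stats = ImputationStats.fit(t)
        lo, hi = stats.envelope("f0")
        # observed [1, 2, 6]: mode 2 (all counts tie; 2 is the median itself),
        # mean 3, median 2 -> envelope [2, 3]
        assert (lo, hi) == (2.0, 3.0)
        draws = np.array([impute_table(t, stats, seed=s).values[3, 0] for s in range(400)])
        stat = kstest((draws - lo) / (hi - lo), "uniform").pvalue
        assert stat > 0.01


def test_stats_roundtrip_json(tmp_path, small_sparse_cohort):
    stats = ImputationStats.fit(small_sparse_cohort)
    p = tmp_path / "stats.json"
    stats.to_json(p)
    back = ImputationStats.from_json(p)
    assert back.triples == {k: tuple(v) for k, v in stats.triples.items()}
    assert back.n_fit == stats.n_fit
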