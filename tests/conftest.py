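import numpy as np
import pytest

from necrotriage import (
    ClassLabel,
    ClinicalTable,
    FeatureCatalog,
    SyntheticConfig,
    generate_cohort,
    inject_missingness,
)


@pytest.fixture(scope="session")
def catalog() -> FeatureCatalog:
    return FeatureCatalog.default()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small cohort for structural tests: mild imbalance, k ~ 5."""
    return SyntheticConfig(n_majority=260, n_minority=50, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> ClinicalTable:
    """Complete (no missingness) small synthetic cohort."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_sparse_cohort(small_config) -> ClinicalTable:
    return inject_missingness(generate_cohort(small_config), small_config)


def make_table(
    values,
    labels,
    catalog,
    feature_ids=None,
    mask=None,
):
    """Hand-build a ClinicalTable from plain lists (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = tuple(catalog.feature_ids[: values.shape[1]])
    if mask is None:
        mask = np.isnan(values)
    return ClinicalTable(
        values=values,
        mask=np.asarray(mask, dtype=bool),
        labels=np.array([ClassLabel.coerce(l) for l in labels], dtype=object),
        feature_ids=tuple(feature_ids),
        catalog=catalog,
    )


@pytest.fixture
def tiny_table(catalog):
    """4 rows x 3 features, one masked cell, both classes."""
    vals = [
        [1.0, 2.0, 3.0],
        [4.0, np.nan, 6.0],
        [7.0, 8.0, 9.0],
        [1.5, 2.5, 3.5],
    ]
    return make_table(vals, ["hernia", "hernia", "necrosis", "necrosis"], catalog)
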