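import numpy as np
import pytest

from cohortnet import preprocess, synthetic
from cohortnet.cohort import CohortTable, MeasureDefinition


def make_table(values, missing=None, names=None):
    """Small cohort table around a plain value matrix (unit test helper)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    if names is None:
        names = [f"m{j}" for j in range(p)]
    measures = [
        MeasureDefinition(name=nm, category="cognition", scale_min=-1e9, scale_max=1e9)
        for nm in names
    ]
    safe_values = np.where(missing, 0.0, values)
    return CohortTable(
        child_ids=[f"c{i}" for i in range(n)],
        measures=measures,
        values=safe_values,
        missing_mask=np.asarray(missing, dtype=bool),
    )


@pytest.fixture(scope="session")
def table2_spec():
    return synthetic.spec_from_table2()


@pytest.fixture(scope="session")
def cohort519():
    """One seeded 519-child synthetic cohort with realistic missingness."""
    spec = synthetic.spec_from_table2(seed=20210904)
    table, factors = synthetic.generate_factor_cohort(spec)
    return table, factors


@pytest.fixture(scope="session")
def z519(cohort519):
    """The 519-child cohort after exclusion, standardisation and imputation."""
    table, _ = cohort519
    kept, _ = preprocess.exclude_high_missingness(table)
    z = preprocess.standardize(kept)
    return preprocess.impute_knn(z, k=9)
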