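import pytest
from hypothesis import settings

from ttnvar.io import packaged_cohort_path, read_variant_table

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort_genotypes():
    """Patient genotypes from the packaged cohort fixture."""
    genotypes, errors = read_variant_table(packaged_cohort_path())
    assert not errors
    return genotypes


@pytest.fixture(scope="session")
def cohort_rows():
    """Raw fixture rows (one per variant) for annotation-level checks."""
    import pandas as pd

    return pd.read_csv(packaged_cohort_path(), sep="\t", comment="#", dtype=str)
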