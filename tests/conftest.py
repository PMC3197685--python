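import pytest

import clcounts as cc


@pytest.fixture(scope="session")
def one_year_cohort():
    """The reconstructed 1-year patient-level cohort (195 records, 4 arms)."""
    return cc.load_one_year_cohort()


@pytest.fixture(scope="session")
def one_year_comparison(one_year_cohort):
    """All four whole-dataset fits plus pairwise tests, shared across tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cc.compare_all(one_year_cohort, arms=cc.ARM_ORDER)
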