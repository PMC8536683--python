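import warnings

import pytest

from m6apattern import default_config, generate


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=600, three planted subtypes)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(default_config())


@pytest.fixture(scope="session")
def survival_arrays(default_cohort):
    clin = default_cohort.clinical.table
    return clin["os_time"].to_numpy(), clin["os_event"].to_numpy()
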