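import numpy as np
import pytest

import ramanbone as rb


@pytest.fixture(scope="session")
def table1():
    return rb.load_table1()


@pytest.fixture(scope="session")
def table2():
    return rb.load_table2()


@pytest.fixture(scope="session")
def combined():
    return rb.load_combined()


@pytest.fixture(scope="session")
def complete(table1):
    """The 31 complete records: ratio, %N, %C and %collagen all present."""
    return table1.complete_cases()


@pytest.fixture
def noiseless_config():
    """Deterministic spectra: no detector noise, no replicate jitter."""
    return rb.CohortConfig(
        noise_sd=0.0, replicate_jitter_sd=0.0, baseline_coeffs=(0.0,), seed=11
    )


@pytest.fixture
def clean_spectrum(noiseless_config):
    """One noiseless bone spectrum at 1 % collagen, flat baseline."""
    return rb.simulate_spectrum(noiseless_config, collagen_pct=1.0, seed=11)
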