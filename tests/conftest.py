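import numpy as np
import pytest

from multipgs import synthetic_data as sd


@pytest.fixture(scope="session")
def small_panel():
    """2,000 variants in AR(1) blocks of 50 (rho=0.5) — the desk-scale panel."""
    return sd.simulate_panel(2000, 50, rho=0.5, seed=11)


@pytest.fixture(scope="session")
def small_arch(small_panel):
    rg = np.array([[1.0, 0.6, 0.6], [0.6, 1.0, 0.3], [0.6, 0.3, 1.0]])
    return sd.simulate_architecture(small_panel, 3, h2=0.5, rg=rg,
                                    polygenicity=0.05, seed=12)


@pytest.fixture(scope="session")
def small_sumstats(small_panel, small_arch):
    return sd.simulate_sumstats(small_panel, small_arch, 0, 50_000, seed=13)


@pytest.fixture(scope="session")
def small_cohort(small_panel, small_arch):
    return sd.simulate_cohort(small_panel, small_arch, 2000, prevalence=0.2,
                              seed=14)
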