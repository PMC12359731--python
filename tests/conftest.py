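import numpy as np
import pytest

from periradiomics.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small rendered cohort shared across tests (8 MIA + 12 IAC)."""
    spec = CohortSpec(n_mia=8, n_iac=12, seed=42)
    cases, table = simulate_cohort(spec)
    return spec, cases, table


@pytest.fixture(scope="session")
def nodule_case():
    spec = CohortSpec(seed=7)
    from periradiomics.synthetic import simulate_nodule

    return simulate_nodule(spec, "IAC", seed=7)
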