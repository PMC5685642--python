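import numpy as np
import pytest

from tyrokin import (AssayConditions, build_deoxyarbutin_scheme, constant_set,
                     enzyme_split, integrate)


@pytest.fixture(scope="session")
def fig4_params():
    return constant_set("fig4")


@pytest.fixture(scope="session")
def base_scheme(fig4_params):
    return build_deoxyarbutin_scheme(fig4_params)


@pytest.fixture(scope="session")
def fig4b_conditions():
    return AssayConditions({**enzyme_split(1.5e-6), "D-Arb": 0.4e-3,
                            "O2": 0.26e-3, "H2O2": 1.25e-6}, 36000.0)


@pytest.fixture(scope="session")
def short_curve(base_scheme):
    """A 60 s run under rate-assay conditions, reused across tests."""
    cond = AssayConditions({**enzyme_split(3e-7), "D-Arb": 2e-4,
                            "O2": 0.26e-3, "H2O2": 1.25e-6}, 60.0)
    return integrate(base_scheme, cond, grid=2000)


def relerr(a, b):
    return abs(a - b) / abs(b)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
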