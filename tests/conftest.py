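import pytest

import nanofate as nf


@pytest.fixture(scope="session")
def sw_result():
    """Solved SW speciation at the measured pH without sludge (7.7)."""
    return nf.solve_equilibrium(nf.sw_problem(pH=7.7))


@pytest.fixture(scope="session")
def thermo_db():
    return nf.default_thermo_db()
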