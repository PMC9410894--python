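import numpy as np
import pytest

from orf1kin import PRESETS, PolymerParams


@pytest.fixture(scope="session")
def polymer():
    return PolymerParams()


@pytest.fixture(scope="session")
def kin111():
    return PRESETS["111p"].kinetic


@pytest.fixture(scope="session")
def bare_5pN(polymer):
    from orf1kin import bare_extension_per_nt
    return bare_extension_per_nt(5.0, polymer)


@pytest.fixture(scope="session")
def bare_30pN(polymer):
    from orf1kin import bare_extension_per_nt
    return bare_extension_per_nt(30.0, polymer)


def theta_matrix(trace):
    """Stack the occupancy channels of a simulated trace as (n, 3)."""
    return np.column_stack([trace.channels["theta_0"],
                            trace.channels["theta_b"],
                            trace.channels["theta_oligo"]])
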