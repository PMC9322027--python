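import numpy as np
import pytest

from acylmig import MigrationScheme, RateSet, path_a, path_b
from acylmig.datasets import COMPOUND_RATES


@pytest.fixture
def scheme_a() -> MigrationScheme:
    return path_a()


@pytest.fixture
def scheme_b_nohyd() -> MigrationScheme:
    return path_b(hydrolysis=False)


@pytest.fixture
def glc_ac_rates() -> RateSet:
    """Acetyl on Me alpha-D-glucopyranoside (path A)."""
    return COMPOUND_RATES[1]


@pytest.fixture
def two_state_scheme() -> MigrationScheme:
    return MigrationScheme(positions=("A", "B"), hydrolysis=("none", "none"))


@pytest.fixture
def symmetric_rates() -> RateSet:
    return RateSet(k_fwd=(1.0,), k_bwd=(1.0,))


def pack_rates(rates: RateSet, with_primary: bool = False) -> np.ndarray:
    """Flatten a RateSet in fit-parameter order, for truth comparisons."""
    x = [v for pair in zip(rates.k_fwd, rates.k_bwd) for v in pair]
    if rates.k_hyd_secondary or with_primary:
        x.append(rates.k_hyd_secondary)
    if with_primary:
        x.append(
            rates.k_hyd_secondary
            if rates.k_hyd_primary is None
            else rates.k_hyd_primary
        )
    return np.array(x)
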