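import numpy as np
import pytest

from n2otrace.isotope_model import PoolComposition
from n2otrace.rate_estimation import IncubationSeries
from n2otrace.synthetic_data import Scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pool_f038():
    """Pool with atom fraction exactly 0.38."""
    return PoolComposition(62.0, 38.0, "NH4")


@pytest.fixture
def pool_f05():
    return PoolComposition(5.0, 5.0, "NH4")


@pytest.fixture
def noiseless_scenario():
    return Scenario(noise_rel=0.0, noise_floor=0.0, seed=7)


@pytest.fixture
def default_scenario():
    return Scenario(seed=42)


def make_series(
    substrate_label,
    analyte,
    times_h,
    values,
    pool,
    **kwargs,
):
    """Build a single-analyte IncubationSeries from plain lists."""
    return IncubationSeries(
        substrate_label=substrate_label,
        data={analyte: (np.asarray(times_h, float), np.asarray(values, float))},
        pools={pool.species: pool},
        **kwargs,
    )
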