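import numpy as np
import pytest

from aerodisp import CumulativePSD, DispersionCondition, SizeGrid


def make_psd(diameters, values, label="", condition=None):
    return CumulativePSD(
        grid=SizeGrid(np.asarray(diameters, dtype=float)),
        values=np.asarray(values, dtype=float),
        label=label,
        condition=condition,
    )


def random_monotone_cdf(rng, grid):
    """Random non-decreasing curve from 0-ish to 1 on the given grid."""
    steps = rng.random(len(grid))
    values = np.concatenate([[0.0], np.cumsum(steps)])[1:]
    return values / values[-1]


@pytest.fixture
def reference_condition():
    return DispersionCondition(
        formulation="mannitol", disperser="reference", rodos_pressure=3.0
    )


@pytest.fixture
def inhaler_condition():
    return DispersionCondition(
        formulation="mannitol",
        disperser="inhaler",
        device_resistance_class="medium",
        resistance=0.025,
        pressure_drop=2.0,
    )
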