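import numpy as np
import pandas as pd
import pytest

from paleospd.calcurve import CalibrationCurve
from paleospd.spd import SPDSeries
from paleospd.synthetic_data import make_synthetic_curve


@pytest.fixture(scope="session")
def identity_curve0():
    """Identity curve with zero curve error: calibration is exact."""
    return CalibrationCurve.identity((21000, 9000), sigma=0.0)


@pytest.fixture(scope="session")
def identity_curve10():
    return make_synthetic_curve("identity", (21000, 9000), sigma=10.0)


@pytest.fixture(scope="session")
def wiggly_curve():
    """Curve with centennial-scale wiggles, as real curves have."""
    return make_synthetic_curve(
        "wiggly", (21000, 9000), sigma=15.0, wiggle_amp=20.0, wiggle_period=400.0
    )


@pytest.fixture(scope="session")
def three_knot_curve():
    knots = pd.DataFrame(
        {"cal_bp": [10000.0, 15000.0, 20000.0],
         "c14_age": [9000.0, 13000.0, 17000.0],
         "sigma": [20.0, 30.0, 40.0]}
    )
    return CalibrationCurve.from_knots(knots, (20000, 10000), name="three-knot")


def series_from_values(values, oldest=20000):
    values = np.asarray(values, dtype=float)
    grid = np.arange(oldest, oldest - values.size, -1, dtype=np.int64)
    return SPDSeries(cal_bp=grid, values=values, n_dates=1, smoothing_window=1)


@pytest.fixture(scope="session")
def make_series():
    return series_from_values
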