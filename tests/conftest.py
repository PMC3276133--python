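import numpy as np
import pytest

from chemscreen import Condition, ODTimeSeries


def logistic_series(
    f: float,
    d_wt: float = 100.0,
    K: float = 1.0,
    od0: float = 0.05,
    hours: float = 24.0,
    dt: float = 15.0,
    strain: str = "s",
) -> ODTimeSeries:
    """Noiseless logistic growth trace with rate r = f·ln2/d_wt."""
    r = f * np.log(2) / d_wt
    t = np.arange(0, hours * 60 + dt / 2, dt)
    od = od0 * K / (od0 + (K - od0) * np.exp(-r * t))
    return ODTimeSeries(f"w_{strain}", strain, Condition(), t, od)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
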