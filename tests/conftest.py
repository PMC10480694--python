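import numpy as np
import pytest

from rollcall.io import AccelTrace
from rollcall.simulate import PopulationParams, simulate_dive_records


@pytest.fixture
def flat_flight_trace():
    """60 s of level flapping flight at 50 Hz: no dives present."""
    rng = np.random.default_rng(123)
    n = 3000
    t = np.arange(n) / 50.0
    return AccelTrace(
        bird_id="flight",
        t=t,
        x=rng.normal(0.3, 0.2, n),
        y=rng.normal(0.0, 0.05, n),
        z=rng.normal(1.0, 0.05, n),
    )


@pytest.fixture
def small_records():
    """Compact per-dive record set with strong individual side bias."""
    pop = PopulationParams(
        n_birds=12,
        days_per_bird=(2, 2),
        dives_per_bird_day=8.0,
        var_id_logit=6.0,
        var_date_logit=0.2,
        seed=99,
    )
    records, truth = simulate_dive_records(pop)
    return records, truth
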