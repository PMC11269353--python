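import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ligbind.buildup import DEFAULT_EPSILON, DEFAULT_SCHEDULE, SaturationSeries

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_noiseless_series(std_max: float, k_sat: float,
                          schedule=DEFAULT_SCHEDULE,
                          epsilon: float = DEFAULT_EPSILON,
                          proton_id: str = "p1",
                          chemical_shift: float = 7.5,
                          base_intensity: float = 1000.0) -> SaturationSeries:
    """Series whose amplification factors follow the build-up model exactly."""
    t = np.asarray(schedule, dtype=float)
    eta = std_max * (1.0 - np.exp(-k_sat * t))
    i0 = np.full_like(t, base_intensity)
    istd = i0 * (1.0 - eta / epsilon)
    return SaturationSeries(
        ligand_id="L", proton_id=proton_id, chemical_shift=chemical_shift,
        times=tuple(t), I0=tuple(i0), ISTD=tuple(istd), epsilon=epsilon,
    )


@pytest.fixture
def noiseless_series():
    return make_noiseless_series
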