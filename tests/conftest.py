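import numpy as np
import pytest

from sulfid.isotope_core import IsotopeComposition, MassBiasModel, SpikeConfig
from sulfid.signal_io import IsotopeTrace, RunConfig
from sulfid.simulate import SimPeak, SimSpec, simulate_run


@pytest.fixture
def natural():
    return IsotopeComposition.natural()


@pytest.fixture
def spike():
    return SpikeConfig()


@pytest.fixture
def small_trace():
    t = np.linspace(0.0, 10.0, 101)
    return IsotopeTrace(time=t, i32=np.full_like(t, 100.0),
                        i34=np.full_like(t, 50.0), run_id="small")


@pytest.fixture
def run_config():
    """Blank regions framing a peak eluting around t = 60 s."""
    return RunConfig(blank_regions=[(0.0, 30.0), (95.0, 120.0)])


@pytest.fixture
def clean_peak_run():
    """Noise-free single 2.16 ng peak at t = 60 s, no mass bias."""
    spec = SimSpec(duration=120.0, peaks=(SimPeak("std", 2.16, 60.0),),
                   noise="none")
    trace, truth = simulate_run(spec)
    return spec, trace, truth


@pytest.fixture
def identity_bias():
    return MassBiasModel()
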