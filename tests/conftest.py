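import numpy as np
import pytest

from avacrit.models import SpikeRaster, SurrogateParams, simulate_surrogate


@pytest.fixture(scope="session")
def surrogate_raster() -> SpikeRaster:
    """A 20-s intermittent surrogate raster shared across read-only tests."""
    return simulate_surrogate(SurrogateParams(), 20_000.0, seed=42)


def make_raster(times, units, n_units, t_end, t_start=0.0) -> SpikeRaster:
    return SpikeRaster(
        times=np.asarray(times, dtype=float),
        units=np.asarray(units, dtype=int),
        n_units=n_units,
        t_start=t_start,
        t_end=t_end,
    )
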