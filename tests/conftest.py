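import warnings

import numpy as np
import pytest

from bas import (AcquisitionParams, LiposomePopulation, LiposomeSpecies,
                 build_histogram, detect_bursts, simulate_trace)
from bas.pipeline import replace_concentration


@pytest.fixture(autouse=True)
def _quiet_concentration_warnings():
    """Several tests deliberately simulate above the single-particle
    limit; the warning itself is asserted where it matters."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*single-particle limit.*")
        warnings.filterwarnings("ignore", message="no bursts.*")
        yield


def measure_histogram(pop, acq, seed, edges=None, dilution=1.0):
    """Full simulate -> detect -> histogram chain for one population."""
    diluted = replace_concentration(pop, pop.total_concentration / dilution)
    trace = simulate_trace(diluted, acq, seed=seed)
    bursts = detect_bursts(trace)
    return build_histogram(bursts, acq, edges=edges,
                           dilution_factor=dilution)


@pytest.fixture
def mono_200():
    return LiposomePopulation(
        species=(LiposomeSpecies(200.0, 0.35, 100.0),))


@pytest.fixture
def fast_acq():
    return AcquisitionParams(duration=60.0)
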