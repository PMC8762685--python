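import numpy as np
import pytest

from shapevolve import (
    InitConfig,
    RFGenome,
    SynthConfig,
    example_target,
    random_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bb_target():
    """Bumpy-brick-style example target (active at frequencies 2 and 6)."""
    return example_target("BB")


@pytest.fixture
def synth_cfg():
    return SynthConfig()


@pytest.fixture
def genome_factory(rng):
    def make(seed=None, **init_kwargs):
        local = rng if seed is None else np.random.default_rng(seed)
        return random_genome(InitConfig(**init_kwargs), local)

    return make


def make_genome(amps, phases=None, gates=None, id="g"):
    """Build a genome from sparse specs: amps is {freq(1-based): amplitude}."""
    amplitudes = np.zeros(10)
    phase_arr = np.full(10, 90.0)
    gate_arr = np.ones(10, dtype=int)
    if isinstance(amps, dict):
        for f, a in amps.items():
            amplitudes[f - 1] = a
    else:
        amplitudes[:] = amps
    if phases is not None:
        phase_arr[:] = phases
    if gates is not None:
        gate_arr[:] = gates
    return RFGenome(amplitudes=amplitudes, phases=phase_arr, gates=gate_arr, id=id)
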