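import numpy as np
import pytest

from nvsleep.pipeline_io import condition_session
from nvsleep.synthgen import GeneratorConfig, simulate_session

MAIN_SEED = 11


@pytest.fixture()
def rng(request):
    # per-test deterministic stream, independent of execution order
    import zlib

    seed = zlib.crc32(request.node.name.encode()) % 2**31
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def short_config():
    # 6 kHz raw rate: all LFP bands and the EMG band present, MUA omitted
    # (above Nyquist); fast enough for per-module checks
    return GeneratorConfig(seed=21, neural_rate=6000.0)


@pytest.fixture(scope="session")
def short_session(short_config):
    return simulate_session(short_config, 600.0, short_config.seed)


@pytest.fixture(scope="session")
def short_derived(short_session):
    return condition_session(short_session)


@pytest.fixture(scope="session")
def main_config():
    return GeneratorConfig(seed=MAIN_SEED)


@pytest.fixture(scope="session")
def main_session(main_config):
    """One hour at generator defaults (20 kHz raw) — the parameter-recovery
    test bed shared across the suite."""
    return simulate_session(main_config, 3600.0, MAIN_SEED)


@pytest.fixture(scope="session")
def main_derived(main_session):
    return condition_session(main_session)
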