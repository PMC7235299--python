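import pytest

from shorthcr import (
    DesignConfig,
    design_hairpin_pair,
    load_default_parameters,
    synth_transcript,
)


@pytest.fixture(scope="session")
def nn_params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def default_config():
    return DesignConfig()


@pytest.fixture(scope="session")
def designed_pairs():
    """100 designer outputs, seeds 1..100, default config."""
    return [design_hairpin_pair(seed=s) for s in range(1, 101)]


@pytest.fixture(scope="session")
def transcript_2kb():
    """Seeded 2-kb synthetic transcript at 50% GC."""
    return synth_transcript(2000, 0.5, 7).as_target()
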