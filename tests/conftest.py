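import hypothesis
import pytest

from elincnet import SimConfig, simulate
from elincnet.features import build_features

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

SIM_SEED = 3


@pytest.fixture(scope="session")
def sim_result():
    """One default-scale simulated dataset shared across the session."""
    return simulate(SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def sim_features(sim_result):
    return build_features(
        sim_result.transcripts,
        sim_result.tracks,
        chrom_lengths=sim_result.config.chrom_lengths,
    )
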