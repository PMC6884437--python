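import numpy as np
import pytest

from infoload import ChannelMeta, NirsSession, SyntheticSpec, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_channel_session(rng) -> NirsSession:
    """A minimal hand-built 4-channel session: 60 s rest + 70 s task at 10 Hz."""
    samples = rng.standard_normal((1300, 4))
    channels = (
        ChannelMeta("L1", 1.0), ChannelMeta("L3", 3.0),
        ChannelMeta("R1", 1.0), ChannelMeta("R3", 3.0),
    )
    return NirsSession(
        samples=samples, fs=10.0, channels=channels, rest_end_index=600,
        subject_id="t01", condition="one-back",
    )


@pytest.fixture
def synthetic_session() -> NirsSession:
    """A default synthetic session (deterministic seed)."""
    return generate_session(SyntheticSpec(seed=99))
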