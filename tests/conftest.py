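import numpy as np
import pytest

from slurrygas import default_scenario
from slurrygas.kinetics import CardinalParams, MicrobialGroup


@pytest.fixture
def mesophile() -> MicrobialGroup:
    return MicrobialGroup(
        id="meso",
        cardinal=CardinalParams(T_min=10.0, T_opt=37.0, T_max=45.0, rate_opt=7.4),
    )


@pytest.fixture
def short_scenario():
    """Default community, 90-day horizon (three emptying cycles)."""
    return default_scenario(duration=90.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
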