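import pytest

from cellclock import default_curve
from cellclock.methylome_sim import MethylomeSimConfig, generate


@pytest.fixture(scope="session")
def curve():
    return default_curve()


@pytest.fixture(scope="session")
def planted_methylome():
    """Default planted two-group methylome (20+20 samples, 2000 probes,
    5% informative at a 0.2 beta-mean shift) with its ground truth."""
    return generate(MethylomeSimConfig(seed=3))


@pytest.fixture(scope="session")
def strong_methylome():
    """Large-effect planted methylome for stability checks."""
    return generate(MethylomeSimConfig(seed=0, effect_delta=0.3))
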