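import numpy as np
import pytest

from ovosex.backbone import Network, profile_config
from ovosex.synthetic import GeneratorParams, render_egg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_baseline():
    return Network(profile_config("desk", seed=0))


@pytest.fixture(scope="session")
def desk_improved():
    return Network(profile_config("desk", mfe_enabled=True, msaaf_enabled=True,
                                  seed=0))


@pytest.fixture(scope="session")
def egg_sample():
    """One deterministic rendered egg at desk resolution."""
    return render_egg(GeneratorParams(image_size=128, class_effect=0.6), seed=42,
                      label="F")
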