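import numpy as np
import pytest

from somadev.embodiment import (Environment, build_fetus_body,
                                build_insect_body, compiled)


@pytest.fixture(scope="session")
def insect_body():
    return build_insect_body()


@pytest.fixture(scope="session")
def fetus_body():
    return build_fetus_body()


@pytest.fixture(scope="session")
def uterus_env(fetus_body):
    from somadev.experiments.bodymap import fitted_uterus
    return fitted_uterus(fetus_body)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
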