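import numpy as np
import pytest

from supergee.task import TaskConfig


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
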