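import numpy as np
import pytest

from topostats.designs import BetweenDesign, WithinDesign
from topostats.simulate import GenerativeSpec, generate


@pytest.fixture(scope="session")
def within_2x2():
    """Standard 2 x 2 within design: conditions (A0B0, A0B1, A1B0, A1B1)."""
    return WithinDesign(((0, 0), (0, 1), (1, 0), (1, 1)),
                        ("day", "expectancy"))


@pytest.fixture(scope="session")
def within_1f():
    return WithinDesign(((0,), (1,)), ("condition",))


@pytest.fixture(scope="session")
def groups_2():
    return BetweenDesign("categorical", (0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_null_dataset():
    """One pure-noise 12-subject 2x2 dataset at the default toy scale."""
    ds, _ = generate(GenerativeSpec(seed=4242))
    return ds
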