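import numpy as np
import pytest

from feral.fixtures import FixtureScript, make_classification_fixture, make_worm_fixture
from feral.labels import ClassCatalog


@pytest.fixture(scope="session")
def class_fixture():
    """A 3-class separable clip: other / moving blob / orbiting pair."""
    script = FixtureScript(
        schedule=(
            ("other", 0, 40),
            ("blob", 40, 90),
            ("pair", 90, 130),
            ("other", 130, 160),
            ("blob", 160, 200),
        ),
        fps=10.0,
        size=32,
        seed=7,
        video_id="fix1",
    )
    return make_classification_fixture(script)


@pytest.fixture(scope="session")
def worm_fixture():
    return make_worm_fixture(seed=3)


@pytest.fixture
def single_catalog():
    return ClassCatalog(names=("other", "groom", "walk"), mode="single_label")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
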