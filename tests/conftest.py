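import pytest

from soilmp.data_model import (
    Color,
    Matrix,
    ParticleRecord,
    Polymer,
    Season,
    Shape,
)
from soilmp.synthetic import default_config, generate_year


def make_particle(**overrides) -> ParticleRecord:
    """A valid soil fiber with typical survey dimensions."""
    fields = dict(
        matrix=Matrix.SOIL,
        season=Season.SUMMER,
        sample_id="soil-summer-1",
        shape=Shape.FIBER,
        color=Color.BLUE,
        length_um=1321.91,
        width_um=19.89,
        polymer=Polymer.PES,
        confirmed=True,
    )
    fields.update(overrides)
    return ParticleRecord(**fields)


@pytest.fixture(scope="session")
def config():
    return default_config(seed=123)


@pytest.fixture(scope="session")
def dataset(config):
    return generate_year(config)
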