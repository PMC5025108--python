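import numpy as np
import pytest

from spermseg.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A fast-to-segment frame: 8 heads incl. one agglutinated pair."""
    spec = SceneSpec(
        height=160,
        width=200,
        n_heads=8,
        n_debris=3,
        agglutinated_fraction=0.25,
        seed=42,
    )
    return generate_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
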