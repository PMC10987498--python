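import numpy as np
import pytest

from grmdesign import GRM, GeneSpec, RegulationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240402)


def make_backbone(**reporter_kw) -> GRM:
    """Two orthogonal inputs plus one reporter, no regulations."""
    kw = {"production": 0.1, "decay": 0.1}
    kw.update(reporter_kw)
    return GRM(
        genes=[
            GeneSpec("red", "input", orientation="from_top"),
            GeneSpec("green", "input", orientation="from_left"),
            GeneSpec("blue", "reporter", **kw),
        ],
        regulations=[],
        reporter_bindings={"blue": 0},
    )


@pytest.fixture
def minimal_grm() -> GRM:
    return make_backbone()


@pytest.fixture
def square_like_grm() -> GRM:
    """The canonical 4-gene / 5-link design for a square pattern: both
    inputs repress the reporter, both activate a low-threshold
    intermediate 'a' (necessary), and 'a' activates the reporter."""
    g = make_backbone()
    g.genes.append(GeneSpec("a", "intermediate", production=0.1, decay=0.5))
    g.regulations = [
        RegulationSpec("red", "blue", "negative", hill_coeff=10, bind_const=4),
        RegulationSpec("green", "blue", "negative", hill_coeff=10, bind_const=4),
        RegulationSpec("red", "a", "positive", "necessary", hill_coeff=10, bind_const=80),
        RegulationSpec("green", "a", "positive", "necessary", hill_coeff=10, bind_const=80),
        RegulationSpec("a", "blue", "positive", "necessary", hill_coeff=4, bind_const=40),
    ]
    return g
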