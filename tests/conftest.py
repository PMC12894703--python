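import numpy as np
import pytest

from twistcloud import geometry
from twistcloud.particles import ParticleList


def random_particle_list(
    rng: np.random.Generator,
    n: int = 50,
    box: float = 100.0,
    n_tomos: int = 1,
    scores: bool = True,
) -> ParticleList:
    """Fuzzed particle list with Haar-random orientations."""
    return ParticleList.from_arrays(
        rng.uniform(0, box, (n, 3)),
        np.stack([geometry.random_rotation(rng) for _ in range(n)]),
        tomo_ids=rng.integers(0, n_tomos, n),
        scores=rng.uniform(0, 1, n) if scores else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260115)


@pytest.fixture(scope="session")
def chromatin_small():
    """Reduced chromatin scene shared by pipeline tests."""
    from twistcloud.synthetic import ChromatinSpec, generate_chromatin

    spec = ChromatinSpec(n_helix=2, n_stack=40, n_tri=40, n_mono=300, box=(250.0, 250.0, 120.0))
    return generate_chromatin(spec, seed=11)
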