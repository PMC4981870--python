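import pytest

from netforge import generate_world
from netforge.pipeline import run_pipeline


@pytest.fixture(scope="session")
def world():
    """Default planted-module synthetic world (300 genes, 6 modules of 20)."""
    return generate_world(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(world):
    """Full gold -> evidence -> calibration -> integration run on `world`.

    Session-scoped: several tests assert different properties of the
    same build.
    """
    return run_pipeline(world, seed=1)


@pytest.fixture(scope="session")
def small_world():
    """Tiny world for fast IO / CLI round-trips."""
    return generate_world(seed=7, n_genes=60, n_modules=3, module_size=8, n_samples=14)
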