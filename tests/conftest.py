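import numpy as np
import pytest

from gastruloid_quant.scenes import (CentralDisc, EdgeBand, IntensityModel,
                                     Ring, SceneSpec, generate_colony_image)


@pytest.fixture(scope="session")
def small_colony():
    """Noise-free 150 µm colony with an edge-band marker; shared read-only."""
    spec = SceneSpec(
        colony_radius=150.0,
        n_nuclei=120,
        channel_models={"MARKER": EdgeBand(width=50.0, colony_radius=150.0)},
        seed=11,
    )
    colony, truth = generate_colony_image(spec)
    return spec, colony, truth


@pytest.fixture(scope="session")
def three_ring_colony():
    """Standard patterned colony: SOX2 disc, BRA ring, CDX2 edge."""
    spec = SceneSpec(
        colony_radius=250.0,
        density=3700.0,
        channel_models={
            "SOX2": CentralDisc(radius=167.0),
            "BRA": Ring(r_in=167.0, r_out=220.0),
            "CDX2": EdgeBand(width=30.0, colony_radius=250.0),
        },
        seed=21,
    )
    colony, truth = generate_colony_image(spec)
    return spec, colony, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
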