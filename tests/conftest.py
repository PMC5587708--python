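import math

import numpy as np
import pytest

import punctaprox as pp


@pytest.fixture(scope="session")
def coupled_truth():
    """A small field with full coupling at a fixed 0.3 um offset."""
    model = pp.CouplingModel(
        cell_count=4,
        cell_radius_um=10.0,
        nucleus_fraction=0.3,
        green_density=0.2,
        red_density=0.02,
        coupling_fraction=1.0,
        offset_law=pp.FixedOffset(0.3),
        seed=11,
    )
    return pp.simulate_point_pattern(model)


@pytest.fixture(scope="session")
def rendered_field(coupled_truth):
    spec = pp.RenderSpec()
    field = pp.render_field(coupled_truth, spec, seed=7)
    regions = pp.regions_from_truth(
        coupled_truth, spec.pixel_size_um, field["red"].shape
    )
    return coupled_truth, field, regions


def csr_median(density: float) -> float:
    return math.sqrt(math.log(2.0) / (math.pi * density))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
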