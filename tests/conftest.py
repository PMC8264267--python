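"""Shared fixtures: a small baseline scenario reused across test modules."""

import numpy as np
import pytest

from tumordds.config import ScenarioConfig
from tumordds.geometry import TissueMap, build_grid, \
    generate_synthetic_vasculature, make_circular_tumor
from tumordds.params import load_parameter_set
from tumordds.perfusion import couple_perfusion


@pytest.fixture()
def params():
    return load_parameter_set()


@pytest.fixture(scope="session")
def baseline():
    """Small synthetic scenario: 48×48 grid, 0.5 mm tumor, seeded network."""
    params = load_parameter_set()
    grid = build_grid(2e-3, 2e-3, 48, 48)
    tissue = make_circular_tumor(grid, (1e-3, 1e-3), 5e-4)
    network = generate_synthetic_vasculature(grid, tissue, seed=1)
    return {"params": params, "grid": grid, "tissue": tissue,
            "network": network}


@pytest.fixture(scope="session")
def baseline_flow(baseline):
    return couple_perfusion(baseline["network"], baseline["grid"],
                            baseline["tissue"], baseline["params"])


@pytest.fixture(scope="session")
def all_tumor_8x8():
    """Tiny homogeneous tumor block for 0D kinetics checks."""
    grid = build_grid(4e-4, 4e-4, 8, 8)
    tissue = TissueMap(tumor_mask=np.ones((8, 8), dtype=bool))
    return grid, tissue


@pytest.fixture()
def default_config():
    return ScenarioConfig()
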