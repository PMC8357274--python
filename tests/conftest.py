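import numpy as np
import pytest

from matprofiler.scenarios import default_scenario
from matprofiler.synthetic import MatScenario


@pytest.fixture
def scenario():
    """The bundled noise-free default scenario."""
    return default_scenario(seed=0)


@pytest.fixture
def single_layer_consumption():
    """One 2-mm layer with uniform O2 consumption, fixed top, closed bottom."""
    return MatScenario(
        layer_boundaries_mm=[0.0, 2.0],
        true_rates={"O2": [-1.0e-4]},
        diffusivity={"O2": 1.5e-9},
        boundary_conditions={"O2": (0.25, "zero_flux")},
        porosity=0.3,
    )


def random_layered_scenario(rng: np.random.Generator, solute: str = "O2") -> MatScenario:
    """A random <=5-layer scenario with boundaries on the 0.05-mm grid."""
    n_layers = int(rng.integers(1, 6))
    widths = rng.integers(10, 41, size=n_layers) * 0.05  # 0.5 - 2 mm per layer
    boundaries = np.round(np.concatenate([[0.0], np.cumsum(widths)]), 9)
    signs = rng.choice([-1.0, 1.0], size=n_layers)
    rates = signs * rng.uniform(2e-5, 5e-4, size=n_layers)
    bottom = "zero_flux" if rng.random() < 0.5 else float(rng.uniform(0.0, 0.5))
    return MatScenario(
        layer_boundaries_mm=boundaries,
        true_rates={solute: rates},
        diffusivity={solute: 1.5e-9},
        boundary_conditions={solute: (float(rng.uniform(0.1, 1.0)), bottom)},
        porosity=float(rng.uniform(0.2, 0.6)),
    )
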