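import numpy as np
import pytest

from risize import AnalytePopulation, SimulationSpec, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def normal_pop():
    """5,000 standard-normal values, fixed seed."""
    spec = SimulationSpec(family="normal", params={"mean": 0.0, "sd": 1.0},
                          pop_size=5000, seed=42)
    return generate_population(spec)


@pytest.fixture
def lognormal_pop():
    """5,000 lognormal(0, 0.5) values, fixed seed (right-skewed analyte)."""
    spec = SimulationSpec(family="lognormal", params={"mu": 0.0, "sigma": 0.5},
                          pop_size=5000, seed=42)
    return generate_population(spec)


@pytest.fixture
def small_pop(rng):
    return AnalytePopulation(rng.normal(10.0, 1.0, 400), "toy", "mmol/L")
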