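import numpy as np
import pytest

import epiclone as ec


@pytest.fixture
def rng():
    return np.random.default_rng(20200318)


@pytest.fixture(scope="session")
def eso_params():
    """Esophageal single-progenitor parameters (shifted-gamma cycle law)."""
    return ec.get_preset("esophagus-lrig1").params()


@pytest.fixture(scope="session")
def eso_exp_params():
    """Esophageal parameters with exponential (Markovian) cycle times."""
    return ec.SPParams.homeostatic(2.9, 0.10, 0.65, family="exponential")


@pytest.fixture(scope="session")
def small_chase_table():
    """A compact synthetic H2B-GFP chase shared across inference tests."""
    design = ec.ChaseDesign(animals_per_time=(2, 2, 2, 2), cells_per_field=80)
    truth = ec.get_preset("esophagus-lrig1").params()
    return ec.generate_h2bgfp_experiment(truth, design, np.random.default_rng(42))
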