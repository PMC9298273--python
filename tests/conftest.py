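import numpy as np
import pytest

from phenoscreen import synthetic as sy


@pytest.fixture(scope="session")
def noiseless_field():
    """A small noise-free rendered field with its ground truth."""
    params = sy.PhenotypeParams(noise_sd=0.0)
    spec = sy.CultureSpec("control", "CTRL1", "EXP1", params, seed=7)
    return sy.render_field(spec, size=(512, 512), n_z=4)


@pytest.fixture(scope="session")
def tiny_plate():
    """A minimal rendered plate: 2 lines x 2 conditions x 4 fields at
    256 px, 3 z-planes — enough for end-to-end plumbing tests."""
    layout = sy.PlateLayout(experiments=("EXP1",),
                            cell_lines=("CTRL1", "CTRL2"),
                            conditions=("control", "heat"))
    return sy.generate_plate(layout, seed=5, size=(256, 256),
                             fields_per_well=4, n_z=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
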