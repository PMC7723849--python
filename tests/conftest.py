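import numpy as np
import pytest

from regenquant import simgen


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def nerve_config():
    """Reference synthetic nerve used across nerve_regen tests."""
    return simgen.NerveSimConfig(
        image_height_px=120,
        image_width_px=800,
        pixel_size_um=5.0,
        injury_x_um=400.0,
        n_fibers=100,
        decay_length_um=700.0,
        nerve_width_profile=(100.0,),
        seed=3,
    )


@pytest.fixture
def explant_config():
    """Reference synthetic explant with moderate outgrowth."""
    return simgen.ExplantSimConfig(
        n_axons=6,
        seed=7,
        noise_sd=0.02,
        tortuosity=0.002,
        axon_length_um_distribution=simgen.LengthDistribution(
            "uniform", {"low": 100.0, "high": 450.0}, 500.0
        ),
    )
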