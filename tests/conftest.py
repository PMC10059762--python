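import numpy as np
import pytest

from mtq.synthdata import FiberFieldParams, simulate_fiber_image


@pytest.fixture(scope="session")
def aligned_fiber_field():
    """One concentrated fiber field (-30 deg, kappa 8) reused across tests."""
    return simulate_fiber_image(
        FiberFieldParams(
            image_size_px=(256, 256),
            mean_angle_deg=-30.0,
            kappa=8.0,
            target_coverage=0.15,
            seed=42,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
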