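import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from nephrotex.phantom import PhantomParams, generate_subject_phantom


@pytest.fixture(scope="session")
def fast_params() -> PhantomParams:
    """Small, quick-to-generate phantom geometry used by unit tests."""
    return PhantomParams(
        image_matrix=128,
        pixel_spacing=2.0,
        kidney_axes=(80.0, 50.0),
        n_cysts=4,
        cyst_radius_range=(3.0, 8.0),
        psoas_axes=(30.0, 18.0),
    )


@pytest.fixture(scope="session")
def fast_case(fast_params):
    return generate_subject_phantom(fast_params, "PKD1-like", 0, 1234)
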