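import pytest

from hemcyto import detector as det_mod
from hemcyto import hem_core, simgen


@pytest.fixture(scope="session")
def trained_detector():
    """Calibrated LDA detector trained on simulated labeled patches."""
    return det_mod.train_calibrated_detector(seed=42)


@pytest.fixture(scope="session")
def single_spot_field():
    """One isolated 7.5 µm spot on Poisson background, with truth."""
    spec = simgen.FieldSpec(
        image_size=(40, 40),
        background_level=30.0,
        noise_model="poisson",
        spots=(
            simgen.SpotTruth(center=(19.4, 20.3), total_photons=8000.0, sigma=(1.06, 1.06)),
        ),
        seed=5,
    )
    return simgen.render_field(spec)


@pytest.fixture
def converged_single_fit(single_spot_field):
    image, _ = single_spot_field
    init = hem_core.initial_fit(image.pixels.shape, [(19.5, 19.5)])
    return hem_core.fit_hem(image.pixels, init)

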