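import pytest

from srskit.simulate import (
    Annulus,
    Disk,
    PhantomScene,
    build_phantom,
    default_library,
    fingerprint_axis,
    make_pair,
    render_clean_stack,
)


@pytest.fixture(scope="session")
def axis32():
    return fingerprint_axis(32)


@pytest.fixture(scope="session")
def library3(axis32):
    return default_library(("bsa", "triglyceride", "cholesterol"), axis32)


@pytest.fixture(scope="session")
def tiny_scene():
    """Deterministic 64x64 scene: one membrane annulus and two droplets."""
    return PhantomScene(
        shape=(64, 64),
        objects=(
            Annulus(32, 32, 18, 22, abundances=(0.8, 0.1, 0.1)),
            Disk(28, 30, 6, abundances=(0.1, 1.0, 0.05)),
            Disk(38, 36, 5, abundances=(0.05, 0.1, 0.9)),
        ),
        baseline_amplitude=0.05,
    )


@pytest.fixture(scope="session")
def tiny_maps(tiny_scene):
    return build_phantom(tiny_scene, 3)


@pytest.fixture(scope="session")
def clean_stack(tiny_maps, library3, tiny_scene):
    return render_clean_stack(tiny_maps, library3, tiny_scene.baseline_amplitude)


@pytest.fixture(scope="session")
def signal_mask(tiny_maps):
    return tiny_maps.sum(axis=2) > 0


@pytest.fixture(scope="session")
def noisy_pair(clean_stack, signal_mask):
    return make_pair(clean_stack, n_avg=100, target_snr=1.4, seed=42,
                     signal_mask=signal_mask)
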