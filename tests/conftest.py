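"""Shared fixtures: phantoms, simulated series, registration parameters."""
import numpy as np
import pytest

from elastimap import (
    MotionModel,
    PhantomSpec,
    RegistrationParams,
    SchemeSpec,
    make_cardiac_phantom,
    simulate_molli_series,
    simulate_scheme_timing,
)


@pytest.fixture(scope="session")
def params() -> RegistrationParams:
    return RegistrationParams()


@pytest.fixture(scope="session")
def phantom128():
    """Full-size textured short-axis phantom."""
    return make_cardiac_phantom(PhantomSpec(shape=(128, 128), seed=1))


@pytest.fixture(scope="session")
def phantom48():
    """Small phantom for pixel-wise fitting tests."""
    return make_cardiac_phantom(PhantomSpec(shape=(48, 48), seed=3))


@pytest.fixture(scope="session")
def tissue_image128(phantom128):
    """Anatomical image (textured equilibrium signal) plus tissue mask."""
    mask = phantom128.labels > 0
    return phantom128.m0, mask


@pytest.fixture(scope="session")
def native_tis():
    """Inversion times of the native 5s(3s)3s scheme at 60 bpm (ms)."""
    spec = SchemeSpec.from_string("5s(3s)3s", 60.0)
    return simulate_scheme_timing(spec).inversion_times_ms


@pytest.fixture(scope="session")
def still_series48(phantom48, native_tis):
    """Noise- and motion-free magnitude MOLLI series of the small phantom."""
    series, fields = simulate_molli_series(
        phantom48,
        native_tis,
        motion=MotionModel(translation_sigma_px=0.0),
        noise_sigma=0.0,
        magnitude=True,
        seed=0,
    )
    return series, fields


@pytest.fixture(scope="session")
def fit_mask48(phantom48):
    """Restrict pixel-wise fits to heart tissue to keep tests brisk."""
    return phantom48.mask("myocardium") | phantom48.mask("blood")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
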