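import numpy as np
import pytest

from spongiometry import (
    MapSeries,
    MorphometryConfig,
    control_phantom_spec,
    fit_monoexponential,
    generate_phantom,
    interpolate_map,
)

PREP_TIMES = np.array([0.0, 20.0, 40.0, 60.0, 80.0])


def series_from_pixel(signals, prep_times=PREP_TIMES, spacing=0.52, contrast="T2"):
    """Single-pixel MapSeries from a 1D signal vector."""
    images = np.asarray(signals, dtype=float)[:, np.newaxis, np.newaxis]
    return MapSeries(
        images=images, prep_times=prep_times, pixel_spacing=spacing, contrast_label=contrast
    )


def moments_vector(mean, sd, n):
    """A length-n vector with exact sample mean and sample SD (ddof=1)."""
    base = np.arange(n, dtype=float)
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="session")
def control_phantom_t2():
    """Noise-free control-pattern phantom, fitted and 3x interpolated."""
    spec = control_phantom_spec(
        snr=np.inf, contrasts=("T2",), image_shape=(34, 36), transition_sigma_mm=0.35
    )
    series_by, truth = generate_phantom(spec)
    rmap = interpolate_map(fit_monoexponential(series_by["T2"]), 3)
    return rmap, truth


@pytest.fixture(scope="session")
def long_profile_config():
    return MorphometryConfig(profile_length=12.0)
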