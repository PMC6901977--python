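import numpy as np
import pytest

import mr2sct as m


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, bias-free, PSF-free head phantom: the analytic limit."""
    return m.head_phantom_spec(64, seed=0, bias_field_amplitude=0.0,
                               mr_noise_sigma=0.0, ct_noise_sigma=0.0,
                               psf_fwhm_px=0.0, tissue_texture=0.0)


@pytest.fixture(scope="session")
def clean_pair(clean_spec):
    return m.generate_pair(clean_spec)


@pytest.fixture(scope="session")
def noisy_pair():
    return m.generate_pair(m.head_phantom_spec(64, seed=11))


@pytest.fixture(scope="session")
def template():
    return m.CohortTemplate(image_size=64)


def tissue_means(spec, field):
    return {t.label: getattr(t, field) for t in spec.tissue_set}


@pytest.fixture(scope="session")
def head_ellipse_mask(clean_spec):
    """Analytic head outline (outer soft-tissue ellipse) of the clean spec."""
    soft = [t for t in clean_spec.tissue_set if t.label == "soft_tissue"][0]
    return soft.geometry.mask((clean_spec.image_size, clean_spec.image_size))
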