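import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spinefat as sf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """64x64 phantom geometry used throughout the fast tests."""
    return sf.PhantomSpec(image_size=64, cortical_rim_px=1, seed=11)


@pytest.fixture(scope="session")
def clean_phantom(small_spec):
    """Noise-free, homogeneous phantom: quantification closure regime."""
    import dataclasses

    spec = dataclasses.replace(small_spec, noise_sd=0.0, ff_heterogeneity_pct=0.0)
    return sf.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom(small_spec):
    return sf.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size (20 x 256 x 256) phantom."""
    return sf.generate_phantom(sf.PhantomSpec(seed=5))


@pytest.fixture(scope="session")
def trained_tiny_model():
    """A small U-Net trained briefly on easy 32x32 phantoms.

    Used by tests that need a model whose in-mask probabilities separate
    from background; trained once per session.
    """
    from spinefat.segmentation import cohort_to_arrays

    spec = sf.PhantomSpec(image_size=32, cortical_rim_px=1, n_vertebrae=3,
                          noise_sd=0.02, seed=2)
    cohort = sf.generate_cohort(4, spec=spec, seed=21)
    X, y, g = cohort_to_arrays([(s, t.mask) for s, t in cohort])
    est = sf.VertebraSegmenter(model_scale=0.125, depth=3, max_epochs=12,
                               early_stopping_patience=12, seed=3,
                               validation_fraction_subjects=0.25)
    est.fit(X, y, groups=g)
    return est, spec
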