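"""Shared fixtures: small seeded phantom subjects and cohorts.

Everything is generated at test time; no data files ship with the package.
Unit-test phantoms are deliberately smaller than the 48-voxel default so
the conv stack runs in well under a second per subject.
"""

import numpy as np
import pytest

from deepradiomics import (
    ConvStackConfig,
    DemographicsSpec,
    PhantomSpec,
    generate_cohort,
    generate_subject,
    preprocess_subject,
)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """A 28-voxel phantom with a small, jitter-free ellipsoid tumour."""
    return PhantomSpec(
        grid_shape=(28, 28, 28),
        tumour_center=(14.0, 14.0, 14.0),
        tumour_semiaxes=(6.0, 5.0, 4.0),
        center_jitter=0.0,
        semiaxis_jitter=0.0,
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_spec):
    return generate_subject(tiny_spec, DemographicsSpec(), "mutant", "sub-0000", seed=11)


@pytest.fixture(scope="session")
def tiny_subject_pre(tiny_subject):
    return preprocess_subject(tiny_subject)


@pytest.fixture(scope="session")
def conv_cfg() -> ConvStackConfig:
    return ConvStackConfig(n_layers_used=3, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """24 balanced subjects on a 32-voxel grid, preprocessed."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        tumour_center=(16.0, 16.0, 16.0),
        tumour_semiaxes=(7.0, 6.0, 5.0),
        center_jitter=1.0,
        semiaxis_jitter=1.0,
    )
    demo = DemographicsSpec(mutant_fraction=0.5)
    return [preprocess_subject(r) for r in generate_cohort(24, spec, demo, seed=5)]


@pytest.fixture(scope="session")
def gaussian_features():
    """A separable 2-class Gaussian feature-space cohort (no imaging)."""
    rng = np.random.default_rng(42)
    n = 200
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, 20))
    X[y == 1, :5] += 2.0
    return X, y
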