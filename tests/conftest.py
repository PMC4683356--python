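"""Shared fixtures: all test data is generated, nothing is downloaded."""

import numpy as np
import pytest

from atlasforge import ReferenceHistogram, match_histogram
from atlasforge.synthetic_cohort import PhantomSpec, generate_cohort, generate_phantom

GRID = (32, 32, 32)


def make_phantom(age=40.0, seed=0, noise_sigma=2.0, warp_amplitude=0.0,
                 warp_smoothness=10.0, affine_jitter=None, grid=GRID, **kw):
    spec = PhantomSpec(age=age, seed=seed, grid_shape=grid, noise_sigma=noise_sigma,
                       warp_amplitude=warp_amplitude, warp_smoothness=warp_smoothness,
                       affine_jitter=affine_jitter, **kw)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Unperturbed, lightly noisy phantom at the session's working grid."""
    return make_phantom(seed=1)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_phantom(seed=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """8 phantoms, ages spanning 18-76, two scanners, written to disk."""
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(8, 18, 76, seed=11, out_dir=out, grid_shape=GRID)


@pytest.fixture(scope="session")
def normalized_cohort(small_cohort):
    """The small cohort after histogram standardization to one reference."""
    cohort, gts = small_cohort
    ref_rec, _ = make_phantom(age=47, seed=999, noise_sigma=0.0)
    ref = ReferenceHistogram.from_volume(ref_rec.volume)
    for rec in cohort:
        rec.volume = match_histogram(rec.load_volume(), ref, rec.load_mask())
    return cohort, gts


def build_config(**kw):
    """The reduced-iteration build settings the test suite runs with."""
    from atlasforge import BuildConfig, RegistrationConfig

    kw.setdefault("max_outer_iterations", 2)
    kw.setdefault("affine_config", RegistrationConfig(affine_max_evals=150))
    kw.setdefault("diffeo_config", RegistrationConfig(max_iterations_per_level=(10, 10, 5)))
    return BuildConfig(**kw)


@pytest.fixture(scope="session")
def normalized_cohort48(tmp_path_factory):
    """8 phantoms at the generator's default 48 mm field of view, normalized."""
    out = tmp_path_factory.mktemp("cohort48")
    cohort, gts = generate_cohort(8, 18, 76, seed=11, out_dir=out, grid_shape=(48, 48, 48))
    ref_rec, _ = make_phantom(age=47, seed=999, noise_sigma=0.0, grid=(48, 48, 48))
    ref = ReferenceHistogram.from_volume(ref_rec.volume)
    for rec in cohort:
        rec.volume = match_histogram(rec.load_volume(), ref, rec.load_mask())
    return cohort, gts


@pytest.fixture(scope="session")
def templates48(normalized_cohort48):
    """Templates at target ages 20, 50 and 75 from the 48-mm cohort."""
    from atlasforge import build_template

    cohort, _ = normalized_cohort48
    cfg = build_config()
    return {age: build_template(cohort, float(age), cfg) for age in (20, 50, 75)}


@pytest.fixture(scope="session")
def age_series32(normalized_cohort):
    """The full default age grid (20..75 step 5) built at 32 mm scale."""
    from atlasforge import build_age_series

    cohort, _ = normalized_cohort
    return build_age_series(cohort, build_config())
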