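"""Kernel-regression weights, groupwise template construction, tissue maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from atlasforge import (
    AgeKernel,
    BrainMask,
    Cohort,
    Volume,
    age_weights,
    build_population_template,
    build_template,
    build_tpm,
)
from atlasforge.synthetic_cohort import PhantomSpec, generate_phantom
from atlasforge.validation import dice
from conftest import GRID, build_config, make_phantom


# ---------------------------------------------------------------- weights


def test_single_subject_weight_is_one():
    np.testing.assert_allclose(age_weights([63.0], AgeKernel(30, 5)), [1.0])


def test_symmetric_ages_share_weight():
    w = age_weights([25.0, 35.0], AgeKernel(30, 5))
    np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-15)
    w2 = age_weights([25.0, 35.0], AgeKernel(30, 11.7))
    np.testing.assert_allclose(w2, [0.5, 0.5], atol=1e-15)


def test_weights_match_closed_form_gaussian():
    ages = np.array([20.0, 30.0, 40.0, 50.0])
    t, h = 30.0, 5.0
    w = age_weights(ages, AgeKernel(t, h))
    brute = np.exp(-((ages - t) ** 2) / (2 * h * h))
    brute /= brute.sum()
    np.testing.assert_allclose(w, brute, atol=1e-12)
    assert abs(w.sum() - 1.0) < 1e-12


def test_weights_strictly_decrease_with_age_distance():
    w = age_weights([30.0, 33.0, 38.0, 45.0], AgeKernel(30, 5))
    assert all(a > b for a, b in zip(w, w[1:]))


def test_all_weights_underflow_is_an_error():
    with pytest.raises(ValueError, match="bandwidth"):
        age_weights([500.0, 600.0], AgeKernel(20, 0.5))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(18, 76), min_size=1, max_size=20),
       st.floats(20, 75), st.floats(3.0, 20.0))
def test_weights_are_a_probability_vector(ages, t, h):
    w = age_weights(ages, AgeKernel(t, h))
    assert np.all(w >= 0)
    assert abs(w.sum() - 1.0) < 1e-9


# ---------------------------------------------------------------- TPM


def test_tpm_binary_on_noiseless_phantom():
    rec, gt = make_phantom(seed=50, noise_sigma=0.0, warp_amplitude=0.0,
                           texture_amplitude=0.0, grid=(48, 48, 48))
    tpm = build_tpm([rec.volume], [1.0], gt.mask)
    hard = np.stack([t.data for t in tpm], axis=-1).argmax(-1) + 1
    from atlasforge.core_volume import LabelMap

    hard_lm = LabelMap(np.where(gt.mask.data > 0, hard, 0), gt.mask.affine)
    for cls in (1, 2, 3):
        assert dice(hard_lm, gt.tissue_partition, cls) > 0.99


def test_tpm_degenerate_weights_pick_single_subject():
    r1, g1 = make_phantom(seed=51, noise_sigma=2.0)
    r2, _ = make_phantom(seed=52, noise_sigma=2.0)
    both = build_tpm([r1.volume, r2.volume], [1.0, 0.0], g1.mask)
    solo = build_tpm([r1.volume], [1.0], g1.mask)
    for a, b in zip(both, solo):
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)


def test_tpm_probability_contract():
    r1, g1 = make_phantom(seed=53, noise_sigma=3.0)
    r2, _ = make_phantom(seed=54, noise_sigma=3.0)
    tpm = build_tpm([r1.volume, r2.volume], [0.3, 0.7], g1.mask)
    probs = np.stack([t.data for t in tpm], axis=-1)
    assert probs.min() >= 0 and probs.max() <= 1 + 1e-6
    inside = g1.mask.data > 0
    np.testing.assert_allclose(probs.sum(-1)[inside], 1.0, atol=1e-6)


# ---------------------------------------------------------------- templates


def _identical_cohort(n=4, seed=60):
    recs = []
    for i in range(n):
        rec, gt = make_phantom(seed=seed, noise_sigma=0.0, warp_amplitude=0.0)
        rec.id = f"c{i}"
        recs.append(rec)
    return Cohort(recs)


def test_template_from_identical_phantoms_reproduces_them():
    cohort = _identical_cohort()
    tpl = build_template(cohort, 40.0, build_config())
    rec, _ = make_phantom(seed=60, noise_sigma=0.0, warp_amplitude=0.0)
    rng_ = rec.volume.data.max() - rec.volume.data.min()
    assert np.abs(tpl.intensity.data - rec.volume.data).mean() < 0.01 * rng_


def test_template_recovers_shape_from_affine_perturbations():
    """One anatomy seen through 6 known affines averages back to itself:
    the template's ventricle-analog volume (half-max contour, robust to
    symmetric blur) lands within 10% of the unperturbed phantom's."""
    from atlasforge.core_volume import target_world_points
    from atlasforge.synthetic_cohort import (CSF_INTENSITY, WM_INTENSITY,
                                             _anatomy_params, _grid_affine)

    G = (48, 48, 48)
    rng = np.random.default_rng(61)
    recs = []
    for i in range(6):
        jit = np.concatenate([rng.uniform(-2, 2, 3), rng.uniform(-0.04, 0.04, 3),
                              rng.uniform(-0.03, 0.03, 3), rng.uniform(-0.02, 0.02, 3)])
        rec, gt = make_phantom(age=40, seed=62, noise_sigma=2.0, warp_amplitude=0.0,
                               affine_jitter=jit, grid=G)
        rec.id = f"a{i}"
        recs.append(rec)
    tpl = build_template(Cohort(recs), 40.0, build_config())
    rec0, gt0 = make_phantom(age=40, seed=62, noise_sigma=0.0, warp_amplitude=0.0,
                             grid=G)
    aff = _grid_affine(G, (1, 1, 1))
    p = _anatomy_params(40, np.asarray(G, float))
    rho = np.sqrt(((target_world_points(G, aff) / p["brain"]) ** 2).sum(-1)).reshape(G)
    central = rho < 0.55

    def vent_volume(vol):
        # linear partial-volume mass: exactly invariant to symmetric blur,
        # unlike a hard half-max count
        return float(((WM_INTENSITY - vol.data[central])
                      / (WM_INTENSITY - CSF_INTENSITY)).sum())

    assert vent_volume(tpl.intensity) == pytest.approx(vent_volume(rec0.volume),
                                                       rel=0.10)
    # template brain volume matches the unperturbed brain volume
    assert tpl.mask.data.sum() == pytest.approx(gt0.mask.data.sum(), rel=0.05)


def test_unbiasing_keeps_mean_displacement_small():
    cohort = _identical_cohort(n=3, seed=63)
    tpl = build_template(cohort, 40.0, build_config())
    assert tpl.provenance["mean_final_displacement_voxels"] < 0.25


def test_cohort_order_does_not_change_template(normalized_cohort):
    cohort, _ = normalized_cohort
    sub = Cohort(cohort.subjects[:3])
    rev = Cohort(cohort.subjects[:3][::-1])
    cfg = build_config(max_outer_iterations=1)
    t1 = build_template(sub, 40.0, cfg)
    t2 = build_template(rev, 40.0, cfg)
    assert np.abs(t1.intensity.data - t2.intensity.data).max() < 1e-3


def test_singleton_age_grid_equals_direct_build(normalized_cohort):
    from atlasforge import build_age_series

    cohort, _ = normalized_cohort
    sub = Cohort(cohort.subjects[:3])
    cfg = build_config(age_grid=(30.0,), max_outer_iterations=1)
    series = build_age_series(sub, cfg)
    direct = build_template(sub, 30.0, cfg)
    assert len(series) == 1
    np.testing.assert_array_equal(series[0].intensity.data, direct.intensity.data)


def test_age_series_recovers_ventricle_growth(templates48):
    """Central CSF mass of the age templates follows the planted growth."""
    from atlasforge.core_volume import target_world_points
    from atlasforge.synthetic_cohort import _anatomy_params, _grid_affine

    shape = (48, 48, 48)
    aff = _grid_affine(shape, (1, 1, 1))
    p = _anatomy_params(47, np.asarray(shape, float))
    rho = np.sqrt(((target_world_points(shape, aff) / p["brain"]) ** 2).sum(-1))
    central = rho.reshape(shape) < 0.55
    masses = [float(templates48[a].tpm[0].data[central].sum()) for a in (20, 50, 75)]
    assert masses[0] < masses[1] < masses[2]


def test_population_template_of_identical_templates_is_stable(templates48):
    tpl = templates48[50]
    copies = [tpl] * 4
    pop = build_population_template(copies, build_config(max_outer_iterations=1))
    rng_ = tpl.intensity.data.max() - tpl.intensity.data.min()
    assert np.abs(pop.intensity.data - tpl.intensity.data).mean() < 0.02 * rng_
    probs = np.stack([t.data for t in pop.tpm], axis=-1)
    inside = pop.mask.data > 0
    np.testing.assert_allclose(probs.sum(-1)[inside], 1.0, atol=1e-6)


def test_empty_and_single_subject_cohorts():
    with pytest.raises(ValueError):
        build_template(Cohort([]), 30.0, build_config())
    rec, _ = make_phantom(seed=70, noise_sigma=2.0)
    with pytest.warns(UserWarning, match="single subject"):
        tpl = build_template(Cohort([rec]), 30.0,
                             build_config(max_outer_iterations=1))
    assert tpl.provenance["weights"] == [1.0]
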