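"""Dice overlap, atlas-based segmentation, morphometry, paired comparison."""

import numpy as np
import pytest

from atlasforge import (
    BrainMask,
    Cohort,
    LabelMap,
    RegistrationConfig,
    Template,
    Volume,
    VolumeError,
    compare_registration_deformation,
    dice,
    measure_morphometry,
    paired_t,
    segment_by_atlas,
)
from atlasforge.synthetic_cohort import (
    LABEL_HIPPOCAMPUS,
    LABEL_VENTRICLE,
    PhantomSpec,
    generate_phantom,
)
from conftest import make_phantom


def _lm(data, affine=None):
    return LabelMap(np.asarray(data, dtype=np.int32),
                    np.eye(4) if affine is None else affine)


# ---------------------------------------------------------------- dice


def test_dice_identity_is_exactly_one():
    data = np.zeros((32, 32, 32), dtype=np.int32)
    data[10:20, 10:20, 10:20] = 1
    assert dice(_lm(data), _lm(data.copy()), 1) == 1.0


def test_dice_disjoint_is_zero():
    a = np.zeros((16, 16, 16), dtype=np.int32)
    b = np.zeros((16, 16, 16), dtype=np.int32)
    a[:4], b[8:12] = 1, 1
    assert dice(_lm(a), _lm(b), 1) == 0.0


def test_dice_half_overlapping_cubes_closed_form():
    a = np.zeros((20, 20, 20), dtype=np.int32)
    b = np.zeros((20, 20, 20), dtype=np.int32)
    a[0:10, 0:10, 0:10] = 1
    b[0:10, 0:10, 5:15] = 1
    # overlap 10x10x5 = 500; 2*500 / (1000 + 1000) = 0.5
    assert dice(_lm(a), _lm(b), 1) == 0.5
    assert dice(_lm(b), _lm(a), 1) == 0.5  # symmetric


def test_dice_empty_both_is_one_with_warning():
    z = np.zeros((8, 8, 8), dtype=np.int32)
    with pytest.warns(UserWarning, match="empty"):
        assert dice(_lm(z), _lm(z.copy()), 3) == 1.0


def test_dice_grid_mismatch_errors():
    a = _lm(np.ones((8, 8, 8)))
    shifted = np.eye(4)
    shifted[0, 3] = 2.0
    b = _lm(np.ones((8, 8, 8)), shifted)
    with pytest.raises(VolumeError):
        dice(a, b, 1)


# ---------------------------------------------------------------- morphometry


def _mask_from_halfaxes(half_axes, shape, spacing=1.0):
    aff = np.diag([spacing] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing
    idx = np.indices(shape).astype(float)
    xyz = np.stack([idx[a] * spacing + aff[a, 3] for a in range(3)], axis=-1)
    inside = (xyz / np.asarray(half_axes)) ** 2
    return BrainMask((inside.sum(-1) <= 1.0).astype(np.uint8), aff)


def test_sphere_morphometry_analytic():
    # even grid: voxel centres at half-integers, so a radius-50 sphere spans
    # centres -49.5..49.5 -> inclusive extent 100 on every axis
    mask = _mask_from_halfaxes((50.0, 50.0, 50.0), (104, 104, 104))
    lms = np.array([[0.0, 13.0, 0.0], [0.0, -13.0, 0.0]])
    rep = measure_morphometry(mask, lms)
    assert rep.length_mm == rep.width_mm == rep.height_mm == 100.0
    assert rep.ratio_wl == rep.ratio_hl == rep.ratio_hw == 1.0
    assert rep.ac_pc_mm == pytest.approx(26.0)


def test_ellipsoid_morphometry_adult_head_proportions():
    # odd grid: integer voxel centres; half-axes (67.5, 80.5, 48.5) mm give
    # inclusive extents width 135, length 161, height 97
    mask = _mask_from_halfaxes((67.5, 80.5, 48.5), (141, 167, 103))
    rep = measure_morphometry(mask, np.array([[0, 13, 0], [0, -13, 0.0]]))
    assert rep.width_mm == 135.0
    assert rep.length_mm == 161.0
    assert rep.height_mm == 97.0
    assert rep.ratio_wl == pytest.approx(0.84, abs=0.005)


def test_morphometry_ratios_consistent():
    mask = _mask_from_halfaxes((10, 12, 8.0), (32, 32, 32))
    rep = measure_morphometry(mask, np.array([[0, 2, 0], [0, -2, 0.0]]))
    assert rep.ratio_wl == pytest.approx(rep.width_mm / rep.length_mm, abs=1e-9)
    assert rep.ratio_hl == pytest.approx(rep.height_mm / rep.length_mm, abs=1e-9)
    assert rep.ratio_hw == pytest.approx(rep.height_mm / rep.width_mm, abs=1e-9)


def test_axis_permuted_mask_permutes_measurements():
    mask = _mask_from_halfaxes((10, 12, 8.0), (32, 32, 32))
    rep = measure_morphometry(mask, np.array([[0, 2, 0], [0, -2, 0.0]]))
    # permute data axes and the affine columns/rows to match: x<->z
    perm = mask.data.transpose(2, 1, 0)
    aff = mask.affine.copy()
    aff[:3, :3] = aff[:3, :3][[2, 1, 0]][:, [2, 1, 0]]
    aff[:3, 3] = aff[:3, 3][[2, 1, 0]]
    rep_p = measure_morphometry(BrainMask(perm, aff), np.array([[0, 2, 0], [0, -2, 0.0]]))
    assert rep_p.width_mm == rep.height_mm
    assert rep_p.height_mm == rep.width_mm
    assert rep_p.length_mm == rep.length_mm


def test_empty_mask_errors():
    with pytest.raises(VolumeError):
        BrainMask(np.zeros((8, 8, 8), dtype=np.uint8), np.eye(4))


# ---------------------------------------------------------------- segmentation


def _phantom_as_template(rec, gt, age=None):
    flat = (gt.mask.data / 3.0).astype(np.float32)
    return Template(rec.volume, gt.mask,
                    [Volume(flat.copy(), rec.volume.affine) for _ in range(3)],
                    age, {})


@pytest.fixture(scope="module")
def atlas48():
    rec, gt = make_phantom(age=40, seed=77, noise_sigma=0.0, warp_amplitude=0.0,
                           grid=(48, 48, 48))
    return _phantom_as_template(rec, gt, 40.0), rec, gt


def test_self_segmentation_near_perfect(atlas48):
    atlas, rec, gt = atlas48
    seg = segment_by_atlas(atlas, gt.labels, rec.volume, subject_mask=gt.mask)
    assert dice(seg, gt.labels, LABEL_HIPPOCAMPUS) > 0.95
    assert dice(seg, gt.labels, LABEL_VENTRICLE) > 0.95


def test_segmentation_of_known_warp_subject(atlas48):
    atlas, rec, gt = atlas48
    rec_w, gt_w = make_phantom(age=40, seed=77, noise_sigma=2.0, warp_amplitude=3.0,
                               warp_smoothness=10.0, grid=(48, 48, 48))
    seg = segment_by_atlas(atlas, gt.labels, rec_w.volume, subject_mask=gt_w.mask)
    assert dice(seg, gt_w.labels, LABEL_HIPPOCAMPUS) > 0.8


# ---------------------------------------------------------------- paired morphometry


def test_paired_t_matches_closed_form():
    a = np.array([25.1, 26.3, 24.8, 25.9, 26.8])
    b = np.array([27.0, 27.1, 26.2, 27.5, 28.1])
    t, p = paired_t(a, b)
    d = b - a
    t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    from scipy import stats

    p_ref = 2 * stats.t.sf(abs(t_ref), d.size - 1)
    assert t == pytest.approx(t_ref, abs=1e-9)
    assert p == pytest.approx(p_ref, abs=1e-9)


def _perturbed_cohort(n, seed0, age=40.0, grid=(32, 32, 32)):
    rng = np.random.default_rng(seed0)
    recs, lms = [], []
    for i in range(n):
        jit = np.concatenate([rng.uniform(-1.5, 1.5, 3), rng.uniform(-0.02, 0.02, 3),
                              rng.uniform(-0.02, 0.02, 3), np.zeros(3)])
        rec, gt = make_phantom(age=age, seed=seed0 + i, noise_sigma=2.0,
                               warp_amplitude=1.0, warp_smoothness=8.0,
                               affine_jitter=jit, grid=grid)
        rec.id = f"v{i}"
        rec.mask = gt.mask
        recs.append(rec)
        lms.append(gt.landmarks)
    return Cohort(recs), lms


def test_matched_template_demands_little_deformation():
    cohort, lms = _perturbed_cohort(4, 80)
    rec_t, gt_t = make_phantom(age=40, seed=88, noise_sigma=0.0, warp_amplitude=0.0)
    template = _phantom_as_template(rec_t, gt_t, 40.0)
    table = compare_registration_deformation(cohort, lms, [template])
    length = table[table.measure == "length_mm"].iloc[0]
    # extents are voxel-quantized; a size-matched template moves the mean
    # length by less than one voxel (1 mm here)
    assert abs(length.registered_mean - length.native_mean) <= 1.0


def test_oversized_template_stretches_every_subject():
    """A template 15% longer than the cohort forces a length increase for
    every subject, the analog of registering to a mismatched-population
    atlas."""
    cohort, lms = _perturbed_cohort(6, 90)
    stretch = np.zeros(12)
    stretch[7] = np.log(1.0 / 1.15)  # canonical seen through y-shrink = longer brain
    rec_t, gt_t = make_phantom(age=40, seed=91, noise_sigma=0.0, warp_amplitude=0.0,
                               affine_jitter=stretch)
    template = _phantom_as_template(rec_t, gt_t, 40.0)

    from atlasforge import affine_register, apply_transform

    natives, registered = [], []
    for rec in cohort:
        rep0 = measure_morphometry(rec.mask, np.zeros((2, 3)))
        aff = affine_register(rec.load_volume(), template.intensity, template.mask)
        w_mask = apply_transform(rec.mask, aff, template.intensity.shape,
                                 template.intensity.affine, "nearest")
        rep1 = measure_morphometry(w_mask, np.zeros((2, 3)))
        natives.append(rep0.length_mm)
        registered.append(rep1.length_mm)
    assert all(b > a for a, b in zip(natives, registered))
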