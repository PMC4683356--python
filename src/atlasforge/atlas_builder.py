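"""Age-conditioned groupwise template construction.

A template at target age t is the iteratively refined, kernel-weighted
average of the cohort: subjects are weighted by a Gaussian kernel of the
distance between their age and t (closer ages contribute more, which also
copes with missing or unevenly distributed ages), and at every outer
iteration each subject is affine- then diffeomorphically registered to the
current reference, warped, and averaged.  No individual subject is ever
elected as the reference: the initial reference is the weighted average
brain itself, and (optionally, on by default) the reference is corrected by
the inverse of the weighted mean deformation so the template does not drift
toward any subject's anatomy.

An age series is one template per grid age (default 20..75 in steps of 5,
i.e. twelve templates); the population template fuses the series with the
same groupwise algorithm under uniform weights.  Tissue probability maps
are per-subject 3-class Gaussian-mixture posteriors (classes ordered by
mean intensity: CSF-, GM-, WM-analog) averaged with the same weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .core_volume import BrainMask, Cohort, LabelMap, Volume, VolumeError
from .registration import (
    DeformationField,
    RegistrationConfig,
    RegistrationError,
    affine_register,
    apply_transform,
    diffeo_register,
    invert_field,
)

logger = logging.getLogger("atlasforge")


@dataclass
class AgeKernel:
    """Gaussian age-weighting kernel centred at the template's target age."""

    target_age: float
    bandwidth: float = 5.0

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")


@dataclass
class Template:
    """An intensity template with mask, tissue probability maps and provenance.

    ``labels`` carries structure labels in template space (the weighted
    majority vote of the subjects' labels warped through their final
    transforms) when the cohort provides them — the stand-in for labels
    drawn manually on a template.
    """

    intensity: Volume
    mask: BrainMask
    tpm: list[Volume]
    target_age: float | None
    provenance: dict
    labels: LabelMap | None = None

    def __post_init__(self) -> None:
        if len(self.tpm) != 3:
            raise ValueError("expected 3 tissue probability maps")
        if not np.all(np.isfinite(self.intensity.data)):
            raise VolumeError("template intensity not finite")
        probs = np.stack([t.data for t in self.tpm], axis=-1)
        if probs.min() < -1e-6 or probs.max() > 1 + 1e-6:
            raise VolumeError("TPM values outside [0, 1]")
        inside = self.mask.data > 0
        s = probs.sum(axis=-1)[inside]
        if s.size and np.abs(s - 1).max() > 1e-5:
            raise VolumeError("TPMs do not sum to 1 inside the mask")


@dataclass
class BuildConfig:
    """Settings of the groupwise builder."""

    age_grid: tuple = tuple(range(20, 80, 5))
    bandwidth: float = 5.0
    max_outer_iterations: int = 5
    convergence_tol: float = 0.001        # fraction of intensity range
    unbias: bool = True
    # register against an unsharp-masked average: counteracts the shrinkage
    # of small structures toward the partial-volumed group mean (the usual
    # sharpening step of iterative template pipelines)
    sharpen_reference: bool = True
    sharpen_sigma: float = 1.0            # voxels
    affine_config: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    diffeo_config: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    gmm_seed: int = 0

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.age_grid)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("age grid must be strictly increasing")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        self.age_grid = ages


# ---------------------------------------------------------------------------
# Kernel regression weights
# ---------------------------------------------------------------------------

def age_weights(ages, kernel: AgeKernel) -> np.ndarray:
    """Normalized Gaussian kernel weights w_i ~ exp(-(a_i - t)^2 / (2 h^2)).

    Strictly decreasing in |a_i - t|; the weights sum to 1.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 1:
        raise ValueError("need at least one subject")
    z = (ages - kernel.target_age) / kernel.bandwidth
    logw = -0.5 * z**2
    if np.exp(logw.max()) == 0.0:
        raise ValueError(
            "all kernel weights underflowed to zero; increase the bandwidth "
            f"(h={kernel.bandwidth}) or choose a target age nearer the cohort"
        )
    # shift by the max exponent for numerical stability before normalizing
    w = np.exp(logw - logw.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# Tissue probability maps
# ---------------------------------------------------------------------------

def build_tpm(warped_subjects: list[Volume], weights, mask: BrainMask,
              seed: int = 0) -> list[Volume]:
    """Weighted-average 3-class GMM posteriors of warped subjects.

    Per subject, a 3-component Gaussian mixture is fit to the intensities
    inside the mask and components are ordered by mean (CSF < GM < WM
    analog).  If the mixture degenerates (fewer than 3 separated modes),
    quantile thresholds are used instead, with a warning.
    """
    from sklearn.mixture import GaussianMixture

    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    inside = mask.data > 0
    shape = mask.shape
    acc = np.zeros(shape + (3,), dtype=np.float64)
    for vol, w in zip(warped_subjects, weights):
        if w == 0.0:
            continue
        x = vol.data[inside].reshape(-1, 1).astype(np.float64)
        post = None
        try:
            # quantile initialisation: deterministic and ordered CSF < GM < WM.
            # A tied covariance rules out the degenerate solution where one
            # very broad component swallows two intensity modes, and the
            # variance floor scales with the intensity span so noiseless
            # (delta-mass) inputs keep sane posteriors
            init = np.quantile(x, [0.10, 0.50, 0.90]).reshape(3, 1)
            span = float(x.max() - x.min())
            gm = GaussianMixture(n_components=3, covariance_type="tied",
                                 random_state=seed, n_init=1,
                                 reg_covar=max(1e-6, (0.01 * span) ** 2),
                                 max_iter=200, means_init=init)
            gm.fit(x)
            means = gm.means_.ravel()
            order = np.argsort(means)
            if np.min(np.diff(np.sort(means))) < 1e-6 * (x.max() - x.min() + 1e-12):
                raise ValueError("mixture means collapsed")
            post = gm.predict_proba(x)[:, order]
        except Exception as exc:  # degenerate fit
            warnings.warn(f"GMM tissue fit degenerate ({exc}); "
                          "falling back to quantile thresholds")
            q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
            post = np.zeros((x.shape[0], 3))
            post[(x.ravel() <= q1), 0] = 1.0
            post[(x.ravel() > q1) & (x.ravel() <= q2), 1] = 1.0
            post[(x.ravel() > q2), 2] = 1.0
        vox = np.zeros(shape + (3,), dtype=np.float64)
        vox[inside] = post
        acc += w * vox
    s = acc.sum(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    acc = acc / s
    acc[~inside] = 0.0
    return [Volume(acc[..., c].astype(np.float32), mask.affine) for c in range(3)]


# ---------------------------------------------------------------------------
# Groupwise template construction
# ---------------------------------------------------------------------------

def _weighted_average(volumes: list[Volume], weights) -> Volume:
    weights = np.asarray(weights, dtype=float)
    out = np.zeros(volumes[0].shape, dtype=np.float64)
    for v, w in zip(volumes, weights):
        out += w * v.data
    return Volume(out.astype(np.float32), volumes[0].affine)


def _unsharp(volume: Volume, sigma_vox: float) -> Volume:
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(volume.data.astype(np.float64), sigma_vox,
                                     mode="nearest")
    return Volume((2.0 * volume.data - smooth).astype(np.float32), volume.affine)


def build_template(cohort: Cohort, target_age: float | None,
                   config: BuildConfig | None = None) -> Template:
    """Build one age-conditioned template by iterative groupwise registration.

    The cohort is expected to be QC'd and intensity-standardized.  See the
    module docstring for the algorithm; deterministic for fixed inputs and
    config.  Subjects whose registration fails are dropped with a warning
    and the kernel weights renormalized; if every subject fails, an error
    is raised.
    """
    config = config or BuildConfig()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if len(cohort) == 1:
        warnings.warn("building a template from a single subject")

    volumes = [rec.load_volume() for rec in cohort]
    masks = [rec.load_mask() for rec in cohort]
    for i, m in enumerate(masks):
        if m is None:  # fall back to an intensity-threshold mask
            v = volumes[i]
            thr = 0.25 * (float(v.data.max()) + 3 * float(np.median(v.data)))
            masks[i] = BrainMask((v.data > thr).astype(np.uint8), v.affine)
    grid_shape = volumes[0].shape
    grid_affine = volumes[0].affine
    for v in volumes[1:]:
        if not v.same_grid_as(volumes[0]):
            raise VolumeError("cohort volumes must share one grid; resample first")

    ages = cohort.ages()
    if target_age is None:
        weights = np.full(len(cohort), 1.0 / len(cohort))
    else:
        weights = age_weights(ages, AgeKernel(target_age, config.bandwidth))

    average = _weighted_average(volumes, weights)
    intensity_range = float(average.data.max() - average.data.min()) or 1.0
    active = list(range(len(volumes)))
    convergence_trace: list[float] = []
    iterations_run = 0
    warped_final = volumes
    warped_masks_final = masks
    fields_final: list[DeformationField | None] = [None] * len(volumes)
    affines_final: list = []
    correction_final: list = []

    for outer in range(config.max_outer_iterations):
        ref_mask_data = np.zeros(grid_shape)
        for i in active:
            ref_mask_data += weights[i] * masks[i].data
        wsum = weights[active].sum()
        ref_mask = BrainMask((ref_mask_data >= 0.5 * wsum).astype(np.uint8), grid_affine)
        reference = (_unsharp(average, config.sharpen_sigma)
                     if config.sharpen_reference else average)

        fields, affines, survivors = [], [], []
        for i in active:
            try:
                aff = affine_register(volumes[i], reference, ref_mask, config.affine_config)
                pre = apply_transform(volumes[i], aff, grid_shape, grid_affine, "linear")
                fld = diffeo_register(pre, reference, ref_mask, config.diffeo_config)
            except (RegistrationError, VolumeError) as exc:
                logger.warning("subject %s dropped at iteration %d: %s",
                               cohort.subjects[i].id, outer, exc)
                continue
            fields.append(fld)
            affines.append(aff)
            survivors.append(i)
        if not survivors:
            raise RegistrationError("every subject failed to register to the reference")
        if len(survivors) < len(active):
            active = survivors
        w = weights[survivors] / weights[survivors].sum()

        # drift correction: an unbiased template has identity mean transform,
        # so compose every subject's map with the weighted mean of the
        # inverse transforms (affine part and deformation part)
        correction: list = []
        if config.unbias:
            inv_mat = np.zeros((4, 4))
            for aff, wi in zip(affines, w):
                inv_mat += wi * aff.inverse_matrix
            mean_disp = np.zeros(tuple(grid_shape) + (3,))
            for fld, wi in zip(fields, w):
                mean_disp += wi * fld.displacement
            try:
                inv_mean_field = invert_field(
                    DeformationField(mean_disp, tuple(grid_shape), grid_affine))
                correction = [inv_mean_field, inv_mat]
            except RegistrationError as exc:
                logger.warning("deformation unbiasing skipped: %s", exc)
                correction = [inv_mat]

        warped, warped_masks = [], []
        for idx, i in enumerate(survivors):
            chain = [affines[idx], fields[idx]] + correction
            warped.append(apply_transform(volumes[i], chain, grid_shape, grid_affine,
                                          "linear"))
            warped_masks.append(apply_transform(masks[i], chain, grid_shape,
                                                grid_affine, "nearest"))

        new_avg = _weighted_average(warped, w)

        change = float(np.abs(new_avg.data - average.data).mean()) / intensity_range
        convergence_trace.append(change)
        average = new_avg
        warped_final, warped_masks_final, fields_final = warped, warped_masks, fields
        affines_final = affines
        correction_final = correction
        iterations_run = outer + 1
        if change < config.convergence_tol:
            break

    # template mask: weighted majority of warped subject masks
    mask_acc = np.zeros(grid_shape)
    wfin = (weights[active] / weights[active].sum()) if iterations_run else weights
    for m, wi in zip(warped_masks_final, wfin):
        mask_acc += wi * m.data
    tmask = BrainMask((mask_acc >= 0.5).astype(np.uint8), grid_affine)

    tpm = build_tpm(warped_final, wfin, tmask, seed=config.gmm_seed)

    # template-space structure labels: weighted majority vote of the
    # subjects' labels carried through their final transforms
    template_labels = None
    subj_labels = [cohort.subjects[i].load_labels() for i in active]
    if iterations_run and all(l is not None for l in subj_labels) and subj_labels:
        votes: dict[int, np.ndarray] = {}
        table: dict[int, str] = {}
        for lab, aff, fld, wi in zip(subj_labels, affines_final, fields_final, wfin):
            w_lab = apply_transform(lab, [aff, fld] + correction_final,
                                    grid_shape, grid_affine, "nearest")
            table.update(w_lab.label_table)
            for lid in np.unique(w_lab.data):
                votes.setdefault(int(lid), np.zeros(grid_shape))
                votes[int(lid)] += wi * (w_lab.data == lid)
        ids = sorted(votes)  # ties break toward the smaller id (background first)
        stack = np.stack([votes[i] for i in ids], axis=0)
        winner = np.asarray(ids, dtype=np.int32)[np.argmax(stack, axis=0)]
        template_labels = LabelMap(winner, grid_affine, table)

    provenance = {
        "subject_ids": [cohort.subjects[i].id for i in active],
        "weights": np.asarray(wfin, float).tolist(),
        "target_age": target_age,
        "iterations_run": iterations_run,
        "convergence_trace": convergence_trace,
        "final_change": convergence_trace[-1] if convergence_trace else 0.0,
        "unbias": config.unbias,
        "mean_final_displacement_voxels": _mean_weighted_displacement(
            fields_final, wfin, grid_affine),
    }
    return Template(average, tmask, tpm, target_age, provenance,
                    labels=template_labels)


def _mean_weighted_displacement(fields, weights, affine) -> float:
    """Mean magnitude (voxels) of the weighted-average final displacement."""
    real = [(f, w) for f, w in zip(fields, weights) if isinstance(f, DeformationField)]
    if not real:
        return 0.0
    acc = np.zeros(real[0][0].displacement.shape)
    for f, w in real:
        acc += w * f.displacement
    sp = float(np.min(np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)))
    return float(np.linalg.norm(acc, axis=-1).mean() / sp)


def build_age_series(cohort: Cohort, config: BuildConfig | None = None) -> list[Template]:
    """One template per grid age (default 20..75 step 5: twelve templates)."""
    config = config or BuildConfig()
    return [build_template(cohort, age, config) for age in config.age_grid]


def build_population_template(templates: list[Template],
                              config: BuildConfig | None = None) -> Template:
    """Fuse age templates into one population template (uniform weights)."""
    if len(templates) < 2:
        raise ValueError("need at least 2 templates to fuse")
    config = config or BuildConfig()
    cohort = Cohort([
        _template_as_record(t, i) for i, t in enumerate(templates)
    ])
    return build_template(cohort, None, config)


def _template_as_record(t: Template, i: int):
    from .core_volume import SubjectRecord

    rec = SubjectRecord(f"template-{t.target_age if t.target_age is not None else i}",
                        t.target_age if t.target_age is not None else 0.0,
                        "", "", "")
    rec.volume = t.intensity
    rec.mask = t.mask
    return rec
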