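"""Multi-scanner, age-varying brain phantoms with full ground truth.

The phantom is a nest of axis-aligned ellipsoids in world mm (RAS+:
x = left-right, y = posterior-anterior, z = inferior-superior):

* a brain ellipsoid whose outer shell is a CSF-analog, enclosing a
  GM-analog cortical band and a WM-analog core;
* a central ventricle-analog ellipsoid (CSF intensity) whose volume grows
  linearly with age;
* one off-centre hippocampus-analog ellipsoid per hemisphere;
* two landmarks on the anterior-posterior axis standing in for the
  anterior/posterior commissures.

Because every structure is an analytic ellipsoid, volumes, extents and
landmark geometry have closed forms, which the validation tests use as
oracles.  Cortical-band thickness shrinks linearly with age, so an
age-ordered cohort carries a recoverable anatomical trend.

Each simulated scanner applies a fixed monotone affine intensity transform
(so histogram standardization can undo it exactly up to binning), and
acquisition noise is additive Gaussian of known sigma (Rician optional).
Per subject, a random 12-parameter affine jitter and a smooth nonrigid warp
(guaranteed fold-free) are applied to the canonical age-specific anatomy
and recorded as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .core_volume import (
    BrainMask,
    Cohort,
    LabelMap,
    SubjectRecord,
    Volume,
    write_manifest,
    write_volume,
)
from .registration import (
    AffineTransform,
    DeformationField,
    apply_transform,
    invert_field,
    jacobian_determinant,
)

# intensity means of the T1-like tissue classes (arbitrary units)
CSF_INTENSITY = 40.0
GM_INTENSITY = 90.0
WM_INTENSITY = 140.0
# rendered well above the WM-analog so the structure carries registerable
# edges at desk-scale grids (a deliberately high-contrast analog)
HIPPO_INTENSITY = 185.0

# label ids
LABEL_VENTRICLE = 1
LABEL_HIPPOCAMPUS = 2
LABEL_TABLE = {LABEL_VENTRICLE: "ventricle-analog", LABEL_HIPPOCAMPUS: "hippocampus-analog"}
TISSUE_CSF, TISSUE_GM, TISSUE_WM = 1, 2, 3

# intensity transform per simulated scanner: I -> scale * I + shift
SCANNER_EFFECTS = {"siemens": (1.0, 0.0), "ge": (1.6, 30.0)}

AGE_LOW_REF = 18.0  # age at which the canonical anatomy parameters are anchored


@dataclass
class PhantomSpec:
    """Parameters of one simulated subject acquisition."""

    age: float = 40.0
    seed: int = 0
    grid_shape: tuple = (48, 48, 48)
    spacing: tuple = (1.0, 1.0, 1.0)
    scanner: str = "siemens"
    noise_sigma: float = 3.0
    affine_jitter: np.ndarray | None = None          # 12-parameter vector
    warp_amplitude: float = 1.5                      # mm, max displacement
    warp_smoothness: float = 8.0                     # mm, Gaussian scale
    texture_amplitude: float = 0.05                  # relative smooth modulation
    noise_model: str = "gaussian"                    # or "rician"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.warp_amplitude < 0:
            raise ValueError("warp_amplitude must be >= 0")
        # fold-free guarantee: a Gaussian field of scale s and amplitude a has
        # gradient magnitude <~ a/s; require it to stay well below 1
        if self.warp_amplitude > 0 and self.warp_amplitude / self.warp_smoothness > 0.45:
            raise ValueError(
                "warp_amplitude/warp_smoothness > 0.45 risks folding space; "
                "increase warp_smoothness or lower warp_amplitude"
            )
        if self.scanner not in SCANNER_EFFECTS:
            raise ValueError(f"unknown scanner {self.scanner!r}; options: {list(SCANNER_EFFECTS)}")


@dataclass
class GroundTruth:
    """Everything the generator knows about one phantom."""

    true_affine: AffineTransform
    true_warp: DeformationField | None
    labels: LabelMap
    landmarks: np.ndarray            # (2, 3) world mm: AC-analog, PC-analog
    tissue_partition: LabelMap
    noise_sigma: float
    mask: BrainMask = None           # type: ignore[assignment]


def _grid_affine(shape, spacing) -> np.ndarray:
    """RAS+ affine with the world origin at the grid centre."""
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = -(shape - 1) / 2.0 * spacing
    return aff


def _anatomy_params(age: float, fov_mm: np.ndarray) -> dict:
    """Closed-form ellipsoid geometry of the canonical anatomy at an age.

    Half-axes are fractions of the field of view; the brain is longest
    along y (anterior-posterior), echoing adult head proportions
    (width/length around 0.84, height/length around 0.6).
    """
    L = float(np.min(fov_mm))
    brain = np.array([0.42, 0.50, 0.30]) * L / 2.0 * np.array([1.0, 1.0, 1.0])
    # relative radial boundaries of the tissue shells (fractions of brain radius)
    csf_inner = 0.88                     # CSF shell between csf_inner and 1
    gm_thick0 = 0.20                     # cortical band thickness at AGE_LOW_REF
    gm_thick = gm_thick0 * (1.0 - 0.004 * (age - AGE_LOW_REF))   # thins with age
    gm_inner = csf_inner - gm_thick
    vent0 = 0.28                         # ventricle radius fraction at AGE_LOW_REF
    # ventricle volume grows linearly with age (2%/year of the baseline)
    vent = vent0 * (1.0 + 0.02 * (age - AGE_LOW_REF)) ** (1.0 / 3.0)
    # hippocampus-analog: one ellipsoid per hemisphere, shrinking mildly
    # with age so age-matched atlases genuinely fit better
    hip_half = 0.30 * brain * (1.0 - 0.004 * (age - AGE_LOW_REF))
    hip_offset = np.array([0.50, -0.30, -0.20]) * brain
    ac = np.array([0.0, 0.16, 0.0]) * 2 * brain
    pc = np.array([0.0, -0.16, 0.0]) * 2 * brain
    return {
        "brain": brain, "csf_inner": csf_inner, "gm_inner": gm_inner,
        "vent": vent, "hip_half": hip_half, "hip_offset": hip_offset,
        "ac": ac, "pc": pc,
    }


def _canonical_phantom(age: float, shape, spacing, texture_amplitude: float):
    """Noise-free canonical anatomy at an age: volume, mask, labels, tissues,
    landmarks — all in the canonical (unperturbed) space."""
    affine = _grid_affine(shape, spacing)
    p = _anatomy_params(age, np.asarray(shape) * np.asarray(spacing))
    idx = np.indices(shape).astype(float)
    xyz = np.stack([
        idx[0] * spacing[0] + affine[0, 3],
        idx[1] * spacing[1] + affine[1, 3],
        idx[2] * spacing[2] + affine[2, 3],
    ], axis=-1)

    rho = np.sqrt(((xyz / p["brain"]) ** 2).sum(axis=-1))
    vol = np.zeros(shape, dtype=np.float64)
    tissue = np.zeros(shape, dtype=np.int32)
    vol[rho <= 1.0] = CSF_INTENSITY
    tissue[rho <= 1.0] = TISSUE_CSF
    vol[rho <= p["csf_inner"]] = GM_INTENSITY
    tissue[rho <= p["csf_inner"]] = TISSUE_GM
    vol[rho <= p["gm_inner"]] = WM_INTENSITY
    tissue[rho <= p["gm_inner"]] = TISSUE_WM

    labels = np.zeros(shape, dtype=np.int32)
    vent_rho = rho / p["vent"]
    vol[vent_rho <= 1.0] = CSF_INTENSITY
    tissue[vent_rho <= 1.0] = TISSUE_CSF
    labels[vent_rho <= 1.0] = LABEL_VENTRICLE

    for side in (+1.0, -1.0):
        c = p["hip_offset"] * np.array([side, 1.0, 1.0])
        hrho = np.sqrt((((xyz - c) / p["hip_half"]) ** 2).sum(axis=-1))
        inside = hrho <= 1.0
        vol[inside] = HIPPO_INTENSITY
        tissue[inside] = TISSUE_WM  # nearest intensity class
        labels[inside] = LABEL_HIPPOCAMPUS

    if texture_amplitude > 0:
        # smooth deterministic modulation so tissue interiors carry gradients
        L = float(np.min(np.asarray(shape) * np.asarray(spacing)))
        mod = 1.0 + texture_amplitude * (
            np.cos(2 * np.pi * xyz[..., 0] / L)
            * np.cos(2 * np.pi * xyz[..., 1] / (1.3 * L))
            * np.cos(2 * np.pi * xyz[..., 2] / (0.8 * L))
        )
        vol *= np.where(rho <= 1.0, mod, 1.0)

    mask = (rho <= 1.0).astype(np.uint8)
    landmarks = np.stack([p["ac"], p["pc"]])
    return (
        Volume(vol.astype(np.float32), affine),
        BrainMask(mask, affine),
        LabelMap(labels, affine, dict(LABEL_TABLE)),
        LabelMap(tissue, affine, {TISSUE_CSF: "csf", TISSUE_GM: "gm", TISSUE_WM: "wm"}),
        landmarks,
    )


def _random_smooth_warp(rng: np.random.Generator, shape, affine,
                        amplitude_mm: float, smoothness_mm: float,
                        brain: np.ndarray | None = None) -> DeformationField:
    """Gaussian-filtered white noise, scaled so the in-brain displacement
    reaches ``amplitude_mm`` (99th percentile); checked fold-free."""
    from scipy import ndimage as ndi

    spacing = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    sigma_vox = smoothness_mm / spacing
    # smooth Gaussian window centred on the grid keeps the field's energy
    # where the brain is, so border lobes cannot dominate the scaling
    idx = np.indices(shape).astype(float)
    ctr = (np.asarray(shape, float) - 1) / 2.0
    r2 = sum(((idx[a] - ctr[a]) / (0.5 * shape[a])) ** 2 for a in range(3))
    window = np.exp(-1.5 * r2)
    disp = np.empty(tuple(shape) + (3,))
    for c in range(3):
        w = rng.standard_normal(shape)
        w = ndi.gaussian_filter(w, sigma=sigma_vox, mode="nearest")
        disp[..., c] = w * window
    norms = np.linalg.norm(disp, axis=-1)
    ref = norms[brain > 0] if brain is not None and (brain > 0).any() else norms.ravel()
    q = float(np.quantile(ref, 0.99))
    if q > 0:
        disp *= amplitude_mm / q
    fld = DeformationField(disp, tuple(shape), affine)
    det = jacobian_determinant(fld).data
    if det.min() <= 0:
        raise ValueError("generated warp folds space; increase warp_smoothness")
    return fld


def generate_phantom(spec: PhantomSpec, out_dir: str | Path | None = None,
                     subject_id: str = "sub-000") -> tuple[SubjectRecord, GroundTruth]:
    """Generate one phantom acquisition and its ground truth.

    Deterministic for a fixed spec.  The subject image is the canonical
    age-specific anatomy seen through the recorded perturbation:
    ``I_subj(x) = I_canon(A(x + u(x)))`` with affine ``A`` and warp ``u``,
    then the scanner intensity transform and acquisition noise.

    If ``out_dir`` is given, volume/mask/labels are written as NIfTI and
    the returned record points at them; otherwise the record's paths are
    empty and the images live on the returned ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    vol, mask, labels, tissue, landmarks = _canonical_phantom(
        spec.age, shape, spec.spacing, spec.texture_amplitude
    )
    affine = vol.affine

    params = np.zeros(12) if spec.affine_jitter is None else np.asarray(spec.affine_jitter, float)
    A = AffineTransform(params, center=np.zeros(3))

    if spec.warp_amplitude > 0:
        warp = _random_smooth_warp(rng, shape, affine, spec.warp_amplitude,
                                   spec.warp_smoothness, brain=mask.data)
        chain = [A, warp]
    else:
        warp = None
        chain = [A]

    moved = apply_transform(vol, chain, shape, affine, interpolation="linear")
    moved_mask = apply_transform(mask, chain, shape, affine, interpolation="nearest")
    moved_labels = apply_transform(labels, chain, shape, affine, interpolation="nearest")
    moved_tissue = apply_transform(tissue, chain, shape, affine, interpolation="nearest")

    # subject-space landmark positions: p_s = T^{-1}(p_c) with T = A o (id+u)
    pts = landmarks @ A.inverse_matrix[:3, :3].T + A.inverse_matrix[:3, 3]
    if warp is not None:
        inv_warp = invert_field(warp)
        pts = inv_warp.apply_points(
            landmarks @ A.inverse_matrix[:3, :3].T + A.inverse_matrix[:3, 3]
        )
    moved_landmarks = np.atleast_2d(pts)

    scale, shift = SCANNER_EFFECTS[spec.scanner]
    data = moved.data.astype(np.float64) * scale + shift
    if spec.noise_sigma > 0:
        if spec.noise_model == "rician":
            re = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
            im = rng.normal(0.0, spec.noise_sigma, size=data.shape)
            data = np.sqrt(re * re + im * im)
        else:
            data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    subject_volume = Volume(data.astype(np.float32), affine)

    gt = GroundTruth(
        true_affine=A,
        true_warp=warp,
        labels=moved_labels,
        landmarks=moved_landmarks,
        tissue_partition=moved_tissue,
        noise_sigma=spec.noise_sigma,
        mask=moved_mask,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vpath = out_dir / f"{subject_id}_T1.nii.gz"
        mpath = out_dir / f"{subject_id}_mask.nii.gz"
        lpath = out_dir / f"{subject_id}_labels.nii.gz"
        write_volume(subject_volume, vpath)
        write_volume(moved_mask, mpath)
        write_volume(moved_labels, lpath)
        # store basenames: the manifest lives in the same directory and its
        # reader resolves relative paths against the manifest location
        record = SubjectRecord(subject_id, spec.age, "u", spec.scanner,
                               vpath.name, mpath.name, lpath.name)
    else:
        record = SubjectRecord(subject_id, spec.age, "u", spec.scanner, "", None, None)
    record.volume = subject_volume
    record.mask = moved_mask
    record.labels = moved_labels
    return record, gt


def generate_cohort(n: int, age_low: float = 18.0, age_high: float = 76.0,
                    seed: int = 0, scanners: tuple = ("siemens", "ge"),
                    out_dir: str | Path = "cohort",
                    grid_shape: tuple = (48, 48, 48),
                    spacing: tuple = (1.0, 1.0, 1.0),
                    noise_sigma: float = 3.0,
                    warp_amplitude: float = 1.5,
                    warp_smoothness: float = 8.0,
                    jitter_scale: float = 1.0) -> tuple[Cohort, list[GroundTruth]]:
    """Generate a cohort of phantoms with a manifest JSON on disk.

    Ages are evenly spread over [age_low, age_high] (deterministic given
    the seed); scanners are assigned round-robin; per-subject affine jitter
    draws translations within ±2 mm, rotations within ±0.04 rad, log-scales
    within ±0.03 and shears within ±0.02 (scaled by ``jitter_scale``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if age_low >= age_high:
        raise ValueError("age_low must be < age_high")
    rng = np.random.default_rng(seed)
    if n == 1:
        ages = np.array([(age_low + age_high) / 2.0])
    else:
        ages = np.linspace(age_low, age_high, n)
        ages = ages + rng.uniform(-0.5, 0.5, size=n) * (ages[1] - ages[0]) * 0.5
        ages = np.clip(ages, age_low, age_high)

    out_dir = Path(out_dir)
    subjects, gts = [], []
    for i in range(n):
        jitter = np.concatenate([
            rng.uniform(-2.0, 2.0, 3),
            rng.uniform(-0.04, 0.04, 3),
            rng.uniform(-0.03, 0.03, 3),
            rng.uniform(-0.02, 0.02, 3),
        ]) * jitter_scale
        spec = PhantomSpec(
            age=float(ages[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
            grid_shape=grid_shape,
            spacing=spacing,
            scanner=scanners[i % len(scanners)],
            noise_sigma=noise_sigma,
            affine_jitter=jitter,
            warp_amplitude=warp_amplitude,
            warp_smoothness=warp_smoothness,
        )
        rec, gt = generate_phantom(spec, out_dir=out_dir, subject_id=f"sub-{i:03d}")
        subjects.append(rec)
        gts.append(gt)
        # persist per-subject ground truth as JSON (affine params, landmarks, sigma)
        with open(out_dir / f"sub-{i:03d}_truth.json", "w") as fh:
            json.dump({
                "affine_parameters": gt.true_affine.parameters.tolist(),
                "landmarks": gt.landmarks.tolist(),
                "noise_sigma": gt.noise_sigma,
                "age": float(ages[i]),
            }, fh, indent=1)

    cohort = Cohort(subjects)
    write_manifest(cohort, out_dir / "manifest.json")
    cohort.manifest_path = str(out_dir / "manifest.json")
    return cohort, gts
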