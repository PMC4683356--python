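# atlasforge

Construction and validation of **age-conditioned brain templates** from a
cohort of 3-D MR-like volumes.

Population studies need a reference anatomy — a template — to put every
subject's brain into a common coordinate space. A single static template
misrepresents cohorts that span decades of ageing, and a template built from
one population misrepresents another: registering subjects to a mismatched
template demands large shape deformations and degrades atlas-based
segmentation. `atlasforge` implements the full pipeline for building a
*spatiotemporal* (age-indexed) template family from a multi-scanner cohort
and for quantifying exactly those two effects. It is aimed at researchers in
neuroimaging methods who want a compact, fully testable implementation of
the groupwise-template recipe.

## What it does

1. **Synthetic cohorts** (`synthetic_cohort`) — multi-scanner, age-varying
   ellipsoidal brain phantoms with complete ground truth: true affine and
   nonrigid perturbations, structure labels (ventricle- and
   hippocampus-analogs), tissue partition, AC/PC-analog landmarks, and known
   noise level. Every downstream stage is testable without any data
   download.
2. **Pre-processing** (`preprocess`) — automatic noise estimation
   (Laplacian pseudo-residuals, σ̂ = 1.4826·MAD) with threshold QC, and
   cross-scanner intensity standardization by full-CDF histogram matching
   to a reference histogram.
3. **Registration** (`registration`) — masked 12-parameter affine
   registration (translations t, rotations r, log-scales s, shears h;
   M = T·R·S·H about the mask centroid) and greedy diffeomorphic
   registration driven by windowed cross-correlation with Gaussian
   regularization (σ = 3 voxels) over three resolutions (≤ 50/50/10
   iterations), plus displacement-field composition, inversion, and
   Jacobian analysis. Fields keep det J > 0 everywhere.
4. **Atlas building** (`atlas_builder`) — kernel-regression age weighting
   w_i ∝ exp(−(a_i−t)²/2h²), iterative unbiased groupwise averaging (the
   average brain is the reference; no subject is elected; mean-transform
   drift correction), the 12-template age series (ages 20…75 step 5),
   template-level fusion into a population template, and 3-class
   Gaussian-mixture tissue probability maps.
5. **Validation** (`validation`) — Dice-scored atlas-based label
   propagation (DSC = 2|A∩B|/(|A|+|B|)) and template morphometry (AC–PC
   distance, length/width/height extents and their ratios) with paired
   two-sided t comparison of native vs template-registered brains.

## Worked example

```python
import numpy as np
from atlasforge import (generate_cohort, qc_filter, ReferenceHistogram,
                        match_histogram, build_template, dice,
                        segment_by_atlas, BuildConfig)
from atlasforge.synthetic_cohort import PhantomSpec, generate_phantom

# an 8-subject, two-scanner cohort, ages 18-76, 48 mm^3 field of view
cohort, truth = generate_cohort(8, 18, 76, seed=11, out_dir="cohort")

# QC: screen noisy acquisitions
kept, rejected, reports = qc_filter(cohort, sigma_threshold=10.0)
print(len(kept), "accepted,", len(rejected), "rejected")
# -> 8 accepted, 0 rejected      (every phantom was generated at sigma = 3)

# standardize intensities across scanners
ref_rec, _ = generate_phantom(PhantomSpec(age=47, seed=999, noise_sigma=0,
                                          warp_amplitude=0))
ref = ReferenceHistogram.from_volume(ref_rec.volume)
for rec in kept:
    rec.volume = match_histogram(rec.load_volume(), ref, rec.load_mask())

# a template conditioned on age 75
template = build_template(kept, target_age=75.0, config=BuildConfig())
print(np.round(template.provenance["weights"], 3))
# -> [0.    0.    0.    0.    0.    0.018 0.16  0.822]
#    the Gaussian age kernel (h = 5 y) concentrates on the oldest subjects

# atlas-based segmentation of a new 74-year-old subject
subject, gt = generate_phantom(PhantomSpec(age=74, seed=123))
seg = segment_by_atlas(template, template.labels, subject.volume,
                       subject_mask=gt.mask)
print(round(dice(seg, gt.labels, 2), 3))   # hippocampus-analog overlap
# -> 0.599
```

The kernel weights show why the age series copes with uneven age sampling:
subjects far from the target age contribute almost nothing. The Dice score
is one subject's hippocampus-analog overlap; the package's headline
validation is the paired version of this experiment in
`tests/test_acceptance.py`, where the age-matched template averages ≈ 0.78
over ten held-out aged subjects against ≈ 0.65 for an age-mismatched
(young) template under identical registration settings.

A CLI mirrors the library:

```bash
atlasforge simulate --n 8 --age-range 18:76 --seed 11 --grid 48 --out cohort/
atlasforge qc --manifest cohort/manifest.json --sigma-threshold 10 --report qc.tsv
atlasforge normalize --manifest cohort/manifest.json --reference ref.nii.gz --out-dir norm/
atlasforge build --manifest norm/manifest.json --age-grid 20:75:5 --out-dir atlases/
atlasforge segment --atlas atlases/template_75.nii.gz --labels labels.nii.gz \
                   --subject subj.nii.gz --out seg.nii.gz
atlasforge measure --mask mask.nii.gz --landmarks acpc.json --report morph.tsv
```

## Scope notes

Bias-field correction and brain orientation adjustment are assumed done
upstream (e.g. with N4); the CLI notes where to insert them. Sex-stratified
templates, multi-modal atlases, and Rician-bias intensity correction are
out of scope.
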