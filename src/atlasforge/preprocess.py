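"""Cohort pre-processing: automatic noise estimation with threshold QC, and
histogram standardization to a reference histogram.

Noise is estimated with a Laplacian pseudo-residual scheme: the volume is
convolved with the stencil (6 at the centre, -1 at the six face neighbours)
scaled by 1/sqrt(42) so the residual variance equals the noise variance on
a locally smooth image, and sigma is the scaled median absolute deviation
(1.4826 x MAD) of the residuals — robust to the sparse set of voxels that
sit on tissue edges.  The QC filter screens subjects whose estimated sigma
exceeds a threshold, reporting SNR (mean foreground intensity / sigma) for
information.

Cross-scanner intensity standardization is full-CDF quantile mapping of the
foreground intensities onto a reference histogram; the fitted monotone
transform is applied to every voxel, background included.

Bias-field correction is deliberately not part of this module: correct with
an external tool (e.g. N4) before QC if the data need it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_volume import BrainMask, Cohort, Volume, VolumeError

DEFAULT_BINS = 1024

# 6-connected Laplacian pseudo-residual stencil; sum of squared weights = 42
_PSEUDO_RESIDUAL_NORM = np.sqrt(42.0)


@dataclass
class QCReport:
    """Per-subject quality-control result."""

    subject_id: str
    noise_sigma_hat: float
    snr_hat: float
    accepted: bool
    threshold_used: float


@dataclass
class ReferenceHistogram:
    """Foreground intensity distribution of a reference image.

    ``cumulative[i]`` is the CDF at the right edge of bin ``i``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if np.any(np.diff(self.cumulative) < -1e-12) or abs(self.cumulative[-1] - 1) > 1e-9:
            raise ValueError("cumulative must be a non-decreasing CDF ending at 1")

    @classmethod
    def from_volume(cls, volume: Volume, mask: BrainMask | None = None,
                    n_bins: int = DEFAULT_BINS) -> "ReferenceHistogram":
        fg = _foreground_values(volume, mask)
        if fg.max() - fg.min() < 1e-12:
            raise VolumeError("constant foreground: reference histogram undefined")
        counts, edges = np.histogram(fg, bins=n_bins)
        cdf = np.cumsum(counts).astype(float)
        cdf /= cdf[-1]
        return cls(edges, counts.astype(float), cdf)

    @property
    def bin_width(self) -> float:
        return float(np.mean(np.diff(self.bin_edges)))


def _foreground_values(volume: Volume, mask: BrainMask | None) -> np.ndarray:
    if mask is not None:
        if not volume.same_grid_as(mask):
            raise VolumeError("volume and mask geometry disagree")
        return volume.data[mask.data > 0].astype(np.float64)
    # no mask: Otsu-split the volume into background and foreground
    from skimage.filters import threshold_otsu

    data = volume.data.astype(np.float64)
    if data.max() - data.min() < 1e-12:
        return data.ravel()
    thr = threshold_otsu(data)
    fg = data[data > thr]
    return fg if fg.size else data.ravel()


# ---------------------------------------------------------------------------
# Noise estimation + QC
# ---------------------------------------------------------------------------

def estimate_noise(volume: Volume, mask: BrainMask | None = None) -> float:
    """Estimate the additive-noise sigma of a volume.

    Pseudo-residuals r = (6 I - sum of 6 face neighbours)/sqrt(42) have
    Var r = sigma^2 for i.i.d. noise on a locally smooth image; the robust
    scale 1.4826 x MAD over the (optionally masked) residuals is returned.
    Invariant to adding a constant; equivariant to intensity scaling.
    """
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 1] = 6.0
    kernel[0, 1, 1] = kernel[2, 1, 1] = -1.0
    kernel[1, 0, 1] = kernel[1, 2, 1] = -1.0
    kernel[1, 1, 0] = kernel[1, 1, 2] = -1.0
    data = volume.data.astype(np.float64)
    res = ndimage.convolve(data, kernel, mode="reflect") / _PSEUDO_RESIDUAL_NORM
    if mask is not None:
        if not volume.same_grid_as(mask):
            raise VolumeError("volume and mask geometry disagree")
        if int(mask.data.sum()) < 27:
            raise VolumeError("mask too small for noise estimation (< 27 voxels)")
        # erode so every residual's stencil support lies inside the mask, and
        # drop voxels near tissue edges, where the pseudo-residual reflects
        # anatomy rather than noise
        core = ndimage.binary_erosion(mask.data > 0)
        smooth = ndimage.median_filter(data, size=3)
        grad = np.linalg.norm(np.stack(np.gradient(smooth)), axis=0)
        span = np.quantile(data, 0.999) - np.quantile(data, 0.001)
        flat = grad <= 0.05 * max(span, 1e-12)
        flat = ~ndimage.binary_dilation(~flat)
        sel = core & flat
        if int(sel.sum()) < 27:
            sel = core if core.any() else (mask.data > 0)
        vals = res[sel]
    else:
        vals = res.ravel()
    med = np.median(vals)
    sigma = 1.4826 * np.median(np.abs(vals - med))
    return float(sigma)


def qc_filter(cohort: Cohort, sigma_threshold: float
              ) -> tuple[Cohort, Cohort, list[QCReport]]:
    """Partition a cohort into accepted/rejected by estimated noise sigma.

    Accepted iff sigma_hat <= sigma_threshold; every subject receives a
    QCReport.  The result depends only on the per-subject estimates, not
    on cohort ordering.
    """
    if sigma_threshold <= 0:
        raise ValueError("sigma_threshold must be > 0")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    reports: list[QCReport] = []
    accepted, rejected = [], []
    for rec in cohort:
        vol = rec.load_volume()
        mask = rec.load_mask()
        # acquisition noise is judged on the whole field of view: the air
        # background carries the noise floor free of anatomy
        sigma = estimate_noise(vol, None)
        fg = _foreground_values(vol, mask)
        snr = float(fg.mean() / sigma) if sigma > 0 else float("inf")
        ok = sigma <= sigma_threshold
        reports.append(QCReport(rec.id, sigma, snr, ok, sigma_threshold))
        (accepted if ok else rejected).append(rec)
    if not accepted:
        warnings.warn("QC rejected every subject; accepted cohort is empty")
    return Cohort(accepted), Cohort(rejected), reports


def qc_reports_to_tsv(reports: list[QCReport], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [{"id": r.subject_id, "sigma_hat": r.noise_sigma_hat,
          "snr_hat": r.snr_hat, "accepted": r.accepted} for r in reports]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Histogram matching
# ---------------------------------------------------------------------------

def match_histogram(volume: Volume, reference: ReferenceHistogram,
                    mask: BrainMask | None = None) -> Volume:
    """Map a volume's intensities so its foreground CDF matches a reference.

    The transform is the monotone non-decreasing quantile map fitted on the
    foreground voxels and applied to all voxels (background passes through
    the same map, clamped at the fitted range).
    """
    fg = _foreground_values(volume, mask)
    if fg.max() - fg.min() < 1e-12:
        raise VolumeError("constant foreground: quantile mapping undefined")
    # empirical quantiles of the input foreground
    src = np.sort(fg)
    src_cdf = (np.arange(src.size) + 0.5) / src.size
    # reference quantile function: CDF value -> intensity (right bin edges)
    ref_cdf = np.concatenate([[0.0], reference.cumulative])
    ref_int = reference.bin_edges
    data = volume.data.astype(np.float64)
    # input intensity -> CDF (monotone), then CDF -> reference intensity
    u = np.interp(data.ravel(), src, src_cdf, left=src_cdf[0], right=src_cdf[-1])
    mapped = np.interp(u, ref_cdf, ref_int)
    return Volume(mapped.reshape(volume.shape).astype(np.float32), volume.affine)
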