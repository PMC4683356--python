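"""Masked affine and diffeomorphic registration.

The linear model is the classical 12-parameter full affine (3 translations,
3 rotations, 3 log-scales, 3 shears) optimised coarse-to-fine over a
three-level image pyramid with a gradient-free local search.

The nonrigid model is a greedy diffeomorphic scheme driven by the local
(windowed) cross-correlation metric: per iteration a CC-gradient update
field is computed inside the mask, Gaussian-smoothed, composed with the
current field via a small step, and the total field is Gaussian-smoothed
with the regularizer sigma.  The default schedule is three resolutions with
at most 50 iterations on the two coarse levels and 10 at full resolution,
and the output field is required to keep a strictly positive Jacobian
determinant (diffeomorphism contract).

Transforms map fixed-grid world points into moving-image world points
(pull-back convention): ``warped(x) = moving(T(x))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .core_volume import (
    BrainMask,
    LabelMap,
    Volume,
    VolumeError,
    _sample_at_world,
    target_world_points,
)


class RegistrationError(RuntimeError):
    """Registration failed to converge; message carries diagnostics."""


# ---------------------------------------------------------------------------
# Affine transform
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """12-parameter affine map of world coordinates.

    ``parameters`` is ``[tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz]``:
    translations in mm, rotations in radians, log-scales, shears.  The matrix
    is composed as T . R . S . Shear about ``center`` (world mm), with
    R = Rz @ Ry @ Rx:

        M(x) = t + c + R S H (x - c)

    The zero parameter vector is exactly the identity map.
    """

    parameters: np.ndarray
    center: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=float).ravel()
        if self.parameters.size != 12:
            raise ValueError("affine transform takes exactly 12 parameters")
        self.center = np.asarray(self.center, dtype=float).ravel()

    @property
    def matrix(self) -> np.ndarray:
        """The derived 4x4 world->world homogeneous matrix."""
        t = self.parameters[:3]
        rx, ry, rz = self.parameters[3:6]
        scale = np.exp(self.parameters[6:9])
        hxy, hxz, hyz = self.parameters[9:12]

        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        S = np.diag(scale)
        H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]], dtype=float)
        A = Rz @ Ry @ Rx @ S @ H
        M = np.eye(4)
        M[:3, :3] = A
        M[:3, 3] = t + self.center - A @ self.center
        return M

    @property
    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        M = self.matrix
        return np.atleast_2d(xyz) @ M[:3, :3].T + M[:3, 3]

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.tolist(),
            "center": self.center.tolist(),
            "matrix": self.matrix.tolist(),
        }


@dataclass
class DeformationField:
    """Dense displacement field u (mm, world RAS+) on a reference grid.

    The mapped point is ``x + u(x)``; the Jacobian determinant of that map
    must stay positive at every interior voxel.
    """

    displacement: np.ndarray
    reference_shape: tuple[int, int, int]
    reference_affine: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise VolumeError("displacement must be (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise VolumeError("displacement field contains NaN/Inf")
        self.reference_shape = tuple(int(s) for s in self.reference_shape)
        self.reference_affine = np.asarray(self.reference_affine, dtype=float)
        if self.displacement.shape[:3] != self.reference_shape:
            raise VolumeError("field shape disagrees with reference grid")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.reference_affine[:3, :3], axis=0)

    @classmethod
    def zero(cls, shape: Sequence[int], affine: np.ndarray) -> "DeformationField":
        return cls(np.zeros(tuple(shape) + (3,)), tuple(shape), affine)

    def sample(self, xyz: np.ndarray) -> np.ndarray:
        """Linearly interpolate the displacement (mm) at world points.

        Points beyond the reference grid take the nearest border value, so
        the field stays continuous across the boundary.
        """
        out = np.empty((np.atleast_2d(xyz).shape[0], 3))
        for c in range(3):
            out[:, c] = _sample_at_world(
                self.displacement[..., c], self.reference_affine, xyz,
                order=1, mode="nearest",
            )
        return out

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        return xyz + self.sample(xyz)


@dataclass
class RegistrationConfig:
    """Settings of the masked registration, defaulting to a cross-correlation
    metric, a Gaussian regularizer of sigma 3 voxels on the deformation
    field, and three resolutions with at most 50/50/10 iterations."""

    metric: str = "cross-correlation"
    cc_window_radius: int = 2
    # Gaussian regularizer sigma (voxels) applied to the CC-gradient update
    # field each iteration — the convention the reference deformable
    # registration tools use for their printed "sigma" setting
    regularizer_sigma: float = 3.0
    total_field_sigma: float = 0.5         # voxels, light smoothing of the total field
    n_levels: int = 3
    max_iterations_per_level: tuple = (50, 50, 10)
    step_size: float = 0.25                # voxels, max update per iteration
    convergence_tol: float = 1e-4          # metric change
    mask_policy: str = "fixed-mask"
    affine_max_evals: int = 400            # per optimisation stage

    def __post_init__(self) -> None:
        self.max_iterations_per_level = tuple(int(i) for i in self.max_iterations_per_level)
        if self.n_levels != len(self.max_iterations_per_level):
            raise ValueError("n_levels must equal len(max_iterations_per_level)")
        if self.regularizer_sigma <= 0:
            raise ValueError("regularizer_sigma must be > 0")
        if any(i < 1 for i in self.max_iterations_per_level):
            raise ValueError("iteration counts must be >= 1")
        if self.metric != "cross-correlation":
            raise ValueError("only the cross-correlation metric is supported")


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def _local_stats(fixed: np.ndarray, moving: np.ndarray, radius: int):
    """Windowed means/covariances with a (2r+1)^3 box filter."""
    size = 2 * radius + 1
    uf = lambda a: ndimage.uniform_filter(a, size=size, mode="nearest")
    fm = uf(fixed)
    mm = uf(moving)
    a = uf(fixed * moving) - fm * mm          # cov(F, M)
    b = uf(fixed * fixed) - fm * fm           # var(F)
    c = uf(moving * moving) - mm * mm         # var(M)
    return fm, mm, a, np.maximum(b, 0.0), np.maximum(c, 0.0)


def masked_cc(fixed: Volume, moving_warped: Volume, mask: BrainMask,
              window_radius: int = 2) -> float:
    """Local (windowed) cross-correlation averaged over mask voxels.

    Similarity in [-1, 1]; windows where either image is locally constant
    contribute 0.
    """
    if not (fixed.same_grid_as(moving_warped) and fixed.same_grid_as(mask)):
        raise VolumeError("masked_cc requires all images on one grid")
    m = mask.data > 0
    if not m.any():
        raise VolumeError("empty mask")
    F = fixed.data.astype(np.float64)
    M = moving_warped.data.astype(np.float64)
    _, _, a, b, c = _local_stats(F, M, window_radius)
    denom = np.sqrt(b * c)
    cc = np.zeros_like(a)
    ok = denom > 1e-9
    cc[ok] = a[ok] / denom[ok]
    return float(np.clip(cc[m], -1.0, 1.0).mean())


def _masked_ncc(fixed: np.ndarray, warped: np.ndarray, mask: np.ndarray) -> float:
    """Global normalized correlation inside the mask (affine objective)."""
    f = fixed[mask]
    w = warped[mask]
    f = f - f.mean()
    w = w - w.mean()
    denom = np.sqrt((f * f).sum() * (w * w).sum())
    if denom < 1e-12:
        return 0.0
    return float((f * w).sum() / denom)


# ---------------------------------------------------------------------------
# Pyramid helpers
# ---------------------------------------------------------------------------

def _downsample(data: np.ndarray, affine: np.ndarray, factor: int,
                order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Smooth-and-decimate by an integer factor; returns (data, affine)."""
    if factor == 1:
        return np.asarray(data, dtype=np.float64), affine
    sm = ndimage.gaussian_filter(np.asarray(data, dtype=np.float64),
                                 sigma=0.5 * factor, mode="nearest")
    sl = tuple(slice(None, None, factor) for _ in range(3))
    out = sm[sl]
    new_affine = affine.copy()
    new_affine[:3, :3] = affine[:3, :3] * factor
    return out, new_affine


def _pyramid_factors(n_levels: int, shape: Sequence[int]) -> list[int]:
    """Coarse-to-fine decimation factors, capped so grids stay >= 12 voxels."""
    factors = []
    for lvl in range(n_levels):
        f = 2 ** (n_levels - 1 - lvl)
        while f > 1 and min(shape) // f < 12:
            f //= 2
        factors.append(f)
    return factors


# ---------------------------------------------------------------------------
# Affine registration
# ---------------------------------------------------------------------------

_PARAM_SCALES = np.array([1.0, 1.0, 1.0,          # mm
                          0.02, 0.02, 0.02,        # rad
                          0.02, 0.02, 0.02,        # log-scale
                          0.02, 0.02, 0.02])       # shear


def _warp_affine(moving_data, moving_affine, params, center, xyz, shape, order=1):
    T = AffineTransform(params, center)
    mapped = T.apply_points(xyz)
    out = _sample_at_world(moving_data, moving_affine, mapped, order=order)
    return out.reshape(shape)


def affine_register(moving: Volume, fixed: Volume, mask: BrainMask,
                    config: RegistrationConfig | None = None) -> AffineTransform:
    """Masked 12-parameter affine registration, coarse-to-fine.

    Returns the transform ``T`` maximising masked similarity such that
    ``moving(T(x)) ~ fixed(x)``.  Deterministic: identity initialisation,
    translation-first coarse search, fixed pyramid and optimiser order.

    Raises
    ------
    RegistrationError
        If the optimum leaves the images essentially uncorrelated
        (non-overlapping fields of view).
    """
    config = config or RegistrationConfig()
    if not fixed.same_grid_as(mask):
        raise VolumeError("fixed image and mask must share a grid")
    center = mask.centroid_world()
    params = np.zeros(12)

    factors = _pyramid_factors(config.n_levels, fixed.shape)
    mov64 = moving.data.astype(np.float64)
    spacing = float(np.mean(fixed.spacing))

    # stages: which parameters are free at each pyramid level
    stages_per_level = {0: [slice(0, 3), slice(0, 6)],
                        1: [slice(0, 9)],
                        2: [slice(0, 12)]}

    for lvl, f in enumerate(factors):
        fdat, faff = _downsample(fixed.data, fixed.affine, f)
        # match the fixed level's blur on the moving side before sampling
        if f > 1:
            mov_lvl = ndimage.gaussian_filter(mov64, sigma=0.5 * f, mode="nearest")
        else:
            mov_lvl = mov64
        mdat, _ = _downsample(mask.data.astype(float), mask.affine, f)
        msk = mdat > 0.25
        if not msk.any():
            msk = np.ones(fdat.shape, dtype=bool)
        xyz = target_world_points(fdat.shape, faff)
        # the metric only reads mask voxels: sample just those
        xyz_m = xyz[msk.ravel()]
        fvec = fdat[msk]
        fvec = fvec - fvec.mean()
        fnorm = np.sqrt((fvec * fvec).sum()) + 1e-12

        def objective(free, free_slice):
            p = params.copy()
            p[free_slice] = free * _PARAM_SCALES[free_slice]
            mapped = AffineTransform(p, center).apply_points(xyz_m)
            w = _sample_at_world(mov_lvl, moving.affine, mapped, order=1)
            w = w - w.mean()
            denom = fnorm * (np.sqrt((w * w).sum()) + 1e-12)
            return -float((fvec * w).sum() / denom)

        if lvl == 0:
            # dense deterministic translation search, one coarse voxel apart
            best = (objective(params[:3] / _PARAM_SCALES[:3], slice(0, 3)), params[:3].copy())
            span = spacing * f * np.arange(-4, 5)
            for dx in span:
                for dy in span:
                    for dz in span:
                        cand = np.array([dx, dy, dz])
                        val = objective(cand / _PARAM_SCALES[:3], slice(0, 3))
                        if val < best[0]:
                            best = (val, cand)
            params[:3] = best[1]

        for free_slice in stages_per_level.get(lvl, [slice(0, 12)]):
            x0 = params[free_slice] / _PARAM_SCALES[free_slice]
            res = optimize.minimize(
                objective, x0, args=(free_slice,), method="Powell",
                options={"maxfev": config.affine_max_evals, "xtol": 1e-3,
                         "ftol": 1e-6, "disp": False},
            )
            params[free_slice] = res.x * _PARAM_SCALES[free_slice]

    # final similarity diagnostic on the full grid
    xyz = target_world_points(fixed.shape, fixed.affine)
    warped = _warp_affine(mov64, moving.affine, params, center, xyz, fixed.shape)
    final = _masked_ncc(fixed.data.astype(np.float64), warped, mask.data > 0)
    if final < 0.1:
        raise RegistrationError(
            f"affine registration failed to converge: final masked correlation "
            f"{final:.3f} < 0.1 (likely non-overlapping fields of view); "
            f"parameters={np.round(params, 3).tolist()}"
        )
    return AffineTransform(params, center)


# ---------------------------------------------------------------------------
# Field algebra
# ---------------------------------------------------------------------------

def jacobian_determinant(fld: DeformationField) -> Volume:
    """Jacobian determinant of x -> x + u(x) by central differences.

    Derivatives are taken in world mm along the grid axes; valid for the
    axis-aligned affines this package produces.
    """
    sp = fld.spacing
    u = fld.displacement
    J = np.zeros(u.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(u[..., comp], sp[0], sp[1], sp[2])
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    J += np.eye(3)
    det = np.linalg.det(J)
    return Volume(det.astype(np.float32), fld.reference_affine)


def compose_fields(f: DeformationField, g: DeformationField) -> DeformationField:
    """Composition ``phi_f o phi_g``: the map x -> f-map(g-map(x)).

    Displacement: ``u(x) = u_g(x) + u_f(x + u_g(x))`` (resample-then-add,
    world mm) on g's reference grid.
    """
    xyz = target_world_points(g.reference_shape, g.reference_affine)
    moved = xyz + g.displacement.reshape(-1, 3)
    uf = f.sample(moved)
    disp = (g.displacement.reshape(-1, 3) + uf).reshape(g.displacement.shape)
    return DeformationField(disp, g.reference_shape, g.reference_affine)


def invert_field(fld: DeformationField, max_iter: int = 50,
                 tol_voxels: float = 0.1) -> DeformationField:
    """Fixed-point inversion: find v with v(x) = -u(x + v(x)).

    Raises :class:`RegistrationError` if the max residual displacement of
    the composition exceeds ``tol_voxels`` after ``max_iter`` sweeps.
    """
    xyz = target_world_points(fld.reference_shape, fld.reference_affine)
    v = np.zeros_like(fld.displacement).reshape(-1, 3)
    sp = float(np.min(fld.spacing))
    for _ in range(max_iter):
        u_at = fld.sample(xyz + v)
        v_new = -u_at
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < 0.01 * sp:
            break
    residual = np.abs(fld.sample(xyz + v) + v).max() / sp
    if residual > tol_voxels:
        raise RegistrationError(
            f"field inversion did not converge: max residual {residual:.3f} voxels "
            f"> {tol_voxels}"
        )
    return DeformationField(v.reshape(fld.displacement.shape),
                            fld.reference_shape, fld.reference_affine)


# ---------------------------------------------------------------------------
# Diffeomorphic registration
# ---------------------------------------------------------------------------

def _cc_force(F: np.ndarray, W: np.ndarray, spacing: np.ndarray, radius: int) -> np.ndarray:
    """Gradient of the windowed CC^2 metric w.r.t. displacement (ascent).

    Standard local-correlation force: with A = cov(F, W), B = var(F),
    C = var(W), d(A^2/(BC))/dW = 2A/(BC) [ (F - Fbar) - (A/C)(W - Wbar) ],
    chained through the moving image gradient.
    """
    fm, wm, a, b, c = _local_stats(F, W, radius)
    eps = 1e-5 * (F.std() ** 2 + 1e-12)
    bc = b * c
    ok = (b > eps) & (c > eps)
    coef = np.zeros_like(a)
    coef[ok] = 2.0 * a[ok] / (bc[ok] + 1e-12)
    term = np.zeros_like(a)
    term[ok] = (F - fm)[ok] - (a[ok] / (c[ok] + 1e-12)) * (W - wm)[ok]
    scalar = coef * term
    g = np.gradient(W, spacing[0], spacing[1], spacing[2])
    force = np.stack([scalar * g[0], scalar * g[1], scalar * g[2]], axis=-1)
    return force


def _warp_with_field(mov_data, mov_affine, fld: DeformationField, order=1) -> np.ndarray:
    xyz = target_world_points(fld.reference_shape, fld.reference_affine)
    mapped = xyz + fld.displacement.reshape(-1, 3)
    out = _sample_at_world(np.asarray(mov_data, np.float64), mov_affine, mapped, order=order)
    return out.reshape(fld.reference_shape)


def _smooth_field(disp: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return disp
    out = np.empty_like(disp)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(disp[..., c], sigma=sigma_vox, mode="nearest")
    return out


def _min_jacobian(disp: np.ndarray, shape, affine) -> float:
    det = jacobian_determinant(DeformationField(disp, shape, affine)).data
    interior = det[1:-1, 1:-1, 1:-1]
    return float(interior.min()) if interior.size else float(det.min())


def diffeo_register(moving: Volume, fixed: Volume, mask: BrainMask,
                    config: RegistrationConfig | None = None) -> DeformationField:
    """Greedy masked diffeomorphic registration with the CC metric.

    The caller is expected to have applied affine pre-alignment; the output
    field lives on the fixed grid and satisfies the positive-Jacobian
    contract.  Deterministic for fixed inputs and config.
    """
    config = config or RegistrationConfig()
    if not (fixed.same_grid_as(moving) and fixed.same_grid_as(mask)):
        raise VolumeError("diffeo_register requires moving/fixed/mask on one grid")
    if not (mask.data > 0).any():
        raise VolumeError("empty mask")

    factors = _pyramid_factors(config.n_levels, fixed.shape)
    fld: DeformationField | None = None

    for lvl, f in enumerate(factors):
        fdat, faff = _downsample(fixed.data, fixed.affine, f)
        mdat, _ = _downsample(moving.data, moving.affine, f)
        mskdat, _ = _downsample(mask.data.astype(float), mask.affine, f)
        msk = mskdat > 0.25
        if not msk.any():
            msk = np.ones(fdat.shape, dtype=bool)
        sp = np.linalg.norm(faff[:3, :3], axis=0)
        shape = fdat.shape

        if fld is None:
            disp = np.zeros(shape + (3,))
        else:  # upsample the previous level's field onto this grid
            xyz = target_world_points(shape, faff)
            disp = fld.sample(xyz).reshape(shape + (3,))
        fld = DeformationField(disp, shape, faff)

        step_mm = config.step_size * float(np.min(sp))
        max_step_mm = 0.4 * float(np.min(sp))  # fold guard per iteration
        prev_cc = -np.inf
        best_disp = fld.displacement.copy()
        best_cc = -np.inf

        for _ in range(config.max_iterations_per_level[lvl]):
            W = _warp_with_field(mdat, faff, fld)
            F = fdat
            cc_val = _masked_ncc_local(F, W, msk, config.cc_window_radius)
            if cc_val > best_cc:
                best_cc = cc_val
                best_disp = fld.displacement.copy()
            if cc_val - prev_cc < config.convergence_tol and prev_cc > -np.inf:
                break
            prev_cc = cc_val

            force = _cc_force(F, W, sp, config.cc_window_radius)
            force[~msk] = 0.0
            force = _smooth_field(force, config.regularizer_sigma)
            mag = np.linalg.norm(force, axis=-1).max()
            if mag < 1e-12:
                break
            delta = force * (min(step_mm, max_step_mm) / mag)

            # compose: phi_new = phi o (id + delta), then regularize the total
            scale = 1.0
            for _try in range(8):
                step = delta * scale
                xyz = target_world_points(shape, faff)
                u_at = fld.sample(xyz + step.reshape(-1, 3)).reshape(shape + (3,))
                new_disp = step + u_at
                new_disp = _smooth_field(new_disp, config.total_field_sigma)
                if _min_jacobian(new_disp, shape, faff) > 0.05:
                    fld = DeformationField(new_disp, shape, faff)
                    break
                scale *= 0.5
            else:
                warnings.warn("diffeo step kept folding space; stopping level early")
                break

        # keep the best-scoring field of the level (metric monotonicity)
        W = _warp_with_field(mdat, faff, fld)
        if _masked_ncc_local(fdat, W, msk, config.cc_window_radius) < best_cc:
            fld = DeformationField(best_disp, shape, faff)

    assert fld is not None
    # resample to the full-resolution grid if the last level was decimated
    if fld.reference_shape != tuple(fixed.shape):
        xyz = target_world_points(fixed.shape, fixed.affine)
        disp = fld.sample(xyz).reshape(tuple(fixed.shape) + (3,))
        fld = DeformationField(disp, tuple(fixed.shape), fixed.affine)
    mj = _min_jacobian(fld.displacement, fld.reference_shape, fld.reference_affine)
    if mj <= 0:
        # final safety regularization; the iteration guard makes this rare
        disp = _smooth_field(fld.displacement, max(config.total_field_sigma, 1.0))
        fld = DeformationField(disp, fld.reference_shape, fld.reference_affine)
        mj = _min_jacobian(fld.displacement, fld.reference_shape, fld.reference_affine)
        if mj <= 0:
            raise RegistrationError(f"deformation folded space (min |J| = {mj:.3f})")
    return fld


def _masked_ncc_local(F: np.ndarray, W: np.ndarray, mask: np.ndarray, radius: int) -> float:
    _, _, a, b, c = _local_stats(F, W, radius)
    denom = np.sqrt(b * c)
    cc = np.zeros_like(a)
    ok = denom > 1e-9
    cc[ok] = a[ok] / denom[ok]
    return float(np.clip(cc[mask], -1, 1).mean())


# ---------------------------------------------------------------------------
# Transform application
# ---------------------------------------------------------------------------

Transform = "AffineTransform | DeformationField | np.ndarray"


def _map_points(transform, xyz: np.ndarray) -> np.ndarray:
    if isinstance(transform, AffineTransform):
        return transform.apply_points(xyz)
    if isinstance(transform, DeformationField):
        return transform.apply_points(xyz)
    M = np.asarray(transform, dtype=float)
    if M.shape == (4, 4):
        return np.atleast_2d(xyz) @ M[:3, :3].T + M[:3, 3]
    raise TypeError(f"unsupported transform {type(transform)!r}")


def apply_transform(image: Volume | LabelMap | BrainMask,
                    transform,
                    target_shape: Sequence[int],
                    target_affine: np.ndarray,
                    interpolation: str = "linear"):
    """Resample an image through a transform (or chain of transforms).

    ``transform`` may be a single AffineTransform / DeformationField / 4x4
    matrix or a list of them; a list ``[T1, T2]`` maps target points as
    ``T1(T2(x))``.  Label maps and masks must use nearest interpolation and
    never acquire label ids absent from the input.
    """
    is_label = isinstance(image, (LabelMap, BrainMask))
    if is_label and interpolation != "nearest":
        raise VolumeError("label/mask images must be warped with nearest interpolation")
    order = 0 if interpolation == "nearest" else 1
    xyz = target_world_points(target_shape, target_affine)
    chain = transform if isinstance(transform, (list, tuple)) else [transform]
    for t in reversed(chain):
        xyz = _map_points(t, xyz)
    out = _sample_at_world(image.data, image.affine, xyz, order=order)
    out = out.reshape(tuple(target_shape[:3]))
    ta = np.asarray(target_affine, dtype=float)
    if isinstance(image, LabelMap):
        return LabelMap(np.round(out).astype(np.int32), ta, dict(image.label_table))
    if isinstance(image, BrainMask):
        return BrainMask(np.round(out).astype(np.uint8), ta)
    return Volume(out.astype(np.float32), ta)
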