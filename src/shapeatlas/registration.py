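"""Groupwise registration of binary shapes under four geometric models.

Transforms are parameterized as forward maps of physical points about the
window center c:

    rigid       x' = R(phi, vphi, psi) (x - c) + c + t
    similarity  x' = K_h R (x - c) + c + t
    affine      x' = M (x - c) + c + t
    demons      dense per-voxel displacement field (pull convention)

with R = Rz(phi) . Ry(vphi) . Rx(psi).  Optimization minimizes the sum of
squared differences between Gaussian-smoothed float copies of the masks,
with a derivative-free (Powell) search started from centroid alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import ContentError, DomainError, FrameError
from .volumes import BinaryVolume, VolumeGrid, assert_common_frame

__all__ = [
    "RigidParams",
    "SimilarityParams",
    "AffineParams",
    "DeformationField",
    "RegistrationResult",
    "RegistrationOptions",
    "ssd",
    "register",
    "register_demons",
    "apply_params",
    "select_reference",
    "coregister_sample",
]

Model = Literal["rigid", "similarity", "affine", "demons"]


def _wrap_angle(a: float) -> float:
    """Wrap into (-pi, pi]."""
    a = float((a + math.pi) % (2 * math.pi) - math.pi)
    return math.pi if a == -math.pi else a


@dataclass(frozen=True)
class RigidParams:
    """Six free parameters: rotation angles (z, y, x order) and translation."""

    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "angles", tuple(_wrap_angle(a) for a in self.angles))
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))

    def rotation_matrix(self) -> np.ndarray:
        phi, vphi, psi = self.angles
        cz, sz = math.cos(phi), math.sin(phi)
        cy, sy = math.cos(vphi), math.sin(vphi)
        cx, sx = math.cos(psi), math.sin(psi)
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
        ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
        rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
        return rz @ ry @ rx

    def as_vector(self) -> np.ndarray:
        return np.array(self.angles + self.translation, dtype=float)


@dataclass(frozen=True)
class SimilarityParams:
    """Rigid motion plus homothety constant K_h: seven free parameters."""

    rigid: RigidParams = field(default_factory=RigidParams)
    k_h: float = 1.0

    def __post_init__(self):
        if self.k_h <= 0:
            raise DomainError(f"homothety constant must be > 0, got {self.k_h}")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.rigid.as_vector(), [self.k_h]])


@dataclass(frozen=True)
class AffineParams:
    """Unrestricted 3x3 matrix plus translation: twelve free parameters."""

    matrix: tuple = ((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0))
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise DomainError("affine matrix must be 3x3")
        if abs(np.linalg.det(m)) <= 1e-8:
            raise DomainError("affine matrix is singular")
        object.__setattr__(self, "matrix", tuple(tuple(row) for row in m))
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [np.asarray(self.matrix, dtype=float).ravel(), self.translation]
        )


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on a grid, pull convention."""

    grid: VolumeGrid
    displacement: np.ndarray  # dims + (3,)

    def __post_init__(self):
        u = np.asarray(self.displacement, dtype=np.float32)
        if u.shape != self.grid.dims + (3,):
            raise FrameError(
                f"displacement shape {u.shape} != {self.grid.dims + (3,)}"
            )
        if not np.isfinite(u).all():
            raise ContentError("displacement field must be finite")
        self.displacement = u

    def as_vector(self) -> np.ndarray:
        return self.displacement.ravel()


TransformParams = RigidParams | SimilarityParams | AffineParams | DeformationField


@dataclass
class RegistrationResult:
    params: TransformParams
    final_ssd: float
    converged: bool
    iterations: int
    initial_ssd: float = float("nan")


@dataclass(frozen=True)
class RegistrationOptions:
    """Optimizer settings shared by all parametric models."""

    sigma: float = 1.0          # Gaussian smoothing of masks, voxels
    maxiter: int = 20           # Powell outer iterations
    xtol: float = 5e-3
    ftol: float = 1e-3
    demons_iterations: int = 50
    demons_sigma_field: float = 1.5  # field regularization, voxels
    demons_step_cap: float = 2.0     # max per-iteration update, voxels


# ---------------------------------------------------------------------------
# Transform application
# ---------------------------------------------------------------------------


def _linear_part(params: TransformParams) -> tuple[np.ndarray, np.ndarray]:
    """(A, t) such that forward map is x' = A (x - c) + c + t."""
    if isinstance(params, RigidParams):
        return params.rotation_matrix(), np.asarray(params.translation)
    if isinstance(params, SimilarityParams):
        return (
            params.k_h * params.rigid.rotation_matrix(),
            np.asarray(params.rigid.translation),
        )
    if isinstance(params, AffineParams):
        return np.asarray(params.matrix, dtype=float), np.asarray(params.translation)
    raise DomainError(f"not a parametric transform: {type(params).__name__}")


def _source_positions(grid: VolumeGrid, params: TransformParams) -> np.ndarray:
    """Physical source position T^{-1}(y) for every output voxel center y."""
    pos = grid.index_grid_physical()
    if isinstance(params, DeformationField):
        assert_common_frame([params.grid, grid])
        return pos + params.displacement
    a, t = _linear_part(params)
    ainv = np.linalg.inv(a)
    c = grid.center
    return (pos - c - t) @ ainv.T + c


def _resample(values: np.ndarray, grid: VolumeGrid, src_pos: np.ndarray, order: int,
              cval: float = 0.0) -> np.ndarray:
    idx = grid.physical_to_index(src_pos)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        values, coords, order=order, mode="constant", cval=cval, prefilter=False
    )


def apply_params(vol: BinaryVolume, params: TransformParams) -> BinaryVolume:
    """Nearest-neighbour resampling of the indicator under the transform."""
    if _is_identity(params):
        return BinaryVolume(vol.grid, vol.occupancy.copy())
    src = _source_positions(vol.grid, params)
    out = _resample(vol.occupancy.astype(np.float32), vol.grid, src, order=0)
    return BinaryVolume(vol.grid, (out > 0.5).astype(np.uint8))


def _is_identity(params: TransformParams) -> bool:
    if isinstance(params, DeformationField):
        return not params.displacement.any()
    a, t = _linear_part(params)
    return np.allclose(a, np.eye(3), atol=1e-15) and np.allclose(t, 0, atol=1e-15)


# ---------------------------------------------------------------------------
# Similarity function
# ---------------------------------------------------------------------------


def ssd(moving, fixed) -> float:
    """Sum of squared voxel differences (fixed - moving)^2."""
    assert_common_frame([moving, fixed])
    a = _values(moving).astype(np.float64)
    b = _values(fixed).astype(np.float64)
    return float(np.sum((b - a) ** 2))


def _values(vol) -> np.ndarray:
    if isinstance(vol, BinaryVolume):
        return vol.occupancy
    return np.asarray(vol.prob if hasattr(vol, "prob") else vol.distance)


def _smooth(vol: BinaryVolume, sigma: float) -> np.ndarray:
    img = vol.occupancy.astype(np.float32)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma)
    return img


# ---------------------------------------------------------------------------
# Parametric registration
# ---------------------------------------------------------------------------


def _params_from_vector(model: str, x: np.ndarray) -> TransformParams:
    if model == "rigid":
        return RigidParams(tuple(x[:3]), tuple(x[3:6]))
    if model == "similarity":
        return SimilarityParams(RigidParams(tuple(x[:3]), tuple(x[3:6])), float(x[6]))
    if model == "affine":
        return AffineParams(x[:9].reshape(3, 3), tuple(x[9:12]))
    raise DomainError(f"unknown model {model!r}")


def _centroid(vol: BinaryVolume) -> np.ndarray:
    idx = np.argwhere(vol.occupancy > 0)
    return vol.grid.index_to_physical(idx.mean(axis=0))


def register(
    moving: BinaryVolume,
    fixed: BinaryVolume,
    model: Model = "rigid",
    opts: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Fit a rigid / similarity / affine transform minimizing smoothed SSD.

    The similarity model is fitted in batches of two successive steps (six
    rigid parameters, then the homothety constant).  The returned transform
    never increases the SSD relative to identity: on optimizer failure the
    identity transform is returned with ``converged=False``.
    """
    if model not in ("rigid", "similarity", "affine"):
        raise DomainError(f"unknown registration model {model!r}")
    assert_common_frame([moving, fixed])
    if moving.empty or fixed.empty:
        raise ContentError("cannot register an empty shape")
    opts = opts or RegistrationOptions()

    mov = _smooth(moving, opts.sigma)
    fix = _smooth(fixed, opts.sigma)
    grid = moving.grid
    pos = grid.index_grid_physical()
    c = grid.center

    def objective(x: np.ndarray) -> float:
        p = _vector_to_params_safe(model, x)
        if p is None:
            return np.inf
        a, t = _linear_part(p)
        src = (pos - c - t) @ np.linalg.inv(a).T + c
        warped = _resample(mov, grid, src, order=1)
        return float(np.sum((fix - warped) ** 2))

    t0 = _centroid(fixed) - _centroid(moving)
    ident = np.zeros(6)
    start = np.concatenate([np.zeros(3), t0])
    initial_ssd = objective(_full_vector(model, ident))
    if initial_ssd == 0.0:  # already identical; nothing to optimize
        identity = _params_from_vector(model, _full_vector(model, ident))
        return RegistrationResult(identity, 0.0, True, 0, 0.0)

    nfev = 0
    if model == "similarity":
        x, n = _optimize_similarity(objective, start, opts)
        nfev += n
    else:
        xfull = _full_vector(model, start)
        res = optimize.minimize(
            objective, xfull, method="Powell",
            options={"maxiter": opts.maxiter, "xtol": opts.xtol, "ftol": opts.ftol},
        )
        x, nfev = res.x, res.nfev
        # retry from pure identity if centroid start went wrong
        if res.fun > initial_ssd:
            res2 = optimize.minimize(
                objective, _full_vector(model, ident), method="Powell",
                options={"maxiter": opts.maxiter, "xtol": opts.xtol, "ftol": opts.ftol},
            )
            nfev += res2.nfev
            if res2.fun < res.fun:
                x = res2.x

    final = objective(x)
    if final <= initial_ssd:
        params = _params_from_vector(model, np.asarray(x, dtype=float))
        return RegistrationResult(params, final, True, nfev, initial_ssd)
    identity = _params_from_vector(model, _full_vector(model, ident))
    return RegistrationResult(identity, initial_ssd, False, nfev, initial_ssd)


def _full_vector(model: str, rigid6: np.ndarray) -> np.ndarray:
    """Embed a 6-vector (angles, translation) into the model's vector."""
    if model == "rigid":
        return np.asarray(rigid6, dtype=float)
    if model == "similarity":
        return np.concatenate([rigid6, [1.0]])
    if model == "affine":
        r = RigidParams(tuple(rigid6[:3]), tuple(rigid6[3:6]))
        return np.concatenate([r.rotation_matrix().ravel(), rigid6[3:6]])
    raise DomainError(model)


def _vector_to_params_safe(model: str, x: np.ndarray):
    try:
        return _params_from_vector(model, np.asarray(x, dtype=float))
    except (DomainError, np.linalg.LinAlgError):
        return None


def _optimize_similarity(objective, start6, opts: RegistrationOptions):
    """Two-stage batches: rigid parameters, then the homothety constant."""
    rigid6 = np.asarray(start6, dtype=float)
    k = 1.0
    nfev = 0
    powell = {"maxiter": opts.maxiter, "xtol": opts.xtol, "ftol": opts.ftol}
    for _ in range(2):  # two batches of the two successive steps
        res = optimize.minimize(
            lambda r6: objective(np.concatenate([r6, [k]])), rigid6,
            method="Powell", options=powell,
        )
        rigid6, nfev = res.x, nfev + res.nfev
        resk = optimize.minimize_scalar(
            lambda kk: objective(np.concatenate([rigid6, [kk]])),
            bounds=(max(0.3, k - 0.5), k + 0.5),
            method="bounded", options={"xatol": 1e-4, "maxiter": 60},
        )
        if np.isfinite(resk.fun):
            k = float(resk.x)
        nfev += resk.nfev
    return np.concatenate([rigid6, [k]]), nfev


# ---------------------------------------------------------------------------
# Demons
# ---------------------------------------------------------------------------


def register_demons(
    moving: BinaryVolume,
    fixed: BinaryVolume,
    opts: RegistrationOptions | None = None,
) -> tuple[DeformationField, RegistrationResult]:
    """Symmetric-forces demons with Gaussian field regularization.

    Returns the displacement field (mm, pull convention) attaining the best
    SSD seen over the iterations; identical inputs give the identity field.
    """
    assert_common_frame([moving, fixed])
    opts = opts or RegistrationOptions()
    grid = moving.grid
    spacing = np.asarray(grid.spacing)

    mov = _smooth(moving, opts.sigma)
    fix = _smooth(fixed, opts.sigma)
    grad_fix = np.stack(np.gradient(fix, *grid.spacing), axis=-1)

    pos = grid.index_grid_physical()
    u = np.zeros(grid.dims + (3,), dtype=np.float32)
    initial_ssd = float(np.sum((fix - mov) ** 2))
    best_ssd, best_u = initial_ssd, u.copy()
    cap = opts.demons_step_cap * float(spacing.min())

    for it in range(opts.demons_iterations):
        warped = _resample(mov, grid, pos + u, order=1)
        cur_ssd = float(np.sum((fix - warped) ** 2))
        if cur_ssd < best_ssd:
            best_ssd, best_u = cur_ssd, u.copy()
        diff = warped - fix
        grad_warp = np.stack(np.gradient(warped, *grid.spacing), axis=-1)
        j = grad_fix + grad_warp
        jj = np.sum(j * j, axis=-1)
        denom = jj + diff * diff
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(denom > 1e-9, -2.0 * diff / denom, 0.0)
        step = j * scale[..., None]
        norm = np.sqrt(np.sum(step * step, axis=-1))
        over = norm > cap
        if over.any():
            step[over] *= (cap / norm[over])[..., None]
        u = u + step.astype(np.float32)
        for a in range(3):
            u[..., a] = ndimage.gaussian_filter(u[..., a], opts.demons_sigma_field)

    warped = _resample(mov, grid, pos + u, order=1)
    cur_ssd = float(np.sum((fix - warped) ** 2))
    if cur_ssd < best_ssd:
        best_ssd, best_u = cur_ssd, u

    field_obj = DeformationField(grid, best_u)
    result = RegistrationResult(
        field_obj, best_ssd, best_ssd <= initial_ssd, opts.demons_iterations,
        initial_ssd,
    )
    return field_obj, result


# ---------------------------------------------------------------------------
# Groupwise alignment
# ---------------------------------------------------------------------------


def _register_any(moving, fixed, model: Model, opts) -> RegistrationResult:
    if model == "demons":
        return register_demons(moving, fixed, opts)[1]
    return register(moving, fixed, model, opts)


def select_reference(
    sample: Sequence[BinaryVolume],
    model: Model = "rigid",
    opts: RegistrationOptions | None = None,
    _cache: dict | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the reference with the smallest mean final SSD over the sample.

    Every shape is registered to every candidate reference; self terms are
    excluded from the average and ties break toward the lowest index.
    """
    n = len(sample)
    if n < 1:
        raise DomainError("sample must contain at least one shape")
    for i, s in enumerate(sample):
        if s.empty:
            raise ContentError(f"shape {i} is empty")
    assert_common_frame(list(sample))
    matrix = np.zeros((n, n))
    for ref in range(n):
        for i in range(n):
            if i == ref:
                continue
            res = _register_any(sample[i], sample[ref], model, opts)
            matrix[i, ref] = res.final_ssd
            if _cache is not None:
                _cache[(i, ref)] = res
    if n == 1:
        return 0, matrix
    means = (matrix.sum(axis=0)) / (n - 1)
    return int(np.argmin(means)), matrix


def coregister_sample(
    sample: Sequence[BinaryVolume],
    model: Model = "rigid",
    opts: RegistrationOptions | None = None,
    reference: int | None = None,
) -> tuple[list[BinaryVolume], int, list[RegistrationResult]]:
    """Register every shape to the (auto-selected) reference and resample."""
    n = len(sample)
    if n < 2:
        raise DomainError("coregistration needs at least two shapes")
    cache: dict = {}
    if reference is None:
        ref, _ = select_reference(sample, model, opts, _cache=cache)
    else:
        ref = int(reference)
        if not (0 <= ref < n):
            raise DomainError(f"reference index {ref} out of range")
    aligned: list[BinaryVolume] = []
    results: list[RegistrationResult] = []
    identity = RegistrationResult(RigidParams(), 0.0, True, 0, 0.0)
    for i, shape in enumerate(sample):
        if i == ref:
            aligned.append(shape)
            results.append(identity)
            continue
        res = cache.get((i, ref)) or _register_any(shape, sample[ref], model, opts)
        aligned.append(apply_params(shape, res.params))
        results.append(res)
    return aligned, ref, results
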