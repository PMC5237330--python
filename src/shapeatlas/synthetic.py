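"""Reproducible populations of organ-like binary shapes.

A base blob (sphere plus smooth lobes) is pushed through per-case random
similarity/affine perturbations and a smooth random displacement field to
emulate inter-subject variability.  Every output is a pure function of the
specification (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .registration import (
    AffineParams,
    RigidParams,
    SimilarityParams,
    TransformParams,
    _linear_part,
    _resample,
    apply_params,
)
from .volumes import BinaryVolume, VolumeGrid

__all__ = ["PopulationSpec", "make_base_shape", "make_population", "apply_known_transform"]


@dataclass(frozen=True)
class PopulationSpec:
    n_cases: int = 8
    grid: VolumeGrid = field(
        default_factory=lambda: VolumeGrid((64, 64, 64), (1.5, 1.5, 1.5))
    )
    base_radius: float = 30.0       # mm
    lobe_count: int = 3
    pose_sd: tuple[float, float] = (0.05, 2.0)   # (rotation rad, translation mm)
    scale_sd: float = 0.0           # log-scale std dev
    affine_sd: float = 0.0          # off-identity matrix entries
    warp_amp: float = 0.0           # mm, RMS displacement magnitude
    warp_smoothness: float = 6.0    # mm correlation length
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise SpecError("n_cases must be >= 1")
        for name in ("base_radius", "scale_sd", "affine_sd", "warp_amp",
                     "warp_smoothness"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if any(v < 0 for v in self.pose_sd):
            raise SpecError("pose_sd entries must be >= 0")


def _margin_mm(spec: PopulationSpec) -> float:
    return spec.warp_amp + 3.0 * spec.pose_sd[1] + 2.0 * max(spec.grid.spacing)


def _check_clear_of_boundary(occ: np.ndarray, what: str) -> None:
    if (
        occ[0].any() or occ[-1].any()
        or occ[:, 0].any() or occ[:, -1].any()
        or occ[:, :, 0].any() or occ[:, :, -1].any()
    ):
        raise SpecError(f"{what} touches the grid boundary; enlarge the window")


def make_base_shape(spec: PopulationSpec) -> BinaryVolume:
    """Connected smooth blob: ball of base_radius plus lobe_count protrusions."""
    grid = spec.grid
    extent = min(d * s for d, s in zip(grid.dims, grid.spacing))
    if 2 * spec.base_radius >= extent:
        raise SpecError(
            f"base_radius {spec.base_radius} mm does not fit a window of "
            f"{extent} mm"
        )
    rng = np.random.default_rng(spec.seed)
    pos = grid.index_grid_physical()
    c = grid.center
    r = np.linalg.norm(pos - c, axis=-1)
    occ = r <= spec.base_radius
    for _ in range(spec.lobe_count):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        lobe_r = spec.base_radius * rng.uniform(0.3, 0.5)
        center = c + direction * spec.base_radius * rng.uniform(0.7, 0.9)
        occ |= np.linalg.norm(pos - center, axis=-1) <= lobe_r
    # smooth the union into one blob, keeping binarity
    sigma_vox = 1.0
    smoothed = ndimage.gaussian_filter(occ.astype(np.float32), sigma_vox)
    occ = smoothed > 0.5
    m = max(int(np.ceil(_margin_mm(spec) / min(grid.spacing))), 1)
    core = occ[m:-m, m:-m, m:-m]
    if not core.size or core.sum() != occ.sum():
        raise SpecError(
            "base shape would touch the grid boundary (insufficient margin)"
        )
    _check_clear_of_boundary(occ, "base shape")
    return BinaryVolume(grid, occ.astype(np.uint8))


def _smooth_noise_field(grid: VolumeGrid, amp: float, corr_mm: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white vector noise with RMS magnitude ``amp`` mm."""
    sig_vox = [max(corr_mm / s, 1e-6) for s in grid.spacing]
    u = rng.standard_normal(grid.dims + (3,)).astype(np.float32)
    for a in range(3):
        u[..., a] = ndimage.gaussian_filter(u[..., a], sig_vox)
    rms = float(np.sqrt(np.mean(np.sum(u * u, axis=-1))))
    if rms > 0:
        u *= amp / rms
    return u


def apply_known_transform(shape: BinaryVolume, params: TransformParams) -> BinaryVolume:
    """Push a shape through an exact parametric transform (NN resampling)."""
    out = apply_params(shape, params)
    if out.count() and shape.count():
        _check_clear_of_boundary(out.occupancy, "transformed shape")
    return out


def make_population(spec: PopulationSpec) -> list[BinaryVolume]:
    """n_cases independently perturbed copies of the base shape."""
    base = make_base_shape(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA71A5]))
    grid = spec.grid
    pos = grid.index_grid_physical()
    c = grid.center
    cases: list[BinaryVolume] = []
    for i in range(spec.n_cases):
        angles = rng.normal(0.0, spec.pose_sd[0], size=3)
        trans = rng.normal(0.0, spec.pose_sd[1], size=3)
        k = float(np.exp(rng.normal(0.0, spec.scale_sd))) if spec.scale_sd else 1.0
        e = (
            rng.normal(0.0, spec.affine_sd, size=(3, 3))
            if spec.affine_sd
            else np.zeros((3, 3))
        )
        matrix = k * RigidParams(tuple(angles)).rotation_matrix() + e
        params = AffineParams(matrix, tuple(trans))
        warp = (
            _smooth_noise_field(grid, spec.warp_amp, spec.warp_smoothness, rng)
            if spec.warp_amp > 0
            else None
        )
        if _no_perturbation(params, warp):
            occ = base.occupancy.copy()
        else:
            a, t = _linear_part(params)
            src = (pos - c - t) @ np.linalg.inv(a).T + c
            if warp is not None:
                src = src + warp
            vals = _resample(base.occupancy.astype(np.float32), grid, src, order=0)
            occ = (vals > 0.5).astype(np.uint8)
        if not occ.any():
            raise SpecError(f"case {i}: perturbed shape is empty")
        _check_clear_of_boundary(occ, f"case {i}")
        cases.append(BinaryVolume(grid, occ))
    return cases


def _no_perturbation(params: AffineParams, warp) -> bool:
    a, t = _linear_part(params)
    return (
        warp is None
        and np.allclose(a, np.eye(3), atol=1e-12)
        and np.allclose(t, 0.0, atol=1e-12)
    )
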