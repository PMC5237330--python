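"""Landmark/PCA statistical atlas with viscous reconstruction.

Semi-landmarks are sampled on equally spaced slices along each axis
(normalized to each shape's bounding extent, so the i-th mark corresponds
across cases), PCA is run on the stacked landmark coordinates, and the mean
landmark cloud is turned back into a binary shape by growing inner and
outer viscous reconstructions against the landmark membrane and merging
them with the mean-signed-distance (Baddeley-Molchanov) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .coverage import mean_shape_bm
from .errors import ContentError, DomainError
from .volumes import BinaryVolume, VolumeGrid, assert_common_frame

__all__ = [
    "LandmarkSet",
    "ShapeModel",
    "StatAtlasConfig",
    "extract_semilandmarks",
    "extract_population_landmarks",
    "fit_shape_model",
    "viscous_reconstruction",
    "statistical_atlas",
]


@dataclass
class LandmarkSet:
    """Ordered 3D landmark points (mm) plus the population slicing layout."""

    points: np.ndarray                      # (N, 3) physical mm
    layout: tuple[tuple[int, int, int], ...]  # (axis, slice ordinal, count)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise DomainError("points must be an (N, 3) array")
        if pts.shape[0] != sum(c for _, _, c in self.layout):
            raise ContentError("point count does not match the slicing layout")
        self.points = pts
        self.layout = tuple(tuple(int(v) for v in row) for row in self.layout)


@dataclass
class ShapeModel:
    mean: np.ndarray          # flattened coordinate vector (3N,)
    modes: np.ndarray         # (n_modes, 3N) orthonormal rows
    eigenvalues: np.ndarray   # non-negative, non-increasing
    layout: tuple = ()


@dataclass(frozen=True)
class StatAtlasConfig:
    slices_per_axis: tuple[int, int, int] = (8, 8, 8)
    density: float = 0.35        # landmarks per mm of contour length
    opening_radius: int = 2      # voxels
    max_iters: int = 200
    stamp_dilation: int = 1      # voxels added around each rasterized landmark


# ---------------------------------------------------------------------------
# Semi-landmark extraction
# ---------------------------------------------------------------------------


def _slice_indices(occ: np.ndarray, axis: int, n_slices: int) -> list[int]:
    proj = np.any(occ, axis=tuple(a for a in range(3) if a != axis))
    nz = np.nonzero(proj)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    out = []
    for s in range(n_slices):
        f = (s + 0.5) / n_slices
        out.append(min(hi, max(lo, int(np.floor(lo + f * (hi - lo + 1))))))
    return out


def _longest_closed_contour(plane: np.ndarray, sp_u: float, sp_v: float):
    """Longest closed boundary contour of a 2D mask, arclength in mm.

    Returns (vertices (K, 2) in index coords, length) or None.
    """
    best = None
    best_len = -1.0
    for cont in measure.find_contours(plane.astype(float), 0.5):
        if not np.allclose(cont[0], cont[-1]):
            continue
        seg = np.diff(cont, axis=0) * np.array([sp_u, sp_v])
        length = float(np.sqrt((seg**2).sum(axis=1)).sum())
        if length > best_len + 1e-12:
            best_len = length
            best = cont[:-1]  # drop duplicated closing vertex
    if best is None:
        return None
    return best, best_len


def _parameterize(cont: np.ndarray, sp_u: float, sp_v: float, n_pts: int) -> np.ndarray:
    """Sample a closed contour at equal arclength fractions.

    Start vertex = smallest (second, then first) in-slice coordinate;
    traversal counter-clockwise (positive signed area).
    """
    mm = cont * np.array([sp_u, sp_v])
    # signed area (shoelace); reverse clockwise contours
    u, v = mm[:, 0], mm[:, 1]
    area = 0.5 * np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v)
    if area < 0:
        cont = cont[::-1]
        mm = mm[::-1]
    start = int(np.lexsort((cont[:, 0], cont[:, 1]))[0])
    cont = np.roll(cont, -start, axis=0)
    mm = np.roll(mm, -start, axis=0)

    closed = np.vstack([mm, mm[:1]])
    seg = np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(n_pts) * total / n_pts
    closed_idx = np.vstack([cont, cont[:1]])
    out = np.empty((n_pts, 2))
    for c in range(2):
        out[:, c] = np.interp(targets, cum, closed_idx[:, c])
    return out


def _measure_slices(shape: BinaryVolume, slices_per_axis) -> dict:
    """Per (axis, ordinal): slice index, contour and its mm length."""
    occ = shape.occupancy.astype(bool)
    if not occ.any():
        raise ContentError("cannot extract landmarks from an empty shape")
    sp = shape.grid.spacing
    found = {}
    for axis in range(3):
        inplane = [a for a in range(3) if a != axis]
        su, sv = sp[inplane[0]], sp[inplane[1]]
        for ordinal, idx in enumerate(_slice_indices(occ, axis, slices_per_axis[axis])):
            plane = np.take(occ, idx, axis=axis)
            res = _longest_closed_contour(plane, su, sv)
            if res is not None:
                found[(axis, ordinal)] = (idx, res[0], res[1])
    if not found:
        raise ContentError("shape too thin for the requested slicing")
    return found


def _landmarks_from_counts(
    shape: BinaryVolume, slices_per_axis, counts: dict
) -> LandmarkSet:
    sliced = _measure_slices(shape, slices_per_axis)
    grid = shape.grid
    sp = grid.spacing
    points = []
    layout = []
    for key in sorted(counts):
        if key not in sliced:
            raise ContentError(f"slice {key} empty for this case (layout mismatch)")
        axis, ordinal = key
        idx, cont, _ = sliced[key]
        inplane = [a for a in range(3) if a != axis]
        sampled = _parameterize(cont, sp[inplane[0]], sp[inplane[1]], counts[key])
        for uv in sampled:
            voxel = np.empty(3)
            voxel[axis] = idx
            voxel[inplane[0]] = uv[0]
            voxel[inplane[1]] = uv[1]
            points.append(grid.index_to_physical(voxel))
        layout.append((axis, ordinal, counts[key]))
    return LandmarkSet(np.asarray(points), tuple(layout))


def extract_semilandmarks(
    shape: BinaryVolume,
    slices_per_axis=(8, 8, 8),
    density: float = 0.35,
    counts: dict | None = None,
) -> LandmarkSet:
    """Ordered surface semi-landmarks from axis-aligned slicing.

    ``counts`` overrides the per-slice point counts (the population rule);
    without it, counts derive from this shape's own contour lengths.
    """
    if counts is None:
        sliced = _measure_slices(shape, slices_per_axis)
        counts = {k: max(3, round(density * v[2])) for k, v in sliced.items()}
    return _landmarks_from_counts(shape, slices_per_axis, counts)


def extract_population_landmarks(
    shapes: Sequence[BinaryVolume],
    slices_per_axis=(8, 8, 8),
    density: float = 0.35,
) -> list[LandmarkSet]:
    """Landmarks for every case with one shared layout.

    Per-slice point counts are max(3, round(density x population-mean contour
    length)); slices lacking a closed contour in any case are dropped for all.
    """
    per_case = [_measure_slices(s, slices_per_axis) for s in shapes]
    keys = set(per_case[0])
    for m in per_case[1:]:
        keys &= set(m)
    if not keys:
        raise ContentError("no slice produces a closed contour in every case")
    counts = {
        k: max(3, round(density * float(np.mean([m[k][2] for m in per_case]))))
        for k in keys
    }
    return [_landmarks_from_counts(s, slices_per_axis, counts) for s in shapes]


# ---------------------------------------------------------------------------
# PCA shape model
# ---------------------------------------------------------------------------


def fit_shape_model(sets: Sequence[LandmarkSet]) -> ShapeModel:
    """PCA over stacked landmark coordinate vectors."""
    if len(sets) < 2:
        raise DomainError("fit_shape_model needs at least two landmark sets")
    layout = sets[0].layout
    for i, s in enumerate(sets[1:], start=1):
        if s.layout != layout:
            raise ContentError(f"landmark layout of case {i} differs from case 0")
    data = np.stack([s.points.ravel() for s in sets])  # (n, 3N)
    mean = data.mean(axis=0)
    centered = data - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    n = len(sets)
    n_modes = min(n - 1, centered.shape[1])
    eigenvalues = (svals[:n_modes] ** 2) / (n - 1)
    return ShapeModel(mean, vt[:n_modes], eigenvalues, layout)


# ---------------------------------------------------------------------------
# Viscous reconstruction
# ---------------------------------------------------------------------------


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x * x + y * y + z * z) <= r * r


_DILATE1 = ndimage.generate_binary_structure(3, 1)


def _open(arr: np.ndarray, ball: np.ndarray) -> np.ndarray:
    # erosion with border_value=1 so shapes hugging the window border survive
    return ndimage.binary_dilation(
        ndimage.binary_erosion(arr, structure=ball, border_value=1), structure=ball
    )


def viscous_reconstruction(
    marker: BinaryVolume,
    seed: BinaryVolume,
    opening_radius: int = 2,
    max_iters: int = 200,
) -> BinaryVolume:
    """Grow a shape from a seed by repeated dilation + opening, clipped to
    the marker (constraint) region.

    The opened seed core always survives; the result never exceeds the
    marker.  ``max_iters = 0`` returns the opened seed.
    """
    if seed.empty:
        raise ContentError("viscous reconstruction needs a non-empty seed")
    assert_common_frame([marker, seed])
    ball = _ball(opening_radius)
    allowed = marker.occupancy.astype(bool)
    s = seed.occupancy.astype(bool)
    core = _open(s, ball)
    if not core.any():
        core = s  # tiny seeds survive unopened
    core = core & allowed if (core & allowed).any() else core
    cur = core
    for _ in range(int(max_iters)):
        grown = ndimage.binary_dilation(cur, structure=_DILATE1)
        nxt = (_open(grown, ball) & allowed) | core
        if (nxt == cur).all():
            break
        cur = nxt
    return BinaryVolume(marker.grid, cur.astype(np.uint8))


# ---------------------------------------------------------------------------
# Full statistical atlas
# ---------------------------------------------------------------------------


def _stamp_membrane(grid: VolumeGrid, points: np.ndarray, dilation: int) -> np.ndarray:
    idx = np.rint(grid.physical_to_index(points)).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.dims) - 1)
    vol = np.zeros(grid.dims, dtype=bool)
    vol[tuple(idx.T)] = True
    if dilation > 0:
        vol = ndimage.binary_dilation(
            vol, structure=ndimage.generate_binary_structure(3, 3),
            iterations=dilation,
        )
    return vol


def _seed_ball(grid: VolumeGrid, center_idx: np.ndarray, radius: int,
               allowed: np.ndarray) -> np.ndarray:
    ax = [np.arange(d) for d in grid.dims]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip((ii, jj, kk), center_idx))
    seed = (dist2 <= radius * radius) & allowed
    if not seed.any():
        seed = np.zeros(grid.dims, dtype=bool)
        seed[tuple(np.clip(center_idx, 0, np.asarray(grid.dims) - 1))] = True
    return seed


def statistical_atlas(
    aligned: Sequence[BinaryVolume],
    cfg: StatAtlasConfig | None = None,
) -> tuple[BinaryVolume, ShapeModel]:
    """Binary statistical atlas plus the PCA landmark model.

    Mean landmarks are rasterized into a membrane; an inner reconstruction
    grows from the landmark centroid and an outer one from a window corner
    (then inverted); the atlas is their mean-signed-distance threshold.
    """
    cfg = cfg or StatAtlasConfig()
    if len(aligned) < 2:
        raise DomainError("statistical_atlas needs at least two shapes")
    assert_common_frame(list(aligned))
    grid = aligned[0].grid

    sets = extract_population_landmarks(aligned, cfg.slices_per_axis, cfg.density)
    model = fit_shape_model(sets)
    mean_pts = model.mean.reshape(-1, 3)

    membrane = _stamp_membrane(grid, mean_pts, cfg.stamp_dilation)
    allowed = ~membrane
    marker = BinaryVolume(grid, allowed.astype(np.uint8))

    centroid_idx = np.rint(grid.physical_to_index(mean_pts.mean(axis=0))).astype(int)
    seed_r = cfg.opening_radius + 1
    inner_seed = BinaryVolume(
        grid, _seed_ball(grid, centroid_idx, seed_r, allowed).astype(np.uint8)
    )
    inner = viscous_reconstruction(marker, inner_seed, cfg.opening_radius,
                                   cfg.max_iters)

    corner_seed = BinaryVolume(
        grid, _seed_ball(grid, np.zeros(3, dtype=int), seed_r, allowed).astype(np.uint8)
    )
    outer = viscous_reconstruction(marker, corner_seed, cfg.opening_radius,
                                   cfg.max_iters)
    inverted_outer = BinaryVolume(grid, (1 - outer.occupancy).astype(np.uint8))

    atlas = mean_shape_bm([inner, inverted_outer])
    return atlas, model
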