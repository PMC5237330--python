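"""Locally weighted logistic-regression atlas.

At each voxel x0 near the zero level of the mean signed distance d*, the
coverage indicators of the aligned sample are regressed on basis functions
of d* with tricube kernel weights, maximizing the weighted Bernoulli
loglikelihood

    l(beta) = sum_i sum_j w(x_j, x0) [ y_ij log p(x_j) + (1 - y_ij) log(1 - p(x_j)) ]

with p = logistic(beta' v(d*)).  Because p(x_j) is shared across sample
members, the per-point data reduce to coverage counts, which keeps the
per-voxel Newton solve small and lets the whole band be fitted in one
vectorized pass.  Deep inside (below the band) the probability is 1 - eps,
far outside it is eps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import mean_distance
from .errors import ContentError, DomainError
from .volumes import (
    BinaryVolume,
    ProbabilityVolume,
    SignedDistanceVolume,
    VolumeGrid,
    assert_common_frame,
)

__all__ = ["GLMConfig", "LocalFit", "tricube", "local_weights",
           "fit_local_logistic", "glm_atlas"]

_TRICUBE_C = 70.0 / 81.0
_NEIGH_POOL = 50  # candidate-neighbourhood size the span fraction applies to


def tricube(u) -> np.ndarray | float:
    """Tricube kernel (70/81)(1-|u|^3)^3 on [-1, 1], zero outside."""
    u = np.abs(np.asarray(u, dtype=float))
    out = np.where(u <= 1.0, _TRICUBE_C * (1.0 - u**3) ** 3, 0.0)
    return float(out) if out.ndim == 0 else out


def local_weights(x0, pts, h: float) -> np.ndarray:
    """w_j = tricube(||x_j - x0|| / h); points at distance >= h get 0."""
    if h <= 0:
        raise DomainError(f"bandwidth must be > 0, got {h}")
    x0 = np.asarray(x0, dtype=float)
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    return tricube(np.linalg.norm(pts - x0, axis=-1) / h)


@dataclass(frozen=True)
class GLMConfig:
    """Settings for the local logistic fits.

    Either ``bandwidth`` (mm) is given, or ``span`` selects the fraction of
    a fixed-size candidate lattice neighbourhood used as kernel support.
    """

    bandwidth: float | None = None
    span: float = 0.7
    kernel: str = "tricube"
    order: int = 1              # basis (1, d*) or (1, d*, d*^2)
    band_halfwidth: float | None = None  # mm; default 3 x max spacing
    eps: float = 1e-3
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self):
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise DomainError("bandwidth must be > 0")
        if not (0.0 < self.span <= 1.0):
            raise DomainError("span must be in (0, 1]")
        if self.kernel != "tricube":
            raise DomainError(f"unsupported kernel {self.kernel!r}")
        if self.order not in (1, 2):
            raise DomainError("basis order must be 1 (linear) or 2 (quadratic)")
        if not (0.0 < self.eps < 0.5):
            raise DomainError("eps must be in (0, 0.5)")

    @property
    def n_params(self) -> int:
        return self.order + 1


@dataclass
class LocalFit:
    beta: np.ndarray
    converged: bool
    n_points: int


# ---------------------------------------------------------------------------
# Bandwidth and neighbourhood resolution
# ---------------------------------------------------------------------------


def resolve_bandwidth(grid: VolumeGrid, cfg: GLMConfig) -> float:
    """Effective kernel bandwidth h (mm) for the given grid.

    With ``span``, h is the distance to the ceil(span * pool)-th nearest
    lattice point of a voxel (pool = 50), so the kernel support covers that
    fraction of the candidate neighbourhood.
    """
    if cfg.bandwidth is not None:
        return float(cfg.bandwidth)
    spacing = np.asarray(grid.spacing)
    reach = 4
    offs = np.mgrid[-reach:reach + 1, -reach:reach + 1, -reach:reach + 1]
    offs = offs.reshape(3, -1).T.astype(float)
    dists = np.sort(np.linalg.norm(offs * spacing, axis=1))
    k = max(int(np.ceil(cfg.span * _NEIGH_POOL)), cfg.order + 2)
    # h strictly above the k-th distance so the k-th point keeps weight > 0
    return float(dists[k - 1] * (1.0 + 1e-9)) if dists[k - 1] > 0 else float(
        spacing.min()
    )


def _stencil(grid: VolumeGrid, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Lattice offsets with tricube weight > 0 for bandwidth h (mm)."""
    spacing = np.asarray(grid.spacing)
    reach = [int(np.floor(h / s)) for s in spacing]
    ax = [np.arange(-r, r + 1) for r in reach]
    offs = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(offs * spacing, axis=1)
    keep = d < h
    return offs[keep], tricube(d[keep] / h)


def _basis(d: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(d), d]
    if order == 2:
        cols.append(d * d)
    return np.stack(cols, axis=-1)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# Newton solver (vectorized over fit locations)
# ---------------------------------------------------------------------------


def _newton_batch(d, cnt, w, n: int, cfg: GLMConfig):
    """Maximize the weighted Bernoulli loglikelihood at many locations.

    d, cnt, w: (V, J) arrays of basis abscissae, coverage counts in [0, n]
    and kernel weights (0 marks padded/invalid points).  Returns
    (beta (V, p), converged (V,)).
    """
    v, j = d.shape
    p = cfg.n_params
    x = _basis(d, cfg.order)                      # (V, J, p)
    wsum = w.sum(axis=1)
    rate = np.clip((w * cnt).sum(axis=1) / (n * np.maximum(wsum, 1e-30)),
                   1e-3, 1 - 1e-3)
    beta = np.zeros((v, p))
    beta[:, 0] = np.log(rate / (1 - rate))

    def loglik(b):
        eta = np.clip(np.einsum("vjp,vp->vj", x, b), -35.0, 35.0)
        return (w * (cnt * eta - n * np.logaddexp(0.0, eta))).sum(axis=1)

    ll = loglik(beta)
    eye = np.eye(p) * 1e-9
    converged = np.zeros(v, dtype=bool)
    for _ in range(cfg.max_iter):
        eta = np.clip(np.einsum("vjp,vp->vj", x, beta), -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = np.einsum("vj,vjp->vp", w * (cnt - n * mu), x)
        gnorm = np.abs(g).max(axis=1)
        scale = np.maximum(n * wsum, 1e-30)
        converged = gnorm <= np.maximum(cfg.tol * scale, 1e-10)
        active = ~converged
        if not active.any():
            break
        h = np.einsum("vj,vjp,vjq->vpq", w * n * mu * (1 - mu), x, x) + eye
        try:
            step = np.linalg.solve(h, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(h + np.eye(p) * 1e-6, g[..., None])[..., 0]
        # cap huge steps (quasi-separated neighbourhoods)
        norm = np.maximum(np.linalg.norm(step, axis=1, keepdims=True), 1e-30)
        step = np.where(norm > 25.0, step * (25.0 / norm), step)
        alpha = np.where(active, 1.0, 0.0)
        for _ in range(25):
            ll_new = loglik(beta + alpha[:, None] * step)
            worse = active & (ll_new < ll - 1e-12)
            if not worse.any():
                break
            alpha[worse] *= 0.5
        beta = beta + alpha[:, None] * step
        ll = loglik(beta)
    return beta, converged


# ---------------------------------------------------------------------------
# Public fitting operations
# ---------------------------------------------------------------------------


def _shortcut_beta(p_hat: float, n_params: int) -> np.ndarray:
    b = np.zeros(n_params)
    b[0] = _logit(p_hat)
    return b


def fit_local_logistic(
    x0,
    dstar: SignedDistanceVolume,
    indicators: Sequence[BinaryVolume],
    cfg: GLMConfig | None = None,
) -> LocalFit:
    """Kernel-weighted logistic fit of coverage on d* at a single point.

    Degenerate neighbourhoods (all covered / all uncovered) short-circuit to
    probability 1 - eps / eps.
    """
    cfg = cfg or GLMConfig()
    if len(indicators) < 1:
        raise DomainError("need at least one indicator volume")
    assert_common_frame([dstar, *indicators])
    grid = dstar.grid
    h = resolve_bandwidth(grid, cfg)
    pos = grid.index_grid_physical().reshape(-1, 3)
    wts = local_weights(np.asarray(x0, dtype=float), pos, h)
    inside = wts > 0
    n_points = int(inside.sum())
    if n_points == 0:
        raise DomainError(f"no grid points within the bandwidth ball around {x0}")
    w = wts[inside]
    d = dstar.distance.reshape(-1)[inside].astype(np.float64)
    cnt = np.zeros(n_points)
    for s in indicators:
        cnt += s.occupancy.reshape(-1)[inside]
    n = len(indicators)
    if (cnt == n).all():
        return LocalFit(_shortcut_beta(1 - cfg.eps, cfg.n_params), True, n_points)
    if (cnt == 0).all():
        return LocalFit(_shortcut_beta(cfg.eps, cfg.n_params), True, n_points)
    beta, conv = _newton_batch(d[None, :], cnt[None, :], w[None, :], n, cfg)
    return LocalFit(beta[0], bool(conv[0]), n_points)


def glm_atlas(
    aligned: Sequence[BinaryVolume],
    cfg: GLMConfig | None = None,
    return_diagnostics: bool = False,
):
    """Local-logistic probabilistic atlas over the band |d*| <= half-width.

    Voxels below the band (deep inside) get 1 - eps, voxels above it eps;
    all outputs are clamped to [eps, 1 - eps].
    """
    cfg = cfg or GLMConfig()
    if len(aligned) < 2:
        raise DomainError("glm_atlas needs at least two shapes")
    assert_common_frame(list(aligned))
    grid = aligned[0].grid
    n = len(aligned)

    dstar = mean_distance(aligned)
    dvol = dstar.distance.astype(np.float64)
    counts = np.zeros(grid.dims, dtype=np.int32)
    for s in aligned:
        counts += s.occupancy

    bhw = cfg.band_halfwidth
    if bhw is None:
        bhw = 3.0 * max(grid.spacing)
    eps = cfg.eps
    out = np.where(dvol < -bhw, 1.0 - eps, eps).astype(np.float64)

    band_idx = np.argwhere(np.abs(dvol) <= bhw)
    n_band = band_idx.shape[0]
    diagnostics = {"band_voxels": int(n_band), "bandwidth_mm": None,
                   "fraction_converged": 1.0}
    if n_band:
        h = resolve_bandwidth(grid, cfg)
        diagnostics["bandwidth_mm"] = h
        offs, woffs = _stencil(grid, h)
        j = offs.shape[0]
        dims = np.asarray(grid.dims)

        d = np.empty((n_band, j))
        cnt = np.empty((n_band, j))
        w = np.empty((n_band, j))
        flat_d = dvol.reshape(-1)
        flat_c = counts.reshape(-1)
        for k in range(j):
            ni = band_idx + offs[k]
            valid = ((ni >= 0) & (ni < dims)).all(axis=1)
            ni_clip = np.clip(ni, 0, dims - 1)
            flat = np.ravel_multi_index(ni_clip.T, grid.dims)
            d[:, k] = flat_d[flat]
            cnt[:, k] = flat_c[flat]
            w[:, k] = np.where(valid, woffs[k], 0.0)
            d[:, k] = np.where(valid, d[:, k], 0.0)
            cnt[:, k] = np.where(valid, cnt[:, k], 0.0)

        active = w > 0
        pure1 = ((cnt == n) | ~active).all(axis=1)
        pure0 = ((cnt == 0) | ~active).all(axis=1)
        mixed = ~(pure1 | pure0)

        p_hat = np.full(n_band, eps)
        p_hat[pure1] = 1.0 - eps
        frac_conv = 1.0
        if mixed.any():
            beta, conv = _newton_batch(d[mixed], cnt[mixed], w[mixed], n, cfg)
            d0 = dvol.reshape(-1)[np.ravel_multi_index(band_idx[mixed].T, grid.dims)]
            v0 = _basis(d0, cfg.order)
            eta0 = np.clip(np.einsum("vp,vp->v", v0, beta), -35.0, 35.0)
            p_hat[mixed] = 1.0 / (1.0 + np.exp(-eta0))
            frac_conv = float(conv.mean())
        diagnostics["fraction_converged"] = frac_conv
        out[tuple(band_idx.T)] = p_hat

    out = np.clip(out, eps, 1.0 - eps)
    atlas = ProbabilityVolume(grid, out)
    if return_diagnostics:
        return atlas, diagnostics
    return atlas
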