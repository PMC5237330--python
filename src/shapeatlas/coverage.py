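"""Coverage and signed-distance building blocks for atlas construction.

The normalized coverage function (NCF) atlas is the per-voxel fraction of
aligned shapes covering that voxel.  Signed distances are spacing-aware
Euclidean voxel-center distances, strictly negative inside the shape and
strictly positive outside (the zero level lives between voxel layers).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ContentError, DomainError
from .volumes import (
    BinaryVolume,
    ProbabilityVolume,
    SignedDistanceVolume,
    assert_common_frame,
)

__all__ = ["signed_distance", "ncf_atlas", "mean_distance", "mean_shape_bm"]


def signed_distance(shape: BinaryVolume) -> SignedDistanceVolume:
    """Signed Euclidean distance (mm) to the shape.

    Background voxels get +distance to the nearest foreground voxel center,
    foreground voxels -distance to the nearest background voxel center.
    """
    if shape.empty or shape.full:
        raise ContentError("signed distance undefined for empty or full shapes")
    occ = shape.occupancy.astype(bool)
    sampling = shape.grid.spacing
    # distance_transform_edt: distance of nonzero voxels to the nearest zero
    outside = ndimage.distance_transform_edt(~occ, sampling=sampling)
    inside = ndimage.distance_transform_edt(occ, sampling=sampling)
    return SignedDistanceVolume(shape.grid, np.where(occ, -inside, outside))


def ncf_atlas(aligned: Sequence[BinaryVolume]) -> ProbabilityVolume:
    """Normalized coverage function: prob(x) = (1/n) sum_i 1_{phi_i}(x)."""
    if len(aligned) < 1:
        raise DomainError("ncf_atlas needs at least one shape")
    assert_common_frame(list(aligned))
    acc = np.zeros(aligned[0].grid.dims, dtype=np.float64)
    for s in aligned:
        acc += s.occupancy
    return ProbabilityVolume(aligned[0].grid, acc / len(aligned))


def mean_distance(aligned: Sequence[BinaryVolume]) -> SignedDistanceVolume:
    """Mean signed distance d*(x) = (1/n) sum_i d_{phi_i}(x)."""
    if len(aligned) < 1:
        raise DomainError("mean_distance needs at least one shape")
    assert_common_frame(list(aligned))
    acc = np.zeros(aligned[0].grid.dims, dtype=np.float64)
    for s in aligned:
        acc += signed_distance(s).distance
    return SignedDistanceVolume(aligned[0].grid, acc / len(aligned))


def mean_shape_bm(aligned: Sequence[BinaryVolume]) -> BinaryVolume:
    """Mean shape by thresholding the mean signed distance at 0 (d* < 0)."""
    dstar = mean_distance(aligned)
    return BinaryVolume(dstar.grid, (dstar.distance < 0).astype(np.uint8))
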