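"""Synthetic nucleus placement: non-overlapping ellipsoids in a voxel grid."""

from __future__ import annotations

import numpy as np

from ..grid import VoxelGrid
from .truth import EllipsoidTruth, GroundTruth

__all__ = ["PlacementError", "rasterize_ellipsoid", "gen_nuclei"]


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be achieved."""


def rasterize_ellipsoid(
    shape: tuple[int, int, int],
    center_vox,
    semiaxes_vox,
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the ellipsoid."""
    center = np.asarray(center_vox, dtype=float)
    semi = np.asarray(semiaxes_vox, dtype=float)
    lo = np.maximum(np.floor(center - semi).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi).astype(int) + 1, np.asarray(shape))
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    r2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = r2 <= 1.0
    return mask


def gen_nuclei(
    n_nuclei: int,
    grid: VoxelGrid,
    seed: int,
    semiaxes_range_vox: tuple[float, float] = (5.0, 9.0),
    max_tries: int = 200,
) -> tuple[np.ndarray, GroundTruth]:
    """Place ``n_nuclei`` non-overlapping ellipsoids; returns label image + truth.

    Labels run 1..n_nuclei. Each ellipsoid fits entirely inside the grid;
    placement is reject-and-resample with at most ``max_tries`` attempts per
    nucleus.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    lo_s, hi_s = semiaxes_range_vox
    shape = np.asarray(grid.shape)
    rng = np.random.default_rng(seed)
    labels = np.zeros(grid.shape, dtype=np.int32)
    truth = GroundTruth(seed=seed, grid=grid)

    for label in range(1, n_nuclei + 1):
        placed = False
        for _ in range(max_tries):
            semi = rng.uniform(lo_s, hi_s, size=3)
            # keep nuclei flatter in z if the grid is shallow
            semi = np.minimum(semi, (shape - 4) / 2.0)
            lo_c = semi + 0.5
            hi_c = shape - 1 - semi - 0.5
            if np.any(hi_c <= lo_c):
                continue
            center = rng.uniform(lo_c, hi_c)
            mask = rasterize_ellipsoid(grid.shape, center, semi)
            if not mask.any():
                continue
            if np.any(labels[mask] != 0):
                continue
            labels[mask] = label
            truth.nuclei.append(
                EllipsoidTruth(
                    label=label,
                    center_vox=tuple(float(c) for c in center),
                    semiaxes_vox=tuple(float(s) for s in semi),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {label}/{n_nuclei} without overlap in a "
                f"{grid.shape} grid after {max_tries} tries "
                f"(semiaxes range {semiaxes_range_vox} voxels)"
            )
    return labels, truth
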