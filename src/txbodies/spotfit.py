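"""Sub-voxel 3D spot detection and localization.

The pipeline is band-pass filtering (difference of Gaussians) for candidate
detection, 3D local-maxima finding, and an iterative Gaussian-mask centroid
fit on the *raw* intensities that yields sub-voxel coordinates and a
mask-weighted intensity estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VolumeImage

__all__ = [
    "SpotRecord",
    "bandpass",
    "find_maxima",
    "gaussian_mask_fit",
    "detect_spots",
    "top_k_brightest",
    "spots_to_frame",
]


@dataclass
class SpotRecord:
    """A localized spot: sub-voxel center, fitted intensity, fit diagnostics."""

    center_vox: tuple[float, float, float]
    center_um: tuple[float, float, float]
    intensity: float
    background: float
    iterations: int
    converged: bool
    channel: str | None = None
    frame: int | None = None
    nucleus: int | None = None


def _sigma_to_vox(sigma_um, grid) -> np.ndarray:
    return np.asarray(sigma_um, dtype=float) / grid.spacing_arr


def bandpass(img: VolumeImage, sigma_small_um, sigma_large_um) -> VolumeImage:
    """Difference-of-Gaussians band-pass; linear in the input, DC removed."""
    small = np.asarray(sigma_small_um, dtype=float)
    large = np.asarray(sigma_large_um, dtype=float)
    if small.size == 1:
        small = np.repeat(small, 3)
    if large.size == 1:
        large = np.repeat(large, 3)
    if np.any(small >= large):
        raise ValueError(
            f"sigma_small must be < sigma_large on every axis, got {small} vs {large}"
        )
    data = np.asarray(img.data, dtype=float)
    lo = ndimage.gaussian_filter(data, sigma=_sigma_to_vox(small, img.grid))
    hi = ndimage.gaussian_filter(data, sigma=_sigma_to_vox(large, img.grid))
    return VolumeImage(data=lo - hi, grid=img.grid, channel=img.channel, frame=img.frame)


def find_maxima(
    img: VolumeImage, threshold: float, min_separation: float = 2.0
) -> list[tuple[int, int, int]]:
    """26-connected local maxima above ``threshold``, merged by proximity.

    Candidates closer than ``min_separation`` voxels (Euclidean, voxel units)
    are merged keeping the brighter; exact ties keep the lexicographically
    smallest (z, y, x) index.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = np.asarray(img.data, dtype=float)
    maxf = ndimage.maximum_filter(data, size=3, mode="nearest")
    cand = np.argwhere((data >= maxf) & (data > threshold))
    if len(cand) == 0:
        return []
    vals = data[tuple(cand.T)]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -vals))
    cand = cand[order]
    kept: list[np.ndarray] = []
    for c in cand:
        if all(np.linalg.norm(c - k) >= min_separation for k in kept):
            kept.append(c)
    return [tuple(int(v) for v in k) for k in kept]


def gaussian_mask_fit(
    img: VolumeImage,
    seed_point: tuple[int, int, int],
    sigma_psf_um,
    max_iter: int = 100,
    tol: float = 0.01,
    window_radius: float = 3.0,
    channel: str | None = None,
) -> SpotRecord:
    """Iterative Gaussian-mask centroid fit with fixed σ.

    Updates the center as the Gaussian-weighted, background-subtracted
    centroid of the window voxels until the step is below ``tol`` voxels
    (anisotropy handled in μm). The local background is the median of the
    window's boundary shell. A non-positive weight sum yields a flagged,
    non-converged record — never an exception.
    """
    grid = img.grid
    data = np.asarray(img.data, dtype=float)
    seed = np.asarray(seed_point, dtype=int)
    if not grid.contains_voxel(seed):
        raise ValueError(f"seed point {seed_point} outside image bounds {grid.shape}")
    sigma_um = np.asarray(sigma_psf_um, dtype=float)
    if sigma_um.size == 1:
        sigma_um = np.repeat(sigma_um, 3)
    sigma_vox = sigma_um / grid.spacing_arr

    radius = np.maximum(np.ceil(window_radius * sigma_vox).astype(int), 1)
    lo = np.maximum(seed - radius, 0)
    hi = np.minimum(seed + radius + 1, np.asarray(grid.shape))
    window = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]

    # boundary shell median as the local background estimate
    interior = window[
        tuple(slice(1, -1) if s > 2 else slice(None) for s in window.shape)
    ]
    if interior.size and interior.size < window.size:
        shell_mask = np.ones(window.shape, dtype=bool)
        shell_mask[
            tuple(slice(1, -1) if s > 2 else slice(None) for s in window.shape)
        ] = False
        background = float(np.median(window[shell_mask]))
    else:
        background = float(np.median(window))

    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]) * grid.spacing[0],
        np.arange(lo[1], hi[1]) * grid.spacing[1],
        np.arange(lo[2], hi[2]) * grid.spacing[2],
        indexing="ij",
    )
    coords_um = np.stack([zz, yy, xx], axis=-1)  # (wz, wy, wx, 3)
    signal = window - background

    center_um = seed * grid.spacing_arr
    converged = False
    iterations = 0
    gauss = np.ones(window.shape)
    for iterations in range(1, max_iter + 1):
        d2 = ((coords_um - center_um) / (sigma_um * np.sqrt(2.0))) ** 2
        gauss = np.exp(-d2.sum(axis=-1))
        weights = signal * gauss
        denom = weights.sum()
        if denom <= 0:
            break
        new_center = (weights[..., None] * coords_um).sum(axis=(0, 1, 2)) / denom
        step_vox = np.linalg.norm((new_center - center_um) / grid.spacing_arr)
        center_um = new_center
        if step_vox < tol:
            converged = True
            break

    g2 = (gauss**2).sum()
    intensity = float((signal * gauss).sum() / g2) if g2 > 0 else 0.0
    center_vox = center_um / grid.spacing_arr
    if converged and not grid.contains_voxel(np.round(center_vox)):
        converged = False
    return SpotRecord(
        center_vox=tuple(float(v) for v in center_vox),
        center_um=tuple(float(v) for v in center_um),
        intensity=intensity,
        background=background,
        iterations=iterations,
        converged=converged,
        channel=channel or img.channel,
        frame=img.frame,
    )


def detect_spots(
    img: VolumeImage,
    sigma_psf_um,
    threshold: float,
    sigma_small_um=None,
    sigma_large_um=None,
    min_separation: float = 2.0,
    nuclei: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 0.01,
    window_radius: float = 3.0,
) -> list[SpotRecord]:
    """Full detection: band-pass → local maxima → Gaussian-mask fit on raw data.

    ``threshold`` applies to the band-passed image. Non-converged fits are
    dropped. With a nucleus label image, spots whose rounded centers fall
    outside all nuclei are excluded and the rest carry their nucleus label.
    """
    sigma_psf = np.asarray(sigma_psf_um, dtype=float)
    if sigma_psf.size == 1:
        sigma_psf = np.repeat(sigma_psf, 3)
    if sigma_small_um is None:
        sigma_small_um = 0.5 * sigma_psf
    if sigma_large_um is None:
        sigma_large_um = 3.0 * sigma_psf
    filtered = bandpass(img, sigma_small_um, sigma_large_um)
    candidates = find_maxima(filtered, threshold, min_separation)
    records: list[SpotRecord] = []
    for c in candidates:
        rec = gaussian_mask_fit(
            img, c, sigma_psf, max_iter=max_iter, tol=tol, window_radius=window_radius
        )
        if not rec.converged:
            continue
        if nuclei is not None:
            vox = tuple(int(round(v)) for v in rec.center_vox)
            if not img.grid.contains_voxel(vox):
                continue
            label = int(nuclei[vox])
            if label == 0:
                continue
            rec.nucleus = label
        records.append(rec)
    return records


def top_k_brightest(spots: list[SpotRecord], k: int) -> tuple[list[SpotRecord], bool]:
    """The ``k`` records of highest fitted intensity (ties by (z,y,x) center).

    Returns ``(records, shortfall)`` where shortfall flags fewer than k inputs.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(spots, key=lambda s: (-s.intensity, s.center_vox))
    return ordered[:k], len(spots) < k


def spots_to_frame(spots: list[SpotRecord]) -> pd.DataFrame:
    """Tabulate spot records (TSV-ready; voxel and μm coordinates)."""
    rows = []
    for s in spots:
        rows.append(
            {
                "channel": s.channel,
                "frame": s.frame,
                "z_vox": s.center_vox[0],
                "y_vox": s.center_vox[1],
                "x_vox": s.center_vox[2],
                "z_um": s.center_um[0],
                "y_um": s.center_um[1],
                "x_um": s.center_um[2],
                "intensity": s.intensity,
                "background": s.background,
                "converged": s.converged,
                "nucleus": s.nucleus,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "channel", "frame", "z_vox", "y_vox", "x_vox",
            "z_um", "y_um", "x_um", "intensity", "background", "converged", "nucleus",
        ],
    )
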