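"""Render diffraction-limited Gaussian spots into noisy volume images."""

from __future__ import annotations

import numpy as np

from ..grid import VoxelGrid, VolumeImage
from .truth import GroundTruth, SpotTruth

__all__ = ["add_gaussian_spot", "gen_spot_image", "apply_noise"]

_NOISE_MODELS = ("none", "poisson", "poisson+gaussian")


def add_gaussian_spot(
    data: np.ndarray,
    grid: VoxelGrid,
    center_um,
    amplitude: float,
    sigma_um,
    window_sigmas: float = 5.0,
) -> None:
    """Add one anisotropic 3D Gaussian (peak value = amplitude) in place.

    Evaluated on voxel centers within ±``window_sigmas``·σ of the center.
    """
    center = np.asarray(center_um, dtype=float)
    sigma = np.asarray(sigma_um, dtype=float)
    spacing = grid.spacing_arr
    c_vox = center / spacing
    s_vox = sigma / spacing
    lo = np.maximum(np.floor(c_vox - window_sigmas * s_vox).astype(int), 0)
    hi = np.minimum(
        np.ceil(c_vox + window_sigmas * s_vox).astype(int) + 1, np.asarray(grid.shape)
    )
    if np.any(lo >= hi):
        return
    ax = [np.arange(lo[d], hi[d]) * spacing[d] for d in range(3)]
    parts = [
        np.exp(-((ax[d] - center[d]) ** 2) / (2.0 * sigma[d] ** 2)) for d in range(3)
    ]
    patch = amplitude * parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += patch


def apply_noise(
    clean: np.ndarray,
    noise: str,
    rng: np.random.Generator,
    read_noise_sigma: float = 0.0,
) -> np.ndarray:
    """Apply the configured acquisition noise to a noiseless image."""
    if noise not in _NOISE_MODELS:
        raise ValueError(f"noise must be one of {_NOISE_MODELS}, got {noise!r}")
    if noise == "none":
        return clean.copy()
    out = rng.poisson(np.maximum(clean, 0.0)).astype(float)
    if noise == "poisson+gaussian":
        out = out + rng.normal(0.0, read_noise_sigma, size=out.shape)
    return out


def gen_spot_image(
    truth: GroundTruth,
    background: float,
    noise: str = "none",
    seed: int = 0,
    channel: str | None = None,
    read_noise_sigma: float = 0.0,
) -> VolumeImage:
    """Render ``truth.spots`` (optionally one channel) onto a flat background.

    Each spot's σ must be ≥ 0.5 voxel on every axis for adequate sampling.
    """
    if truth.grid is None:
        raise ValueError("truth must carry a VoxelGrid")
    grid = truth.grid
    spacing = grid.spacing_arr
    spots: list[SpotTruth] = [
        s for s in truth.spots if channel is None or s.channel == channel
    ]
    for s in spots:
        s_vox = np.asarray(s.sigma_um) / spacing
        if np.any(s_vox < 0.5):
            raise ValueError(
                f"spot sigma {s.sigma_um} μm is < 0.5 voxel on some axis "
                f"(spacing {grid.spacing})"
            )
    data = np.full(grid.shape, float(background))
    for s in spots:
        add_gaussian_spot(data, grid, s.center_um, s.amplitude, s.sigma_um)
    rng = np.random.default_rng(seed)
    data = apply_noise(data, noise, rng, read_noise_sigma)
    return VolumeImage(data=data, grid=grid, channel=channel)
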