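"""Multi-channel nuclear scenes with amorphous bodies and analytic expectations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grid import VoxelGrid, VolumeImage
from .nuclei import PlacementError, rasterize_ellipsoid
from .spots import apply_noise
from .truth import BodyTruth, GroundTruth

__all__ = ["BodySpec", "gen_body_scene"]


@dataclass
class BodySpec:
    """One body to plant inside a nucleus."""

    nucleus_label: int
    identity: str = "mir430"
    state: str = "initiating-elongating"
    semiaxes_vox: tuple[float, float, float] = (1.5, 2.5, 2.5)
    channel_intensity: dict[str, float] = field(default_factory=dict)


def _place_body(
    rng: np.random.Generator,
    nucleus_mask: np.ndarray,
    occupied: np.ndarray,
    semiaxes,
    max_tries: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a body mask strictly inside the nucleus, disjoint from others."""
    idx = np.argwhere(nucleus_mask)
    for _ in range(max_tries):
        center = idx[rng.integers(len(idx))] + rng.uniform(-0.5, 0.5, size=3)
        mask = rasterize_ellipsoid(nucleus_mask.shape, center, semiaxes)
        if not mask.any():
            continue
        if np.all(nucleus_mask[mask]) and not np.any(occupied[mask]):
            return center, mask
    raise PlacementError(
        f"could not place a body of semiaxes {tuple(semiaxes)} strictly inside "
        "its nucleus without overlapping existing bodies"
    )


def gen_body_scene(
    nuclei_labels: np.ndarray,
    grid: VoxelGrid,
    body_specs: list[BodySpec],
    seed: int,
    channels: tuple[str, ...] = ("cdk9", "ser2p"),
    nucleus_intensity: dict[str, float] | None = None,
    background: float = 0.0,
    no_primary_mean: float = 0.0,
    noise: str = "none",
    read_noise_sigma: float = 0.0,
) -> tuple[dict[str, VolumeImage], GroundTruth]:
    """Render bodies inside segmented nuclei and record analytic enrichment truth.

    Voxel values per channel: ``background`` outside nuclei, a flat nuclear
    level inside, plus each body's intensity on its own voxels. For every
    nucleus holding exactly two bodies the truth records the exact
    area/mean-intensity quantities of the enrichment formulas, computed from
    the noiseless rendering.
    """
    nucleus_intensity = nucleus_intensity or {c: 10.0 for c in channels}
    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed, grid=grid)
    occupied = np.zeros(nuclei_labels.shape, dtype=bool)
    body_masks: list[np.ndarray] = []

    for i, spec in enumerate(body_specs):
        nucleus_mask = nuclei_labels == spec.nucleus_label
        if not nucleus_mask.any():
            raise ValueError(f"nucleus label {spec.nucleus_label} not in label image")
        center, mask = _place_body(rng, nucleus_mask, occupied, spec.semiaxes_vox)
        occupied |= mask
        body_masks.append(mask)
        truth.bodies.append(
            BodyTruth(
                body_id=i,
                nucleus_label=spec.nucleus_label,
                identity=spec.identity,
                state=spec.state,
                center_vox=tuple(float(c) for c in center),
                semiaxes_vox=tuple(float(s) for s in spec.semiaxes_vox),
                channel_intensity=dict(spec.channel_intensity),
            )
        )

    clean: dict[str, np.ndarray] = {}
    for ch in channels:
        img = np.full(nuclei_labels.shape, float(background))
        img[nuclei_labels > 0] = nucleus_intensity.get(ch, 0.0)
        for spec, mask in zip(body_specs, body_masks):
            img[mask] += spec.channel_intensity.get(ch, 0.0)
        clean[ch] = img

    # analytic enrichment expectations for nuclei with exactly two bodies
    expectations: dict[str, dict] = {}
    labels_present = sorted(int(v) for v in np.unique(nuclei_labels) if v != 0)
    for label in labels_present:
        body_idx = [i for i, s in enumerate(body_specs) if s.nucleus_label == label]
        if len(body_idx) != 2:
            continue
        nucleus_mask = nuclei_labels == label
        m1, m2 = (body_masks[i] for i in body_idx)
        for ch in channels:
            img = clean[ch]
            a1, a2 = int(m1.sum()), int(m2.sum())
            an = int(nucleus_mask.sum())
            mi1 = float(img[m1].mean())
            mi2 = float(img[m2].mean())
            min_ = float(img[nucleus_mask].mean())
            corr = min_ - no_primary_mean
            pa = 100.0 * (a1 + a2) / an
            pi = 100.0 * (a1 * mi1 + a2 * mi2) / (an * corr)
            ie = ((a1 * mi1 + a2 * mi2) / (a1 + a2)) / corr
            expectations[f"{label}:{ch}"] = {
                "area_body1": a1,
                "area_body2": a2,
                "area_nucleus": an,
                "mean_body1": mi1,
                "mean_body2": mi2,
                "mean_nucleus": min_,
                "mean_nucleus_noprimary": no_primary_mean,
                "percentage_area": pa,
                "percentage_intensity": pi,
                "intensity_enrichment": ie,
            }
    truth.expectations["enrichment"] = expectations

    images = {
        ch: VolumeImage(
            data=apply_noise(clean[ch], noise, rng, read_noise_sigma),
            grid=grid,
            channel=ch,
        )
        for ch in channels
    }
    return images, truth
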