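"""Synthetic timelapses: body appearance, fusion and envelope-breakdown events."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grid import VoxelGrid, VolumeImage
from .nuclei import gen_nuclei, rasterize_ellipsoid
from .spots import apply_noise
from .truth import EventTruth, FrameTruth, GroundTruth

__all__ = ["BodySchedule", "NucleusSchedule", "TimelapseSpec", "gen_timelapse",
           "make_random_timelapse_spec"]

CHANNELS = ("ser5p", "ser2p", "movie")


@dataclass
class BodySchedule:
    identity: str  # "mir430" | "ectopic"
    state: str  # "initiating" | "initiating-elongating" | "elongating"
    appearance_frame: int
    offset_vox: tuple[float, float, float]  # relative to nucleus center
    semiaxes_vox: tuple[float, float, float] = (1.2, 1.8, 1.8)
    intensity: float = 60.0


@dataclass
class NucleusSchedule:
    label: int
    bodies: list[BodySchedule] = field(default_factory=list)
    fusion_frame: int | None = None  # fuses all mir430 bodies of this nucleus
    breakdown_frame: int | None = None


@dataclass
class TimelapseSpec:
    grid: VoxelGrid
    n_frames: int
    nuclei: list[NucleusSchedule]
    nucleus_base_intensity: float = 10.0
    background: float = 0.0


def _channels_for(identity: str, state: str) -> list[str]:
    chans = []
    if state in ("initiating", "initiating-elongating"):
        chans.append("ser5p")
    if state in ("elongating", "initiating-elongating"):
        chans.append("ser2p")
    if identity == "mir430":
        chans.append("movie")
    return chans


def gen_timelapse(
    spec: TimelapseSpec,
    seed: int,
    nuclei_labels: np.ndarray | None = None,
    nuclei_truth: GroundTruth | None = None,
    noise: str = "none",
    read_noise_sigma: float = 0.0,
) -> tuple[list[dict[str, VolumeImage]], np.ndarray, GroundTruth]:
    """Render a multi-channel frame sequence with scheduled body events.

    Frame schedules must be monotone per nucleus: appearance before fusion
    before envelope breakdown. Frames at or after a nucleus's breakdown are
    flagged non-analysable and carry no body signal for that nucleus; after a
    fusion the constituent mir430 bodies are replaced by a single blob at
    their mean offset, so per-frame truth counts drop accordingly while the
    fusion event itself is recorded.
    """
    grid = spec.grid
    if nuclei_labels is None:
        nuclei_labels, nuclei_truth = gen_nuclei(len(spec.nuclei), grid, seed)
    if nuclei_truth is None:
        raise ValueError("nuclei_truth required when nuclei_labels is supplied")
    centers = {e.label: np.asarray(e.center_vox) for e in nuclei_truth.nuclei}

    truth = GroundTruth(seed=seed, grid=grid, nuclei=list(nuclei_truth.nuclei))
    for nuc in spec.nuclei:
        mir_appear = [b.appearance_frame for b in nuc.bodies if b.identity == "mir430"]
        if nuc.fusion_frame is not None:
            if any(f >= nuc.fusion_frame for f in mir_appear):
                raise ValueError(
                    f"nucleus {nuc.label}: mir430 bodies must appear before fusion_frame"
                )
            truth.events.append(
                EventTruth(kind="fusion", nucleus_label=nuc.label, frame=nuc.fusion_frame)
            )
        if nuc.breakdown_frame is not None:
            if nuc.fusion_frame is not None and nuc.fusion_frame >= nuc.breakdown_frame:
                raise ValueError(
                    f"nucleus {nuc.label}: fusion must precede envelope breakdown"
                )
            truth.events.append(
                EventTruth(
                    kind="envelope_breakdown",
                    nucleus_label=nuc.label,
                    frame=nuc.breakdown_frame,
                )
            )

    rng = np.random.default_rng(seed)
    frames: list[dict[str, VolumeImage]] = []
    next_body_id = 0
    body_ids: dict[tuple[int, int], int] = {}
    for nuc in spec.nuclei:
        for j, _ in enumerate(nuc.bodies):
            body_ids[(nuc.label, j)] = next_body_id
            next_body_id += 1
    fused_ids = {nuc.label: next_body_id + i for i, nuc in enumerate(spec.nuclei)}

    for t in range(spec.n_frames):
        clean = {
            ch: np.full(grid.shape, float(spec.background)) for ch in CHANNELS
        }
        clean["ser5p"][nuclei_labels > 0] = spec.nucleus_base_intensity
        for nuc in spec.nuclei:
            analysable = nuc.breakdown_frame is None or t < nuc.breakdown_frame
            present: list[dict] = []
            if analysable:
                center = centers[nuc.label]
                fused = nuc.fusion_frame is not None and t >= nuc.fusion_frame
                mir = [b for b in nuc.bodies if b.identity == "mir430"]
                others = [b for b in nuc.bodies if b.identity != "mir430"]
                render: list[tuple[int, BodySchedule, np.ndarray]] = []
                if fused and len(mir) >= 2:
                    if all(b.appearance_frame <= t for b in mir):
                        mean_off = np.mean([b.offset_vox for b in mir], axis=0)
                        merged = BodySchedule(
                            identity="mir430",
                            state=mir[0].state,
                            appearance_frame=min(b.appearance_frame for b in mir),
                            offset_vox=tuple(mean_off),
                            semiaxes_vox=tuple(
                                float(s) * 1.26 for s in mir[0].semiaxes_vox
                            ),
                            intensity=mir[0].intensity,
                        )
                        render.append((fused_ids[nuc.label], merged, center + mean_off))
                else:
                    for j, b in enumerate(mir):
                        if b.appearance_frame <= t:
                            idx = nuc.bodies.index(b)
                            render.append(
                                (body_ids[(nuc.label, idx)], b, center + np.asarray(b.offset_vox))
                            )
                for b in others:
                    if b.appearance_frame <= t:
                        idx = nuc.bodies.index(b)
                        render.append(
                            (body_ids[(nuc.label, idx)], b, center + np.asarray(b.offset_vox))
                        )
                for body_id, b, pos in render:
                    mask = rasterize_ellipsoid(grid.shape, pos, b.semiaxes_vox)
                    mask &= nuclei_labels == nuc.label
                    for ch in _channels_for(b.identity, b.state):
                        clean[ch][mask] += b.intensity
                    present.append(
                        {
                            "body_id": int(body_id),
                            "identity": b.identity,
                            "state": b.state,
                            "center_vox": [float(p) for p in pos],
                        }
                    )
            truth.frames.append(
                FrameTruth(
                    frame=t,
                    nucleus_label=nuc.label,
                    analysable=analysable,
                    n_mir430=sum(1 for p in present if p["identity"] == "mir430"),
                    n_ectopic=sum(1 for p in present if p["identity"] == "ectopic"),
                    bodies=present,
                )
            )
        frames.append(
            {
                ch: VolumeImage(
                    data=apply_noise(clean[ch], noise, rng, read_noise_sigma),
                    grid=grid,
                    channel=ch,
                    frame=t,
                )
                for ch in CHANNELS
            }
        )
    return frames, nuclei_labels, truth


def make_random_timelapse_spec(
    n_nuclei: int,
    grid: VoxelGrid,
    n_frames: int,
    seed: int,
    p_fusion: float = 0.3,
    p_breakdown: float = 0.5,
    n_ectopic_range: tuple[int, int] = (0, 2),
    min_separation_vox: float = 6.0,
) -> tuple[TimelapseSpec, np.ndarray, GroundTruth]:
    """Build a randomized but well-separated schedule on freshly placed nuclei."""
    labels, nuc_truth = gen_nuclei(
        n_nuclei, grid, seed, semiaxes_range_vox=(7.0, 9.0)
    )
    rng = np.random.default_rng(seed + 1)
    states = ("initiating", "initiating-elongating", "elongating")
    schedules = []
    for e in nuc_truth.nuclei:
        semi = np.asarray(e.semiaxes_vox)
        bodies: list[BodySchedule] = []
        offsets: list[np.ndarray] = []

        def sample_offset() -> np.ndarray | None:
            for _ in range(200):
                off = rng.uniform(-0.45, 0.45, size=3) * semi
                if all(np.linalg.norm(off - o) >= min_separation_vox for o in offsets):
                    return off
            return None

        appear = int(rng.integers(0, 3))
        for _ in range(2):  # the two mir430-nucleated bodies
            off = sample_offset()
            if off is None:
                break
            offsets.append(off)
            bodies.append(
                BodySchedule(
                    identity="mir430",
                    state="initiating-elongating",
                    appearance_frame=appear,
                    offset_vox=tuple(off),
                )
            )
        for _ in range(int(rng.integers(*n_ectopic_range)) if n_ectopic_range[1] > n_ectopic_range[0] else n_ectopic_range[0]):
            off = sample_offset()
            if off is None:
                continue
            offsets.append(off)
            hi = max(appear + 1, min(appear + 3, n_frames - 1))
            bodies.append(
                BodySchedule(
                    identity="ectopic",
                    state=str(rng.choice(states)),
                    appearance_frame=int(rng.integers(appear, hi)),
                    offset_vox=tuple(off),
                    semiaxes_vox=(1.0, 1.4, 1.4),
                )
            )
        fusion = None
        if len(bodies) >= 2 and appear + 2 < n_frames and rng.random() < p_fusion:
            fusion = int(rng.integers(appear + 2, n_frames))
        breakdown = None
        if rng.random() < p_breakdown:
            lo = (fusion + 1) if fusion is not None else appear + 2
            if lo < n_frames:
                breakdown = int(rng.integers(lo, n_frames + 1))
                if breakdown >= n_frames:
                    breakdown = None
        if fusion is not None and breakdown is not None and fusion >= breakdown:
            fusion = None
        schedules.append(
            NucleusSchedule(
                label=e.label, bodies=bodies, fusion_frame=fusion, breakdown_frame=breakdown
            )
        )
    spec = TimelapseSpec(grid=grid, n_frames=n_frames, nuclei=schedules)
    return spec, labels, nuc_truth
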