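"""Transcription-body detection, classification and per-nucleus tracking.

Bodies are connected components of above-threshold signal inside segmented
nuclei. Identity (mir430 vs ectopic) comes from overlap with the reporter
(MOVIE) channel; state (initiating / initiating-elongating / elongating)
from pairing initiation (Ser5P) and elongation (Ser2P) bodies by proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grid import VolumeImage, VoxelGrid

__all__ = [
    "NucleusMask",
    "BodyRecord",
    "segment_nuclei",
    "detect_bodies",
    "merge_by_reference",
    "classify_identity",
    "classify_state",
    "track_and_time",
    "summarize_counts",
]

STATES = ("initiating", "initiating-elongating", "elongating")


@dataclass
class NucleusMask:
    label: int
    mask: np.ndarray  # boolean, full image shape
    frame: int | None = None
    analysable: bool = True

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError(f"nucleus {self.label}: empty mask")


@dataclass
class BodyRecord:
    voxels: np.ndarray  # (N, 3) int voxel indices
    shape: tuple[int, int, int]
    grid: VoxelGrid
    nucleus: int
    frame: int | None = None
    channel: str | None = None
    total_intensity: float = 0.0
    identity: str = "unassigned"
    state: str | None = None
    source_channels: tuple[str, ...] = ()
    track_id: int | None = field(default=None, compare=False)

    @property
    def size(self) -> int:
        return len(self.voxels)

    @property
    def mean_intensity(self) -> float:
        return self.total_intensity / self.size if self.size else 0.0

    @property
    def centroid_vox(self) -> np.ndarray:
        return self.voxels.mean(axis=0)

    @property
    def centroid_um(self) -> np.ndarray:
        return self.centroid_vox * self.grid.spacing_arr

    def voxel_set(self) -> set[int]:
        return set(np.ravel_multi_index(self.voxels.T, self.shape).tolist())


def segment_nuclei(
    img: VolumeImage,
    smoothing_sigma_um: float = 0.5,
    threshold: float | None = None,
    min_volume: int = 50,
    exclude_labels: set[int] | None = None,
) -> np.ndarray:
    """Smooth, threshold (Otsu by default) and label nuclei; returns label image.

    ``exclude_labels`` stands in for manual curation: those labels are zeroed
    after connected-component labeling, keeping runs reproducible.
    """
    sigma_vox = smoothing_sigma_um / img.grid.spacing_arr
    smoothed = ndimage.gaussian_filter(np.asarray(img.data, dtype=float), sigma_vox)
    if threshold is None:
        threshold = float(threshold_otsu(smoothed))
    binary = smoothed > threshold
    labels, n = ndimage.label(binary)
    out = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < min_volume:
            continue
        next_label += 1
        out[mask] = next_label
    if exclude_labels:
        for lab in exclude_labels:
            out[out == lab] = 0
    return out


def detect_bodies(
    img: VolumeImage,
    intensity_threshold: float,
    min_size: int,
    nuclei_labels: np.ndarray,
    frame: int | None = None,
) -> list[BodyRecord]:
    """Above-threshold connected components within nuclei, size ≥ min_size.

    The threshold is a single fixed value per channel per run, applied
    identically to every nucleus and frame.
    """
    data = np.asarray(img.data, dtype=float)
    records: list[BodyRecord] = []
    for nucleus in sorted(int(v) for v in np.unique(nuclei_labels) if v != 0):
        mask = (data > intensity_threshold) & (nuclei_labels == nucleus)
        labels, n = ndimage.label(mask)
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() < min_size:
                continue
            voxels = np.argwhere(comp)
            records.append(
                BodyRecord(
                    voxels=voxels,
                    shape=tuple(data.shape),
                    grid=img.grid,
                    nucleus=nucleus,
                    frame=frame if frame is not None else img.frame,
                    channel=img.channel,
                    total_intensity=float(data[comp].sum()),
                    source_channels=(img.channel,) if img.channel else (),
                )
            )
    return records


def _merge_records(group: list[BodyRecord]) -> BodyRecord:
    voxel_sets = [b.voxel_set() for b in group]
    union = set().union(*voxel_sets)
    voxels = np.stack(np.unravel_index(sorted(union), group[0].shape), axis=1)
    return BodyRecord(
        voxels=voxels,
        shape=group[0].shape,
        grid=group[0].grid,
        nucleus=group[0].nucleus,
        frame=group[0].frame,
        channel=group[0].channel,
        total_intensity=float(sum(b.total_intensity for b in group)),
        identity=group[0].identity,
        state=group[0].state,
        source_channels=tuple(
            dict.fromkeys(c for b in group for c in b.source_channels)
        ),
    )


def merge_by_reference(
    bodies: list[BodyRecord], reference_objects: list[BodyRecord]
) -> list[BodyRecord]:
    """Merge fragments that overlap the same reference object into one body.

    A large amorphous body can be detected as several fragments; any set of
    fragments sharing ≥1 voxel with the same reference object becomes a
    single record (union mask, summed intensity). Bodies overlapping no
    reference pass through unchanged. Never increases the body count.
    """
    ref_sets = [r.voxel_set() for r in reference_objects]
    groups: dict[int, list[BodyRecord]] = {}
    out: list[BodyRecord] = []
    for b in bodies:
        vox = b.voxel_set()
        best, best_overlap = None, 0
        for ri, rs in enumerate(ref_sets):
            ov = len(vox & rs)
            if ov > best_overlap:
                best, best_overlap = ri, ov
        if best is None:
            out.append(b)
        else:
            groups.setdefault(best, []).append(b)
    for ri in sorted(groups):
        group = groups[ri]
        out.append(group[0] if len(group) == 1 else _merge_records(group))
    return out


def classify_identity(
    ser2p_bodies: list[BodyRecord], movie_objects: list[BodyRecord]
) -> list[BodyRecord]:
    """Assign identity: ≥1 voxel of reporter overlap ⇒ mir430, else ectopic."""
    movie_sets = [m.voxel_set() for m in movie_objects]
    for b in ser2p_bodies:
        vox = b.voxel_set()
        b.identity = (
            "mir430" if any(vox & ms for ms in movie_sets) else "ectopic"
        )
    return ser2p_bodies


def _greedy_pairs(
    a: list[BodyRecord], b: list[BodyRecord], radius_um: float
) -> list[tuple[int, int]]:
    """One-to-one greedy matching by ascending centroid distance (μm)."""
    cands = []
    for i, ba in enumerate(a):
        for j, bb in enumerate(b):
            d = float(np.linalg.norm(ba.centroid_um - bb.centroid_um))
            if d <= radius_um:
                cands.append((d, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def classify_state(
    ser5p_bodies: list[BodyRecord],
    ser2p_bodies: list[BodyRecord],
    pairing_radius_um: float = 0.5,
) -> list[BodyRecord]:
    """Pair initiation and elongation bodies into state-labeled records.

    A Ser5P body with a Ser2P partner within the pairing radius becomes one
    initiating-elongating record (union mask); unpaired Ser5P bodies are
    initiating, unpaired Ser2P bodies elongating. Every input body is
    represented exactly once in the output.
    """
    pairs = _greedy_pairs(ser5p_bodies, ser2p_bodies, pairing_radius_um)
    paired_5 = {i for i, _ in pairs}
    paired_2 = {j for _, j in pairs}
    out: list[BodyRecord] = []
    for i, j in pairs:
        merged = _merge_records([ser5p_bodies[i], ser2p_bodies[j]])
        merged.state = "initiating-elongating"
        if ser2p_bodies[j].identity != "unassigned":
            merged.identity = ser2p_bodies[j].identity
        out.append(merged)
    for i, b in enumerate(ser5p_bodies):
        if i not in paired_5:
            b.state = "initiating"
            out.append(b)
    for j, b in enumerate(ser2p_bodies):
        if j not in paired_2:
            b.state = "elongating"
            out.append(b)
    return out


def classify_frame(
    channels: dict[str, VolumeImage],
    nuclei_labels: np.ndarray,
    intensity_threshold: float,
    min_size: int = 3,
    pairing_radius_um: float = 0.5,
    frame: int | None = None,
    body_channels: tuple[str, str] = ("ser5p", "ser2p"),
    reporter_channel: str = "movie",
    nucleus_base_threshold: float | None = None,
) -> list[BodyRecord]:
    """One-frame pipeline: detect, merge on the reporter, classify state+identity.

    The initiation channel carries diffuse nuclear signal, so its detection
    threshold can be raised separately via ``nucleus_base_threshold``.
    Identity is assigned to every output record (reporter overlap ⇒ mir430),
    not only elongation bodies, so purely initiating bodies are classified
    too.
    """
    ch5, ch2 = body_channels
    thr5 = nucleus_base_threshold if nucleus_base_threshold is not None else intensity_threshold
    b5 = detect_bodies(channels[ch5], thr5, min_size, nuclei_labels, frame=frame)
    b2 = detect_bodies(channels[ch2], intensity_threshold, min_size, nuclei_labels, frame=frame)
    movie = (
        detect_bodies(channels[reporter_channel], intensity_threshold, min_size,
                      nuclei_labels, frame=frame)
        if reporter_channel in channels
        else []
    )
    b2 = merge_by_reference(b2, movie)
    b5 = merge_by_reference(b5, movie)
    b2 = classify_identity(b2, movie)
    classified = classify_state(b5, b2, pairing_radius_um)
    return classify_identity(classified, movie)


def track_and_time(
    per_frame: list[tuple[int, list[BodyRecord]]],
    breakdown_frames: dict[int, int | None],
    linking_radius_um: float = 1.0,
) -> dict[int, pd.DataFrame]:
    """Per-nucleus time series with cell-cycle alignment and fusion handling.

    Frames at or after a nucleus's envelope breakdown are excluded; t = 0 is
    the first analysed frame with ≥1 body; nuclei whose bodies are seen in
    exactly one frame are dropped. Bodies are linked across frames by
    nearest centroid within the linking radius; an observed fusion of
    mir430-body tracks never reduces that nucleus's reported mir430 count.
    """
    frames_idx = [f for f, _ in per_frame]
    if frames_idx != sorted(frames_idx) or len(set(frames_idx)) != len(frames_idx):
        raise ValueError("frames must be strictly time-ordered")

    nuclei = sorted(
        {b.nucleus for _, bodies in per_frame for b in bodies}
        | set(breakdown_frames.keys())
    )
    series: dict[int, pd.DataFrame] = {}
    for nucleus in nuclei:
        breakdown = breakdown_frames.get(nucleus)
        frames = [
            (f, [b for b in bodies if b.nucleus == nucleus])
            for f, bodies in per_frame
            if breakdown is None or f < breakdown
        ]
        occupied = [f for f, bodies in frames if bodies]
        if len(occupied) <= 1:
            continue
        t0 = occupied[0]
        rows = []
        prev: list[BodyRecord] = []
        fusion_bonus = 0
        for f, bodies in frames:
            if f < t0:
                continue
            pairs = _greedy_pairs(prev, bodies, linking_radius_um)
            matched_prev = {i for i, _ in pairs}
            # fusion: a lost mir430 track whose last position sits on a
            # surviving mir430 body means two bodies became one
            for i, b_prev in enumerate(prev):
                if i in matched_prev or b_prev.identity != "mir430":
                    continue
                for j, b_now in enumerate(bodies):
                    if b_now.identity != "mir430":
                        continue
                    d = float(np.linalg.norm(b_prev.centroid_um - b_now.centroid_um))
                    if d <= linking_radius_um and j in {jj for _, jj in pairs}:
                        fusion_bonus += 1
                        break
            n_mir = sum(1 for b in bodies if b.identity == "mir430")
            n_ect = sum(1 for b in bodies if b.identity == "ectopic")
            row = {
                "frame": f,
                "t": f - t0,
                "n_bodies": len(bodies),
                "n_mir430_detected": n_mir,
                "n_mir430": n_mir + (fusion_bonus if n_mir else 0),
                "n_ectopic": n_ect,
            }
            for st in STATES:
                row[f"n_{st}"] = sum(1 for b in bodies if b.state == st)
            rows.append(row)
            prev = bodies
        series[nucleus] = pd.DataFrame(rows)
    return series


def summarize_counts(series: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-timepoint counts and state percentages pooled over nuclei.

    Percentages are of all bodies present at that timepoint and sum to 100
    where any body exists; timepoints with zero bodies report NA.
    """
    frames = []
    for nucleus, df in series.items():
        d = df.copy()
        d["nucleus"] = nucleus
        frames.append(d)
    if not frames:
        return pd.DataFrame()
    allb = pd.concat(frames, ignore_index=True)
    out_rows = []
    for t, grp in allb.groupby("t"):
        total = int(grp["n_bodies"].sum())
        row = {
            "t": int(t),
            "n_nuclei": int(grp["nucleus"].nunique()),
            "mean_bodies_per_nucleus": float(grp["n_bodies"].mean()),
            "mean_mir430_per_nucleus": float(grp["n_mir430"].mean()),
            "mean_ectopic_per_nucleus": float(grp["n_ectopic"].mean()),
            "n_bodies_total": total,
        }
        for st in STATES:
            n_st = int(grp[f"n_{st}"].sum())
            row[f"pct_{st}"] = 100.0 * n_st / total if total else np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows).sort_values("t").reset_index(drop=True)
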