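"""Ground-truth containers for all synthetic generators.

Every rendered object (nucleus, spot, body, read) has exactly one truth
entry, and the whole structure round-trips through JSON without loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from ..grid import VoxelGrid

__all__ = [
    "EllipsoidTruth",
    "SpotTruth",
    "BodyTruth",
    "FrameTruth",
    "EventTruth",
    "FragmentTruth",
    "SnpTruth",
    "GroundTruth",
]


@dataclass
class EllipsoidTruth:
    """An axis-aligned ellipsoidal nucleus: center/semiaxes in voxel units."""

    label: int
    center_vox: tuple[float, float, float]
    semiaxes_vox: tuple[float, float, float]


@dataclass
class SpotTruth:
    """A diffraction-limited Gaussian spot."""

    center_um: tuple[float, float, float]
    amplitude: float
    sigma_um: tuple[float, float, float]
    channel: str
    spot_id: int = 0


@dataclass
class BodyTruth:
    """A larger amorphous transcription body (ellipsoidal blob)."""

    body_id: int
    nucleus_label: int
    identity: str  # "mir430" | "ectopic"
    state: str  # "initiating" | "initiating-elongating" | "elongating"
    center_vox: tuple[float, float, float]
    semiaxes_vox: tuple[float, float, float]
    channel_intensity: dict[str, float] = field(default_factory=dict)
    appearance_frame: int = 0


@dataclass
class EventTruth:
    kind: str  # "appearance" | "fusion" | "envelope_breakdown"
    nucleus_label: int
    frame: int
    body_ids: list[int] = field(default_factory=list)


@dataclass
class FrameTruth:
    """Per-frame, per-nucleus body inventory."""

    frame: int
    nucleus_label: int
    analysable: bool
    n_mir430: int
    n_ectopic: int
    bodies: list[dict] = field(default_factory=list)  # body_id, identity, state, center_vox


@dataclass
class SnpTruth:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str


@dataclass
class FragmentTruth:
    fragment_id: str
    gene_id: str
    chrom: str
    strand: str  # transcript strand
    start: int  # 0-based, fragment span on genome
    end: int
    labeled: bool
    conversion_positions: list[int] = field(default_factory=list)
    # final planted differences per read: {"r1": [[pos, base], ...], "r2": [...]}
    read_mismatches: dict[str, list] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Union container; generators populate the sections they produce."""

    seed: int
    grid: VoxelGrid | None = None
    nuclei: list[EllipsoidTruth] = field(default_factory=list)
    spots: list[SpotTruth] = field(default_factory=list)
    bodies: list[BodyTruth] = field(default_factory=list)
    frames: list[FrameTruth] = field(default_factory=list)
    events: list[EventTruth] = field(default_factory=list)
    fragments: list[FragmentTruth] = field(default_factory=list)
    snps: list[SnpTruth] = field(default_factory=list)
    # free-form analytic expectations (e.g. enrichment values per nucleus)
    expectations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = self.grid.to_dict() if self.grid is not None else None
        # normalize tuples to lists so dict equality matches a JSON round-trip
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        grid = VoxelGrid.from_dict(d["grid"]) if d.get("grid") else None
        return cls(
            seed=d["seed"],
            grid=grid,
            nuclei=[EllipsoidTruth(**n) for n in d.get("nuclei", [])],
            spots=[SpotTruth(**s) for s in d.get("spots", [])],
            bodies=[BodyTruth(**b) for b in d.get("bodies", [])],
            frames=[FrameTruth(**f) for f in d.get("frames", [])],
            events=[EventTruth(**e) for e in d.get("events", [])],
            fragments=[FragmentTruth(**f) for f in d.get("fragments", [])],
            snps=[SnpTruth(**s) for s in d.get("snps", [])],
            expectations=d.get("expectations", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))
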