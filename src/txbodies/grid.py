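"""Voxel-grid geometry and single-channel volume images.

One convention throughout the package: axis order is (z, y, x), voxel
indices are 0-based, and the physical coordinate of a voxel center is
``index * spacing`` in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelGrid", "VolumeImage", "write_volume", "read_volume"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D voxel grid with anisotropic spacing.

    Parameters
    ----------
    shape
        Voxel counts along (z, y, x).
    spacing
        Micrometres per voxel along (z, y, x).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("shape and spacing must be length-3 (z, y, x)")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(not (float(s) > 0) for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    def voxel_to_um(self, idx) -> np.ndarray:
        """Physical coordinate (μm) of voxel center(s) ``idx`` (z, y, x)."""
        return np.asarray(idx, dtype=float) * self.spacing_arr

    def um_to_voxel(self, pos) -> np.ndarray:
        """Fractional voxel index of a physical coordinate (μm)."""
        return np.asarray(pos, dtype=float) / self.spacing_arr

    def contains_voxel(self, idx) -> bool:
        idx = np.asarray(idx)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    def to_dict(self) -> dict:
        return {"shape": list(self.shape), "spacing": list(self.spacing)}

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGrid":
        return cls(shape=tuple(d["shape"]), spacing=tuple(d["spacing"]))


@dataclass
class VolumeImage:
    """One channel of a 3D stack on a :class:`VoxelGrid`."""

    data: np.ndarray
    grid: VoxelGrid
    channel: str | None = None
    frame: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D (z, y, x) data, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


def write_volume(img: VolumeImage, path: str | Path) -> None:
    """Write a volume as multi-page TIFF plus a JSON sidecar with grid metadata."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(img.data, dtype=np.float32), photometric="minisblack"
    )
    sidecar = {
        "grid": img.grid.to_dict(),
        "channel": img.channel,
        "frame": img.frame,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path) -> VolumeImage:
    """Read a TIFF written by :func:`write_volume` (sidecar JSON required)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"grid metadata sidecar missing for {path}: expected {sidecar_path}"
        )
    sidecar = json.loads(sidecar_path.read_text())
    return VolumeImage(
        data=data,
        grid=VoxelGrid.from_dict(sidecar["grid"]),
        channel=sidecar.get("channel"),
        frame=sidecar.get("frame"),
    )
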