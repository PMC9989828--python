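"""4D time-lapse container and TIFF round-trip.

A :class:`TimelapseStack` is the unit every tracking stage consumes: a
``(t, z, y, x)`` intensity array with anisotropic voxel sizes (µm) and
per-frame timestamps (s). On disk it is a multi-page TIFF plus a sidecar
JSON carrying voxel sizes, timestamps and the generator seed, so that a
round trip preserves both pixels and metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["TimelapseStack", "read_timelapse", "write_timelapse"]


@dataclass
class TimelapseStack:
    """4D fluorescence stack with physical calibration.

    Parameters
    ----------
    data
        Intensity array with axes ``(t, z, y, x)``.
    voxel_size_xy, voxel_size_z
        Voxel edge lengths in µm. ``voxel_size_z >= voxel_size_xy`` in
        confocal acquisitions (e.g. 0.12 µm pixels, 0.4 µm z sections).
    timestamps
        Acquisition time of each frame in seconds, strictly increasing.
    metadata
        Free-form extras (seed, ground-truth provenance, ...).
    """

    data: np.ndarray
    voxel_size_xy: float
    voxel_size_z: float
    timestamps: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected a (t, z, y, x) array, got ndim={self.data.ndim}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.data.shape[0],):
            raise ValueError("timestamps must have one entry per frame")
        if self.data.shape[0] > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.voxel_size_xy <= 0 or self.voxel_size_z <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        """Voxel edge lengths in µm, ordered like the array axes."""
        return (self.voxel_size_z, self.voxel_size_xy, self.voxel_size_xy)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³ (anisotropic)."""
        return self.voxel_size_z * self.voxel_size_xy**2

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timelapse(stack: TimelapseStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with a sidecar metadata JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, stack.data, photometric="minisblack", metadata={"axes": "TZYX"}
    )
    sidecar = {
        "voxel_size_xy_um": stack.voxel_size_xy,
        "voxel_size_z_um": stack.voxel_size_z,
        "timestamps_s": stack.timestamps.tolist(),
        "metadata": stack.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_timelapse(
    path: str | Path,
    *,
    voxel_size_xy: float | None = None,
    voxel_size_z: float | None = None,
    frame_interval: float | None = None,
) -> TimelapseStack:
    """Read a TIFF stack, taking calibration from the sidecar JSON.

    Calibration missing from the sidecar must be supplied via keywords;
    missing timestamps are reconstructed as a uniform grid from
    ``frame_interval``. An unambiguous ``(t, z, y, x)`` axis order is
    required: 3D arrays are promoted to a single-frame stack.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[np.newaxis]
    if data.ndim != 4:
        raise ValueError(
            f"cannot infer (t, z, y, x) axes from a {data.ndim}-D TIFF; "
            "re-save with explicit axes or supply a 4D stack"
        )

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    vxy = meta.get("voxel_size_xy_um", voxel_size_xy)
    vz = meta.get("voxel_size_z_um", voxel_size_z)
    if vxy is None or vz is None:
        raise ValueError(
            "voxel sizes not found in sidecar metadata and not supplied; "
            "pass voxel_size_xy= and voxel_size_z= (µm)"
        )
    ts = meta.get("timestamps_s")
    if ts is None:
        if frame_interval is None:
            raise ValueError(
                "no timestamps in sidecar and no frame_interval supplied"
            )
        ts = np.arange(data.shape[0], dtype=float) * frame_interval
    return TimelapseStack(
        data=data,
        voxel_size_xy=float(vxy),
        voxel_size_z=float(vz),
        timestamps=np.asarray(ts, dtype=float),
        metadata=meta.get("metadata", {}),
    )
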