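"""Volumetric containers shared across the imaging toolkit.

A :class:`VolumeImage` is a 3D scalar field of EPR signal intensity on a
regular, (by default) isotropic grid described by a field of view in mm and
the coordinate of the first voxel center.  An :class:`ImageSeries` is a
time-ordered list of such volumes with per-frame timestamps, the input of
the voxelwise decay-rate fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def _as_triple(value) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"expected a scalar or 3-vector, got shape {arr.shape}")
    return tuple(float(v) for v in arr)


@dataclass
class VolumeImage:
    """3D scalar field with physical geometry.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)``, signal intensity in arbitrary units.
    fov:
        Field of view per axis in mm (scalar for an isotropic cube).
    origin:
        mm coordinate of the *center* of voxel ``(0, 0, 0)``.  Default places
        the volume symmetrically about the coordinate origin.
    """

    data: np.ndarray
    fov: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(np.asarray(self.data, dtype=np.float64))
        if self.data.ndim != 3:
            raise ValueError("VolumeImage.data must be 3D")
        self.fov = _as_triple(self.fov)
        if self.origin is None:
            self.origin = tuple(
                -(n - 1) / 2.0 * s for n, s in zip(self.data.shape, self.spacing)
            )
        else:
            self.origin = _as_triple(self.origin)

    @property
    def matrix(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov, self.data.shape))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-12 and abs(s[1] - s[2]) < 1e-12

    def axis_coords(self, axis: int) -> np.ndarray:
        """mm coordinates of voxel centers along ``axis``."""
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.axis_coords(a) for a in range(3))

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """New volume on the same grid with different voxel values."""
        return VolumeImage(np.asarray(data, dtype=np.float64), self.fov, self.origin)

    def same_grid(self, other: "VolumeImage", tol: float = 1e-9) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.fov, other.fov, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class ImageSeries:
    """Time-ordered volumes with per-frame timestamps.

    ``times`` holds the frame mid-scan times; ``time_unit`` is ``"s"`` or
    ``"min"``.  Decay rates fitted from a series carry the reciprocal unit.
    """

    frames: list[VolumeImage]
    times: np.ndarray
    time_unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != self.times.size:
            raise ValueError("frame count and timestamp count differ")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.time_unit not in ("s", "min"):
            raise ValueError("time_unit must be 's' or 'min'")
        first = self.frames[0]
        for f in self.frames[1:]:
            if not first.same_grid(f):
                raise ValueError("all frames must share one grid")

    def __len__(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        """Frames as one array of shape ``(n_frames, nx, ny, nz)``."""
        return np.stack([f.data for f in self.frames])

    def times_in(self, unit: str) -> np.ndarray:
        if unit == self.time_unit:
            return self.times.copy()
        if (self.time_unit, unit) == ("s", "min"):
            return self.times / 60.0
        if (self.time_unit, unit) == ("min", "s"):
            return self.times * 60.0
        raise ValueError(f"unknown time unit {unit!r}")

    def scaled(self, factors: Sequence[float]) -> "ImageSeries":
        factors = np.asarray(factors, dtype=float)
        if factors.size != len(self.frames):
            raise ValueError("one scale factor per frame required")
        frames = [f.with_data(f.data * c) for f, c in zip(self.frames, factors)]
        return ImageSeries(frames, self.times.copy(), self.time_unit, dict(self.meta))
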