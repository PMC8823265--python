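"""Digital phantoms: synthetic stand-ins for the measured objects.

Two objects are provided.  The *multiple pillar phantom* is a cylinder bore
(21.8 mm diameter) holding ten radical-solution pillars of 3.0 mm diameter
and 15.0 mm length on a 5.0 mm center-to-center pitch (1.06 mL of solution
in total).  The exact in-plane hole layout is not printed anywhere; the
4-3-3 row pattern used here keeps the stated pitch, count and bore and is
documented as approximate.

The *two-compartment leg phantom* is a synthetic stand-in for a
tumor-bearing mouse leg: an ellipsoid of uniform initial amplitude with an
embedded spherical "tumor" whose decay rate differs from the surrounding
"normal" tissue (defaults 1.36 vs 1.00 min^-1, the group-mean rates of the
two tissue classes).  It exists because in-vivo data cannot be regenerated;
it emulates only the two-rate geometry, not vasculature or uptake kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageSeries, VolumeImage

__all__ = [
    "DecayPhantomSpec",
    "pillar_phantom",
    "two_compartment_leg_phantom",
    "decay_series",
    "frame_mid_times",
    "PILLAR_CENTERS_MM",
]

#: approximate Fig-2A-style hole centers (x, y) in mm: rows of 4, 3, 3 on the
#: 5.0 mm pitch, all holes inside the 21.8 mm bore.
PILLAR_CENTERS_MM: tuple[tuple[float, float], ...] = (
    (-7.5, 0.0),
    (-2.5, 0.0),
    (2.5, 0.0),
    (7.5, 0.0),
    (-5.0, 5.0),
    (0.0, 5.0),
    (5.0, 5.0),
    (-5.0, -5.0),
    (0.0, -5.0),
    (5.0, -5.0),
)

PILLAR_DIAMETER_MM = 3.0
PILLAR_LENGTH_MM = 15.0
BORE_DIAMETER_MM = 21.8


@dataclass
class DecayPhantomSpec:
    """A decaying object: initial amplitude field, rate field, frame times.

    ``rate_map`` is in min^-1; ``frame_times`` in seconds (strictly
    increasing).
    """

    base: VolumeImage
    rate_map: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.rate_map = np.asarray(self.rate_map, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.rate_map.shape != self.base.data.shape:
            raise ValueError("rate_map must match the base volume shape")
        if np.any(self.rate_map < 0):
            raise ValueError("decay rates must be >= 0")
        if self.frame_times.size >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")


def _supersampled_coords(n: int, fov: float, factor: int) -> np.ndarray:
    """Sub-voxel center coordinates for ``factor``x supersampling."""
    spacing = fov / n
    fine = fov / (n * factor)
    start = -(n * factor - 1) / 2.0 * fine
    del spacing
    return start + np.arange(n * factor) * fine


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    n0, n1, n2 = (s // factor for s in data.shape)
    return (
        data.reshape(n0, factor, n1, factor, n2, factor)
        .mean(axis=(1, 3, 5))
    )


def pillar_phantom(matrix: int, fov: float, supersample: int = 8) -> VolumeImage:
    """Ten-pillar solution phantom, intensity 1 inside the pillars.

    Pillar axes run along z; the mid-height plane shows the ten discs of
    the cross-section pattern.  The construction is separable: an
    anti-aliased in-plane disc mask (``supersample``x supersampling of the
    cross-section) times an exact 1D partial-volume profile along z, which
    keeps the total solution volume within a fraction of a percent of
    10 pi (1.5 mm)^2 15 mm ~ 1060 mm^3 at any grid size.
    """
    if fov < BORE_DIAMETER_MM:
        raise ValueError(f"fov must be >= {BORE_DIAMETER_MM} mm to hold the phantom")
    c = _supersampled_coords(matrix, fov, supersample)
    x = c[:, None]
    y = c[None, :]
    r2 = (PILLAR_DIAMETER_MM / 2.0) ** 2
    plane = np.zeros((c.size, c.size))
    for cx, cy in PILLAR_CENTERS_MM:
        plane += ((x - cx) ** 2 + (y - cy) ** 2) <= r2
    np.clip(plane, 0.0, 1.0, out=plane)
    plane = plane.reshape(matrix, supersample, matrix, supersample).mean(axis=(1, 3))

    # exact voxel coverage of |z| <= L/2 along the pillar axis
    spacing = fov / matrix
    zc = -(matrix - 1) / 2.0 * spacing + np.arange(matrix) * spacing
    zprof = np.clip(
        (PILLAR_LENGTH_MM / 2.0 - np.abs(zc)) / spacing + 0.5, 0.0, 1.0
    )
    return VolumeImage(plane[:, :, None] * zprof[None, None, :], fov)


def two_compartment_leg_phantom(
    matrix: int,
    fov: float = 37.5,
    rate_normal: float = 1.00,
    rate_tumor: float = 1.36,
    leg_semiaxes: tuple[float, float, float] = (7.0, 7.0, 12.0),
    tumor_radius: float = 3.5,
    tumor_center: tuple[float, float, float] = (0.0, 0.0, 5.0),
    frame_times: np.ndarray | None = None,
    supersample: int = 2,
) -> DecayPhantomSpec:
    """Ellipsoidal "leg" with an embedded spherical "tumor".

    The amplitude field is 1 inside the leg (edge anti-aliased); the rate
    map holds exactly two values: ``rate_tumor`` inside the tumor sphere and
    ``rate_normal`` everywhere else, in min^-1.
    """
    if rate_normal < 0 or rate_tumor < 0:
        raise ValueError("decay rates must be >= 0")
    c = _supersampled_coords(matrix, fov, supersample)
    x = c[:, None, None]
    y = c[None, :, None]
    z = c[None, None, :]
    a, b, cc = leg_semiaxes
    leg = ((x / a) ** 2 + (y / b) ** 2 + (z / cc) ** 2) <= 1.0
    base = VolumeImage(_downsample(leg.astype(np.float64), supersample), fov)

    vol = base  # rate map on the target grid (no averaging: exactly 2 values)
    gx, gy, gz = vol.coords()
    tx, ty, tz = tumor_center
    dist2 = (
        (gx[:, None, None] - tx) ** 2
        + (gy[None, :, None] - ty) ** 2
        + (gz[None, None, :] - tz) ** 2
    )
    rate_map = np.full(vol.data.shape, rate_normal)
    rate_map[dist2 <= tumor_radius**2] = rate_tumor

    if frame_times is None:
        frame_times = frame_mid_times()
    return DecayPhantomSpec(base, rate_map, np.asarray(frame_times, dtype=float))


def frame_mid_times(
    n_frames: int = 12, frame_duration_s: float = 16.8, start_s: float = 30.0
) -> np.ndarray:
    """Mid-scan timestamps of the serial acquisition, in seconds.

    Twelve back-to-back 16.8 s scans (128 projections + zero-gradient at
    130 ms each) starting 30 s post-injection; the frame time is the
    mid-acquisition time, which minimizes timestamp bias for an exponential
    decay sampled by a finite scan.
    """
    starts = start_s + frame_duration_s * np.arange(n_frames)
    return starts + frame_duration_s / 2.0


def decay_series(spec: DecayPhantomSpec) -> ImageSeries:
    """Voxelwise exponential decay: frame f = base * exp(-k * t_f).

    ``rate_map`` is in min^-1 and ``frame_times`` in seconds, so the
    exponent uses ``t / 60``.  Frame timestamps are kept in seconds.
    """
    frames = []
    for t in spec.frame_times:
        frames.append(
            spec.base.with_data(spec.base.data * np.exp(-spec.rate_map * t / 60.0))
        )
    return ImageSeries(frames, spec.frame_times.copy(), time_unit="s")
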