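"""File formats: HDF5 projection containers, NIfTI volumes, CSV, YAML.

A spectral projection set lives in a single HDF5 container (arrays
``/spectra``, ``/field_axis_mT``, ``/directions`` and optionally
``/zero_gradient``; scan-protocol fields and the frame timestamp as root
attributes, plus a ``schema_version``).  Volumes are written as NIfTI with
the mm voxel spacing and the first-voxel-center coordinate in the affine.
All round-trips are lossless (bit-exact arrays).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .forward import ScanProtocol, SpectralProjectionSet
from .geometry import DirectionSet
from .volume import VolumeImage

__all__ = [
    "SchemaError",
    "save_projections",
    "load_projections",
    "save_volume",
    "load_volume",
    "load_yaml_config",
    "write_manifest",
]

SCHEMA_VERSION = "1"

_PROTOCOL_ATTRS = (
    "sweep_width",
    "scan_duration",
    "flyback_duration",
    "gradient_magnitude",
    "n_field_points",
    "includes_zero_gradient",
)


class SchemaError(RuntimeError):
    """A container is missing required members or has a wrong version."""


def save_projections(path, s: SpectralProjectionSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["timestamp_s"] = s.timestamp
        f.attrs["direction_scheme"] = s.directions.scheme
        for name in _PROTOCOL_ATTRS:
            f.attrs[name] = getattr(s.protocol, name)
        f.create_dataset("spectra", data=s.spectra)
        f.create_dataset("field_axis_mT", data=s.field_axis)
        f.create_dataset("directions", data=s.directions.vectors)
        if s.zero_gradient_spectrum is not None:
            f.create_dataset("zero_gradient", data=s.zero_gradient_spectrum)


def load_projections(path) -> SpectralProjectionSet:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported projection-container schema {version!r} "
                f"(expected {SCHEMA_VERSION!r})"
            )
        for name in ("spectra", "field_axis_mT", "directions"):
            if name not in f:
                raise SchemaError(f"projection container missing /{name}")
        protocol = ScanProtocol(
            sweep_width=float(f.attrs["sweep_width"]),
            scan_duration=float(f.attrs["scan_duration"]),
            flyback_duration=float(f.attrs["flyback_duration"]),
            gradient_magnitude=float(f.attrs["gradient_magnitude"]),
            n_field_points=int(f.attrs["n_field_points"]),
            includes_zero_gradient=bool(f.attrs["includes_zero_gradient"]),
        )
        zero_g = f["zero_gradient"][()] if "zero_gradient" in f else None
        return SpectralProjectionSet(
            DirectionSet(f["directions"][()], str(f.attrs["direction_scheme"])),
            f["field_axis_mT"][()],
            f["spectra"][()],
            protocol,
            zero_g,
            float(f.attrs["timestamp_s"]),
        )


def save_volume(path, v: VolumeImage) -> None:
    """Write a volume as NIfTI; spacing and first-voxel center in the affine."""
    affine = np.diag(list(v.spacing) + [1.0])
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(v.data, affine), str(path))


def load_volume(path) -> VolumeImage:
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.diag(affine)[:3]
    data = np.asarray(img.dataobj, dtype=np.float64)
    fov = tuple(s * n for s, n in zip(spacing, data.shape))
    return VolumeImage(data, fov, tuple(affine[:3, 3]))


def load_yaml_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping")
    return cfg


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, inputs=()) -> Path:
    """Record config, seed, package version and input hashes for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "eprredox",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_hashes": {str(p): _file_sha256(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
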