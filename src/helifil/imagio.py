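"""MRC stack/volume I/O, sidecar metadata tables, and run configuration.

Images and volumes travel as MRC2014 files restricted to mode 2 (32-bit
float); other modes are rejected rather than converted so that write->read
round-trips are bit-exact.  MRC carries no per-image records, so per-image
metadata (ground-truth helical parameters for synthetic data, assigned
orientations, class labels, defocus) lives in a sidecar TSV keyed by image
index.

Coordinate convention used throughout the package: the helical axis is the z
grid axis through the box centre; for side-view images the in-plane axes map
to (z, x) = (row, column); angles are degrees and a right-handed helix has
positive twist.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ImageStack", "VolumeGrid", "RunConfig",
    "FormatError", "ConfigError",
    "read_stack", "write_stack", "read_volume", "write_volume",
    "read_metadata", "write_metadata", "load_config",
]

_HEADER_SIZE = 1024
_MRC_MODE_FLOAT32 = 2
_MAP_ID = b"MAP "

# columns of the sidecar metadata table
METADATA_COLUMNS = [
    "id", "state", "pitch_true", "twist_true",
    "phi", "theta", "psi", "defocus", "class",
]


class FormatError(ValueError):
    """A file violates the MRC/TSV contract; the message names the field."""


class ConfigError(ValueError):
    """A run configuration is malformed; the message lists offending keys."""


@dataclass
class ImageStack:
    """An ordered set of square 2-D images with one shared pixel size."""

    images: np.ndarray          # (n, box, box) float32
    pixel_size: float           # Angstrom / px
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.images = np.ascontiguousarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise FormatError(f"stack must be 3-D (n, box, box), got shape {self.images.shape}")
        n, ny, nx = self.images.shape
        if n == 0:
            raise FormatError("empty stack: header declares 0 images")
        if ny != nx:
            raise FormatError(f"images must be square, got {ny}x{nx}")
        if nx < 16 or nx % 2:
            raise FormatError(f"box size must be even and >= 16, got {nx}")
        if not self.pixel_size > 0:
            raise FormatError(f"pixel_size must be positive, got {self.pixel_size}")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def box_size(self) -> int:
        return self.images.shape[1]


@dataclass
class VolumeGrid:
    """A cubic 3-D density map; axis 0 (z) is the helical axis."""

    voxels: np.ndarray          # (n, n, n) float32
    voxel_size: float           # Angstrom

    def __post_init__(self) -> None:
        self.voxels = np.ascontiguousarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise FormatError(f"volume must be 3-D, got shape {self.voxels.shape}")
        nz, ny, nx = self.voxels.shape
        if not (nz == ny == nx):
            raise FormatError(f"volume must be cubic, got {self.voxels.shape}")
        if not self.voxel_size > 0:
            raise FormatError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def box_size(self) -> int:
        return self.voxels.shape[0]


def _pack_header(nx: int, ny: int, nz: int, pixel_size: float) -> bytes:
    """Minimal MRC2014 header for a mode-2 file."""
    h = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", h, 0, nx, ny, nz)
    struct.pack_into("<i", h, 12, _MRC_MODE_FLOAT32)
    struct.pack_into("<3i", h, 28, nx, ny, nz)              # mx, my, mz
    struct.pack_into("<3f", h, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size)
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)        # cell angles
    struct.pack_into("<3i", h, 64, 1, 2, 3)                 # axis order
    struct.pack_into("<i", h, 92, 0)                        # nsymbt
    h[208:212] = _MAP_ID
    h[212:216] = b"\x44\x44\x00\x00"                        # little-endian stamp
    return bytes(h)


def _read_header(raw: bytes, path) -> tuple[int, int, int, float]:
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: truncated header ({len(raw)} bytes)")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    mode, = struct.unpack_from("<i", raw, 12)
    mx, = struct.unpack_from("<i", raw, 28)
    xlen, = struct.unpack_from("<f", raw, 40)
    if mode != _MRC_MODE_FLOAT32:
        raise FormatError(f"{path}: mode={mode} unsupported; only mode 2 (float32) is accepted")
    if min(nx, ny, nz) < 0:
        raise FormatError(f"{path}: negative dimension in header (nx={nx}, ny={ny}, nz={nz})")
    pixel_size = xlen / mx if mx > 0 and xlen > 0 else 0.0
    if pixel_size <= 0:
        raise FormatError(f"{path}: header cell/mx does not define a positive pixel size "
                          f"(xlen={xlen}, mx={mx})")
    return nx, ny, nz, pixel_size


def _read_mrc(path) -> tuple[np.ndarray, float]:
    raw = Path(path).read_bytes()
    nx, ny, nz, pixel_size = _read_header(raw, path)
    n_expected = nx * ny * nz
    data = np.frombuffer(raw, dtype="<f4", count=-1, offset=_HEADER_SIZE)
    if data.size != n_expected:
        raise FormatError(f"{path}: data size {data.size} does not match header "
                          f"nx*ny*nz={n_expected}")
    return data.reshape(nz, ny, nx).copy(), pixel_size


def _write_mrc(array: np.ndarray, pixel_size: float, path) -> Path:
    path = Path(path)
    nz, ny, nx = array.shape
    with open(path, "wb") as fh:
        fh.write(_pack_header(nx, ny, nz, pixel_size))
        fh.write(np.ascontiguousarray(array, dtype="<f4").tobytes())
    return path


def read_stack(path, metadata_path=None) -> ImageStack:
    """Read an MRC mode-2 image stack (and optional sidecar TSV metadata)."""
    data, pixel_size = _read_mrc(path)
    if data.shape[0] == 0:
        raise FormatError(f"{path}: header declares 0 images (nz=0)")
    if data.shape[1] != data.shape[2]:
        raise FormatError(f"{path}: images are {data.shape[1]}x{data.shape[2]}, not square")
    meta = read_metadata(metadata_path) if metadata_path is not None else None
    if meta is not None and len(meta) != data.shape[0]:
        raise FormatError(f"{metadata_path}: {len(meta)} metadata rows for "
                          f"{data.shape[0]} images")
    return ImageStack(images=data, pixel_size=pixel_size, metadata=meta)


def write_stack(stack: ImageStack, path, metadata_path=None) -> Path:
    """Write an image stack as MRC mode 2; metadata, if present, as TSV."""
    out = _write_mrc(stack.images, stack.pixel_size, path)
    if metadata_path is not None and stack.metadata is not None:
        write_metadata(stack.metadata, metadata_path)
    return out


def read_volume(path) -> VolumeGrid:
    """Read a cubic MRC mode-2 volume."""
    data, voxel_size = _read_mrc(path)
    nz, ny, nx = data.shape
    if not (nz == ny == nx):
        raise FormatError(f"{path}: volume is {data.shape}, not cubic")
    return VolumeGrid(voxels=data, voxel_size=voxel_size)


def write_volume(vol: VolumeGrid, path) -> Path:
    """Write a cubic volume as MRC mode 2."""
    return _write_mrc(vol.voxels, vol.voxel_size, path)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_DEFAULTS: dict = {
    "seed": None,                    # required
    "out_dir": ".",
    "n_segments": 12000,             # study-scale default
    "box_size": 160,
    "pixel_size": 1.59,
    "snr": 0.1,
    "states": None,                  # list of {name, pitch, twist, fraction}
    "tilt_sd": 5.0,
    "inplane_jitter": 5.0,
    "defocus": 12000.0,              # Angstrom underfocus; null disables CTF
    "filter": {"low_cutoff": 100.0, "low_transmission": 0.10,
               "high_cutoff": 7.0, "edge_width": 5},
    "grid": {"twist_min": 35.0, "twist_max": 48.0, "twist_step": 2.0,
             "pitch_min": 80.0, "pitch_max": 130.0, "pitch_step": 3.2,
             "fine_step_pitch": 0.5, "fine_step_twist": 0.5},
    "reconstruction": {"angular_step": 4.0, "z_fraction": 0.6},
}


@dataclass
class RunConfig:
    """Validated run configuration; ``seed`` feeds every stochastic stage."""

    seed: int
    options: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.options[key]

    def get(self, key, default=None):
        return self.options.get(key, default)


def _merge_defaults(user: dict, defaults: dict, prefix: str = "") -> tuple[dict, list[str]]:
    merged, unknown = {}, []
    for key, default in defaults.items():
        if key in user and isinstance(default, dict) and isinstance(user[key], dict):
            sub, sub_unknown = _merge_defaults(user[key], default, f"{prefix}{key}.")
            merged[key] = sub
            unknown += sub_unknown
        elif key in user:
            merged[key] = user[key]
        else:
            merged[key] = default
    unknown += [f"{prefix}{k}" for k in user if k not in defaults]
    return merged, unknown


def load_config(path, log=None) -> RunConfig:
    """Load a YAML run configuration, applying and logging defaults.

    Unknown keys and a missing ``seed`` raise :class:`ConfigError` naming
    them — silent typos in a reconstruction run are costly.
    """
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    merged, unknown = _merge_defaults(user, _CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(f"{path}: unknown keys: {', '.join(sorted(unknown))}")
    if merged.get("seed") is None:
        raise ConfigError(f"{path}: missing required key: seed")
    if log is not None:
        for key, value in merged.items():
            source = "user" if key in user else "default"
            log(f"config {key} = {value!r} ({source})")
    seed = int(merged.pop("seed"))
    return RunConfig(seed=seed, options=merged)
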