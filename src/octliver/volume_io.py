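"""C-scan container I/O and 8-bit B-scan conversion.

A C-scan is stored on disk as a directory holding one 16-bit grayscale PNG
per B-scan plus a ``meta.json`` file.  Raw intensities are in decibel (dB);
the PNG encoding is affine (``db = offset + scale * code``) with the slope
and offset recorded in the metadata, so a round trip is lossless up to the
16-bit quantization step (well below 0.01 dB for any realistic dynamic
range).

The 8-bit conversion follows the acquisition convention of scaling a whole
C-scan by the minimum and maximum intensity found in its first, middle and
last B-scans, which anchors the contrast to the surface peak and the deep
noise floor rather than to per-image histograms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import FormatError, IntegrityError, ParameterError

LABELS = ("healthy", "tumor")

_META_NAME = "meta.json"
_BSCAN_FMT = "bscan_{:04d}.png"


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (symmetric rounding)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    scaled = x * factor
    out = np.copysign(np.floor(np.abs(scaled) + 0.5), scaled) / factor
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata for one C-scan.

    Lateral pixel sizes are derived from the physical field of view and the
    pixel counts.  The axial (z) pixel size is stored independently because
    the optical path through tissue makes it differ from the naive
    ``depth_mm / height_px`` ratio; when not supplied it falls back to that
    ratio.
    """

    scan_id: str
    patient_id: str
    label: str
    n_bscans: int
    height_px: int
    width_px: int
    fov_x_mm: float = 3.0
    fov_y_mm: float = 3.0
    depth_mm: float = 2.5
    pixel_z_um: float | None = None
    generator_seed: int | None = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")
        for name in ("n_bscans", "height_px", "width_px"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.pixel_z_um is None:
            object.__setattr__(self, "pixel_z_um", 1000.0 * self.depth_mm / self.height_px)

    @property
    def pixel_x_um(self) -> float:
        return 1000.0 * self.fov_x_mm / self.width_px

    @property
    def pixel_y_um(self) -> float:
        return 1000.0 * self.fov_y_mm / self.n_bscans

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "patient_id": self.patient_id,
            "label": self.label,
            "n_bscans": self.n_bscans,
            "height_px": self.height_px,
            "width_px": self.width_px,
            "fov_x_mm": self.fov_x_mm,
            "fov_y_mm": self.fov_y_mm,
            "depth_mm": self.depth_mm,
            "pixel_z_um": self.pixel_z_um,
            "generator_seed": self.generator_seed,
        }


@dataclass
class RawCScan:
    """A raw 3-D volume of dB intensities, indexed (bscan, depth row, column)."""

    values: np.ndarray
    meta: ScanMeta

    def __post_init__(self):
        self.values = np.asarray(self.values)
        expected = (self.meta.n_bscans, self.meta.height_px, self.meta.width_px)
        if self.values.shape != expected:
            raise IntegrityError(
                f"volume shape {self.values.shape} does not match metadata {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("volume contains non-finite values")


@dataclass
class BScanImage:
    """One 8-bit B-scan cross-section (possibly narrowed by column removal)."""

    pixels: np.ndarray
    scan_id: str
    bscan_index: int
    removed_columns: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError("B-scan pixels must be a 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ParameterError("B-scan pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)


def write_cscan(raw: RawCScan, path) -> Path:
    """Write a C-scan container (16-bit PNGs + meta.json) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    values = np.asarray(raw.values, dtype=np.float64)
    lo = float(values.min())
    hi = float(values.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    meta = raw.meta.to_dict()
    meta["db_offset"] = lo
    meta["db_scale"] = scale
    with open(path / _META_NAME, "w") as fh:
        json.dump(meta, fh, indent=1)
    codes = np.clip(np.rint((values - lo) / scale), 0, 65535).astype(np.uint16)
    for b in range(raw.meta.n_bscans):
        iio.imwrite(path / _BSCAN_FMT.format(b), codes[b])
    return path


def read_cscan(path) -> RawCScan:
    """Read a C-scan container written by :func:`write_cscan`."""
    path = Path(path)
    meta_path = path / _META_NAME
    if not meta_path.is_file():
        raise FormatError(f"missing {_META_NAME} in {path}")
    try:
        with open(meta_path) as fh:
            raw_meta = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise FormatError(f"malformed {_META_NAME} in {path}: {exc}") from exc
    required = {
        "scan_id", "patient_id", "label", "n_bscans", "height_px",
        "width_px", "db_offset", "db_scale",
    }
    missing = required - raw_meta.keys()
    if missing:
        raise FormatError(f"{_META_NAME} missing keys: {sorted(missing)}")
    meta = ScanMeta(
        scan_id=raw_meta["scan_id"],
        patient_id=raw_meta["patient_id"],
        label=raw_meta["label"],
        n_bscans=int(raw_meta["n_bscans"]),
        height_px=int(raw_meta["height_px"]),
        width_px=int(raw_meta["width_px"]),
        fov_x_mm=float(raw_meta.get("fov_x_mm", 3.0)),
        fov_y_mm=float(raw_meta.get("fov_y_mm", 3.0)),
        depth_mm=float(raw_meta.get("depth_mm", 2.5)),
        pixel_z_um=raw_meta.get("pixel_z_um"),
        generator_seed=raw_meta.get("generator_seed"),
    )
    offset = float(raw_meta["db_offset"])
    scale = float(raw_meta["db_scale"])
    images = sorted(path.glob("bscan_*.png"))
    if len(images) != meta.n_bscans:
        raise IntegrityError(
            f"metadata declares {meta.n_bscans} B-scans but {len(images)} images found"
        )
    volume = np.empty((meta.n_bscans, meta.height_px, meta.width_px), dtype=np.float32)
    for b, img_path in enumerate(images):
        img = iio.imread(img_path)
        if img.shape != (meta.height_px, meta.width_px):
            raise IntegrityError(
                f"{img_path.name} has shape {img.shape}, metadata says "
                f"({meta.height_px}, {meta.width_px})"
            )
        volume[b] = img.astype(np.float64) * scale + offset
    return RawCScan(values=volume, meta=meta)


def anchor_bscan_indices(n_bscans: int) -> tuple[int, int, int]:
    """Indices of the first, middle and last B-scan used for contrast anchoring."""
    return 0, (n_bscans - 1) // 2, n_bscans - 1


def scale_to_8bit(raw: RawCScan) -> list[BScanImage]:
    """Convert a dB volume to 8-bit B-scans with whole-C-scan contrast.

    The global minimum / maximum are taken over the first, middle and last
    B-scans only; every voxel is then mapped linearly onto [0, 255] (half
    away from zero rounding) and clamped, so voxels of other B-scans falling
    outside the anchor range saturate at 0 or 255.
    """
    values = np.asarray(raw.values, dtype=np.float64)
    idx = sorted(set(anchor_bscan_indices(raw.meta.n_bscans)))
    lo = float(values[idx].min())
    hi = float(values[idx].max())
    if hi == lo:
        warnings.warn(
            f"C-scan {raw.meta.scan_id!r} has degenerate contrast (constant "
            f"anchor B-scans); producing all-zero images",
            stacklevel=2,
        )
        scaled = np.zeros_like(values)
    else:
        scaled = 255.0 * (values - lo) / (hi - lo)
        scaled = np.copysign(np.floor(np.abs(scaled) + 0.5), scaled)
        scaled = np.clip(scaled, 0, 255)
    return [
        BScanImage(pixels=scaled[b].astype(np.uint8), scan_id=raw.meta.scan_id, bscan_index=b)
        for b in range(raw.meta.n_bscans)
    ]


def export_8bit_pngs(images: list[BScanImage], out_dir) -> list[Path]:
    """Write 8-bit B-scans as grayscale PNGs, one file per B-scan."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in images:
        p = out_dir / f"{img.scan_id}_b{img.bscan_index:04d}.png"
        iio.imwrite(p, img.pixels)
        paths.append(p)
    return paths


__all__ = [
    "LABELS",
    "ScanMeta",
    "RawCScan",
    "BScanImage",
    "write_cscan",
    "read_cscan",
    "scale_to_8bit",
    "anchor_bscan_indices",
    "export_8bit_pngs",
    "round_half_away",
]
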