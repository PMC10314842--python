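"""Synthetic SD-OCT C-scan generator with ground truth.

The phantom reproduces the statistical structure the downstream analysis
relies on, for two tissue classes:

* a dark air region above a tilted, gently rough tissue surface;
* a bright surface peak followed by exponential depth attenuation of the
  log-intensity along each A-scan, with per-A-scan rate jitter;
* a smooth zero-mean heterogeneity field modulating the local attenuation
  (tumor tissue gets a larger amplitude, i.e. coarser texture);
* multiplicative gamma-distributed speckle on the linear intensity
  (applied in dB as an additive ``10/ln10 * ln(s)`` term);
* full-height, near-saturation column artifacts emulating detector
  saturation from specular surface reflections.

Tumor tissue attenuates faster and is texturally more heterogeneous than
healthy parenchyma; both knobs are controlled by :class:`PhantomParams`.
Everything is driven by a single integer seed, so identical parameters
reproduce a volume bit for bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ParameterError
from .volume_io import LABELS, RawCScan, ScanMeta

# dB per neper of linear-intensity decay
_DB_PER_NEPER = 10.0 / math.log(10.0)

# geometry of the acquisition the phantom is scaled from (3 mm lateral FOV
# over 1024 columns, 2.5 mm depth over 512 rows)
_LATERAL_UM_PER_PX = 3000.0 / 1024.0
_AXIAL_UM_PER_PX = 4.97


@dataclass(frozen=True)
class PhantomParams:
    """Generator knobs for one C-scan.

    ``attenuation_per_px`` is the mean decay rate of the natural
    log-intensity per depth pixel (nepers/px).  ``speckle_shape`` is the
    gamma shape parameter of the multiplicative speckle (mean one, variance
    ``1/shape``); ``None`` disables speckle.  ``snr_floor_db`` is the margin
    above the noise floor below which tissue no longer counts as useful
    signal in the ground-truth mask.
    """

    n_bscans: int = 32
    height_px: int = 400
    width_px: int = 340
    surface_level_px: float = 60.0
    surface_tilt: float = 0.03
    surface_roughness_px: float = 3.0
    attenuation_per_px: float = 0.030
    attenuation_jitter: float = 0.05
    speckle_shape: float | None = 4.0
    heterogeneity_amp: float = 0.10
    heterogeneity_scale_px: float = 12.0
    artifact_col_rate: float = 1.0
    noise_floor_db: float = 0.0
    surface_peak_db: float = 60.0
    snr_floor_db: float = 5.0
    air_noise_db: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_bscans", "height_px", "width_px"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.artifact_col_rate < 0:
            raise ParameterError("artifact_col_rate must be >= 0")
        if self.surface_peak_db <= self.noise_floor_db:
            raise ParameterError("surface_peak_db must exceed noise_floor_db")
        if self.attenuation_per_px <= 0:
            raise ParameterError("attenuation_per_px must be positive")
        if self.speckle_shape is not None and not (
            math.isfinite(self.speckle_shape) and self.speckle_shape > 0
        ):
            raise ParameterError("speckle_shape must be positive and finite, or None")


def healthy_params(**overrides) -> PhantomParams:
    """Default parameters for homogeneous healthy liver parenchyma."""
    return PhantomParams(**overrides)


def tumor_params(**overrides) -> PhantomParams:
    """Default parameters for heterogeneous metastatic tissue.

    Attenuation is 1.6x and heterogeneity amplitude 2.5x the healthy
    defaults, which keeps the two classes separable by a simple depth-decay
    statistic while remaining visually plausible.
    """
    defaults = dict(attenuation_per_px=0.048, heterogeneity_amp=0.25)
    defaults.update(overrides)
    return PhantomParams(**defaults)


@dataclass
class GroundTruth:
    """Per-voxel truth accompanying a phantom C-scan."""

    surface_height: np.ndarray        # (n_bscans, width) int row indices
    tissue_mask: np.ndarray           # (n_bscans, height, width) uint8
    artifact_columns: set             # {(bscan_index, column), ...}
    label: str


def _unit_std(field: np.ndarray) -> np.ndarray:
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_cscan(
    params: PhantomParams,
    label: str,
    scan_id: str | None = None,
    patient_id: str | None = None,
) -> tuple[RawCScan, GroundTruth]:
    """Generate one phantom C-scan plus its ground truth.

    The random stream is consumed in a fixed order (surface roughness,
    heterogeneity, attenuation jitter, detector noise, speckle, artifact
    columns), so outputs are reproducible bit for bit from ``params``.
    """
    if label not in LABELS:
        raise ParameterError(f"label must be one of {LABELS}, got {label!r}")
    nb, h, w = params.n_bscans, params.height_px, params.width_px
    rng = np.random.default_rng(params.seed)

    # tilted surface with smoothed roughness, slowly varying across B-scans
    rough = _unit_std(
        gaussian_filter(rng.standard_normal((nb, w)), sigma=(2.0, max(w / 16.0, 1.0)))
    )
    cols = np.arange(w, dtype=np.float64)
    surface = (
        params.surface_level_px
        + params.surface_tilt * (cols - (w - 1) / 2.0)
        + params.surface_roughness_px * rough
    )
    surface = np.clip(np.rint(surface).astype(np.int64), 1, h - 2)

    # smooth unit-variance heterogeneity field modulating the local decay rate
    s = params.heterogeneity_scale_px
    hetero = _unit_std(
        gaussian_filter(rng.standard_normal((nb, h, w)), sigma=(2.0, s, s))
    )

    jitter = rng.standard_normal((nb, w))
    rate = params.attenuation_per_px * (1.0 + params.attenuation_jitter * jitter)
    rate = np.maximum(rate, 0.2 * params.attenuation_per_px)

    detector_noise = params.air_noise_db * rng.standard_normal((nb, h, w))

    rows = np.arange(h)[:, None]                     # (h, 1)
    volume = np.empty((nb, h, w), dtype=np.float32)
    tissue_mask = np.zeros((nb, h, w), dtype=np.uint8)
    expected_db = np.empty((h, w), dtype=np.float64)
    for b in range(nb):
        below = rows >= surface[b][None, :]          # (h, w)
        # decay increments accumulate only below the surface
        increments = rate[b][None, :] * (1.0 + params.heterogeneity_amp * hetero[b])
        increments = np.where(below, increments, 0.0)
        depth_integral = np.cumsum(increments, axis=0) - increments  # zero at surface row
        expected_db[:] = params.surface_peak_db - _DB_PER_NEPER * depth_integral
        signal_db = expected_db.copy()
        if params.speckle_shape is not None:
            speckle = rng.gamma(params.speckle_shape, 1.0 / params.speckle_shape, (h, w))
            signal_db += _DB_PER_NEPER * np.log(speckle)
        floor = params.noise_floor_db + detector_noise[b]
        bscan = np.where(below, np.maximum(signal_db, floor), floor)
        volume[b] = bscan.astype(np.float32)
        tissue_mask[b] = (
            below & (expected_db >= params.noise_floor_db + params.snr_floor_db)
        ).astype(np.uint8)

    artifact_columns: set = set()
    if params.artifact_col_rate > 0:
        saturation_db = params.surface_peak_db + 1.0
        for b in range(nb):
            n_art = min(int(rng.poisson(params.artifact_col_rate)), w)
            if n_art == 0:
                continue
            art_cols = rng.choice(w, size=n_art, replace=False)
            volume[b][:, art_cols] = saturation_db
            artifact_columns.update((b, int(c)) for c in art_cols)

    if scan_id is None:
        scan_id = f"{label}-s{params.seed}"
    if patient_id is None:
        patient_id = scan_id
    meta = ScanMeta(
        scan_id=scan_id,
        patient_id=patient_id,
        label=label,
        n_bscans=nb,
        height_px=h,
        width_px=w,
        fov_x_mm=w * _LATERAL_UM_PER_PX / 1000.0,
        fov_y_mm=nb * _LATERAL_UM_PER_PX / 1000.0,
        depth_mm=h * _AXIAL_UM_PER_PX / 1000.0,
        pixel_z_um=_AXIAL_UM_PER_PX,
        generator_seed=params.seed,
    )
    truth = GroundTruth(
        surface_height=surface,
        tissue_mask=tissue_mask,
        artifact_columns=artifact_columns,
        label=label,
    )
    return RawCScan(values=volume, meta=meta), truth


def derive_scan_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-scan seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_cohort(
    n_per_class: int,
    healthy: PhantomParams | None = None,
    tumor: PhantomParams | None = None,
    seed: int = 0,
) -> list[tuple[RawCScan, GroundTruth, ScanMeta]]:
    """Generate a balanced cohort of 2 * n_per_class phantom C-scans.

    Scans are paired per pseudo-patient (one healthy and one tumor scan per
    patient, as when both tissue types are imaged on the same resection
    specimen).  Per-scan seeds are derived deterministically from the master
    seed.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    healthy = healthy if healthy is not None else healthy_params()
    tumor = tumor if tumor is not None else tumor_params()
    seeds = derive_scan_seeds(seed, 2 * n_per_class)
    out = []
    for i in range(n_per_class):
        for label, params, s in (
            ("healthy", healthy, seeds[2 * i]),
            ("tumor", tumor, seeds[2 * i + 1]),
        ):
            p = dataclasses.replace(params, seed=s)
            raw, truth = generate_cscan(
                p,
                label,
                scan_id=f"{label}_{i:03d}",
                patient_id=f"patient_{i:03d}",
            )
            out.append((raw, truth, raw.meta))
    return out


__all__ = [
    "PhantomParams",
    "GroundTruth",
    "healthy_params",
    "tumor_params",
    "generate_cscan",
    "generate_cohort",
    "derive_scan_seeds",
]
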