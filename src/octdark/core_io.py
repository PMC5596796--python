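"""Domain types, coordinate conventions, and volume/map/config I/O.

Conventions used throughout the package:

* Volumes are indexed ``[b, a, z]`` — ``b`` the slow (B-scan) axis, ``a`` the
  fast (A-scan) axis, ``z`` depth, increasing posteriorly toward Bruch's
  membrane.  Array indices are 0-based.
* Physical units at every public interface: transverse positions in mm with
  origin at the volume centre (or the fovea, where stated), depth in μm below
  the ellipsoid zone, positive posteriorly.
* The inferior retina is the +y (increasing ``b``) half of the map.

Volumes are stored as multi-page TIFF (one page per B-scan, shape ``(z, a)``)
plus a JSON sidecar carrying the sampling metadata; thickness/difference maps
as CSV with NaN for invalid pixels plus a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml

__all__ = [
    "OCTVolume",
    "AcquisitionSchedule",
    "ThicknessMap",
    "DifferenceMap",
    "PipelineConfig",
    "ConfigError",
    "write_volume",
    "read_volume",
    "write_map",
    "read_map",
    "load_config",
]

BANDS = ("CIZ", "RIZ", "RPE", "BM")

# Defaults of the imaging protocol: 6 × 6 mm, 400 × 400 A-scan volumes,
# 0.52 μm axial sampling in tissue after zero-padding to 4096 pixels.
DEFAULT_GRID = (400, 400)
DEFAULT_EXTENT_MM = (6.0, 6.0)
DEFAULT_AXIAL_SAMPLING_UM = 0.52


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration values."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with sampling metadata.

    Parameters
    ----------
    intensity
        Nonnegative array ``[b, a, z]``.
    axial_sampling_um
        μm per depth pixel in tissue.
    transverse_extent_mm
        ``(fast, slow)`` scan extent in mm.
    timestamp_s
        Seconds relative to flash offset; negative for baseline volumes.
    meta
        Free-form provenance.
    """

    intensity: np.ndarray
    axial_sampling_um: float = DEFAULT_AXIAL_SAMPLING_UM
    transverse_extent_mm: tuple[float, float] = DEFAULT_EXTENT_MM
    timestamp_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        _require(self.intensity.ndim == 3, "intensity must be a 3-D [b, a, z] array")
        _require(np.isfinite(self.intensity).all(), "intensity must be finite")
        _require(float(self.intensity.min(initial=0.0)) >= 0.0, "intensity must be >= 0")
        _require(self.axial_sampling_um > 0, "axial_sampling_um must be > 0")
        _require(
            len(self.transverse_extent_mm) == 2
            and all(e > 0 for e in self.transverse_extent_mm),
            "transverse_extent_mm must be two positive lengths",
        )

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[2]

    @property
    def transverse_spacing_mm(self) -> tuple[float, float]:
        """(fast, slow) pixel pitch in mm (pixel-centre grid)."""
        return (
            self.transverse_extent_mm[0] / self.n_ascans,
            self.transverse_extent_mm[1] / self.n_bscans,
        )


@dataclass
class AcquisitionSchedule:
    """Imaging schedule: baselines in darkness, rapid volumes for the first
    minutes after the flash, then one volume per minute to the end."""

    baseline_count: int = 3
    fast_interval_s: float = 20.0
    fast_window_s: float = 300.0
    slow_interval_s: float = 60.0
    total_s: float = 1800.0

    def __post_init__(self) -> None:
        _require(self.baseline_count >= 1, "baseline_count must be >= 1")
        _require(
            self.fast_interval_s > 0 and self.slow_interval_s > 0,
            "intervals must be > 0",
        )
        _require(self.fast_window_s <= self.total_s, "fast_window_s must be <= total_s")

    def baseline_times_s(self) -> np.ndarray:
        k = np.arange(self.baseline_count, 0, -1)
        return -k * self.fast_interval_s

    def postflash_times_s(self) -> np.ndarray:
        fast = np.arange(self.fast_interval_s, self.fast_window_s + 1e-9, self.fast_interval_s)
        slow = np.arange(
            self.fast_window_s + self.slow_interval_s,
            self.total_s + 1e-9,
            self.slow_interval_s,
        )
        return np.concatenate([fast, slow])

    def times_s(self) -> np.ndarray:
        return np.concatenate([self.baseline_times_s(), self.postflash_times_s()])


@dataclass
class _MapBase:
    values_um: np.ndarray
    band: str
    valid: np.ndarray
    transverse_extent_mm: tuple[float, float] = DEFAULT_EXTENT_MM
    fovea_mm: tuple[float, float] | None = None
    timestamp_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_um = np.asarray(self.values_um, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        _require(self.values_um.ndim == 2, "map values must be 2-D [b, a]")
        _require(self.valid.shape == self.values_um.shape, "valid mask shape mismatch")
        _require(self.band in BANDS, f"band must be one of {BANDS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values_um.shape

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates ``(x_mm[a], y_mm[b])`` about the map centre."""
        n_b, n_a = self.values_um.shape
        ex, ey = self.transverse_extent_mm
        x = (np.arange(n_a) + 0.5) * ex / n_a - ex / 2.0
        y = (np.arange(n_b) + 0.5) * ey / n_b - ey / 2.0
        return x, y

    def radius_mm(self) -> np.ndarray:
        """Per-pixel distance (mm) from the fovea (map centre if unset)."""
        x, y = self.pixel_coords_mm()
        fx, fy = self.fovea_mm if self.fovea_mm is not None else (0.0, 0.0)
        return np.hypot(x[None, :] - fx, y[:, None] - fy)


@dataclass
class ThicknessMap(_MapBase):
    """Depth of a named outer-retinal band below the EZ, per A-scan, in μm."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.valid.any():
            _require(
                float(self.values_um[self.valid].min()) > 0,
                "thickness values must be > 0 wherever valid",
            )


@dataclass
class DifferenceMap(_MapBase):
    """Thickness change from the dark-adapted baseline, in μm (signed)."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the processing pipeline.

    ``cscan_filter_sigma`` is the transverse Gaussian filter applied at every
    depth of the flattened volume (A-scan units); ``diff_filter_sigma`` the
    display smoothing of difference maps.  ``band_windows_um`` are the depth
    search intervals below the EZ for the four bands.  ``roi_diameters_mm``
    hold the averaging regions: a 3-mm circle for the cone band, a 1.5–5.5-mm
    annulus for the rod band, a 5.5-mm circle for the RPE and BM bands.
    """

    cscan_filter_sigma: float = 2.0
    diff_filter_sigma: float = 9.0
    band_windows_um: dict = field(
        default_factory=lambda: {
            "CIZ": (15.0, 40.0),
            "RIZ": (30.0, 55.0),
            "RPE": (40.0, 65.0),
            "BM": (55.0, 85.0),
        }
    )
    roi_diameters_mm: dict = field(
        default_factory=lambda: {
            "CIZ": (0.0, 3.0),
            "RIZ": (1.5, 5.5),
            "RPE": (0.0, 5.5),
            "BM": (0.0, 5.5),
        }
    )
    ring_base_radius_mm: float = 0.75
    knot_mm: float = 2.0
    rng_seed: int = 0
    ez_max_step_px: int = 2
    ez_target_index: int = 48
    prominence_frac: float = 0.10
    band_min_separation_um: float = 6.0
    fovea_smooth_mm: float = 0.25
    spline_df: int = 8
    motion_qc_rms_px: float = 5.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cscan_filter_sigma <= 0:
            raise ConfigError("cscan_filter_sigma must be > 0")
        if self.diff_filter_sigma <= 0:
            raise ConfigError("diff_filter_sigma must be > 0")
        if self.ring_base_radius_mm <= 0:
            raise ConfigError("ring_base_radius_mm must be > 0")
        if self.knot_mm <= 0:
            raise ConfigError("knot_mm must be > 0")
        if self.ez_max_step_px < 1:
            raise ConfigError("ez_max_step_px must be >= 1")
        if not 0 < self.prominence_frac < 1:
            raise ConfigError("prominence_frac must be in (0, 1)")
        if self.band_min_separation_um <= 0:
            raise ConfigError("band_min_separation_um must be > 0")
        for band in BANDS:
            if band not in self.band_windows_um:
                raise ConfigError(f"band_windows_um missing band {band}")
            lo, hi = self.band_windows_um[band]
            if not 0 < lo < hi:
                raise ConfigError(f"band_windows_um[{band}] must satisfy 0 < lo < hi")
        for band, (d_in, d_out) in self.roi_diameters_mm.items():
            if d_in < 0 or d_out <= d_in:
                raise ConfigError(f"roi_diameters_mm[{band}] must satisfy 0 <= inner < outer")


# ---------------------------------------------------------------------------
# Volume I/O: multi-page TIFF + JSON sidecar.

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: OCTVolume, path: str | Path, dtype: str = "float32") -> None:
    """Write a volume as multi-page TIFF (page per B-scan, shape ``(z, a)``).

    ``dtype='float32'`` (default) is a lossless round trip for float32 data;
    ``dtype='uint16'`` writes linearly rescaled 16-bit pages for inspection
    in image viewers, with the scale factor recorded in the sidecar.
    """
    path = Path(path)
    data = np.ascontiguousarray(np.transpose(vol.intensity, (0, 2, 1)))
    scale = 1.0
    if dtype == "uint16":
        vmax = float(data.max()) if data.size else 0.0
        scale = (65535.0 / vmax) if vmax > 0 else 1.0
        data = np.round(data * scale).astype(np.uint16)
    elif dtype == "float32":
        data = data.astype(np.float32, copy=False)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "axial_sampling_um": vol.axial_sampling_um,
        "transverse_extent_mm": list(vol.transverse_extent_mm),
        "timestamp_s": vol.timestamp_s,
        "intensity_scale": scale,
        "dtype": dtype,
        "meta": vol.meta,
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path) -> OCTVolume:
    path = Path(path)
    side_path = _sidecar(path)
    if not side_path.exists():
        raise FileNotFoundError(f"missing volume sidecar {side_path}")
    side = json.loads(side_path.read_text())
    for key in ("axial_sampling_um", "transverse_extent_mm", "timestamp_s"):
        if key not in side:
            raise KeyError(f"volume sidecar missing field {key!r}")
    data = tifffile.imread(path)
    if data.ndim == 2:  # single B-scan
        data = data[None]
    intensity = np.transpose(data, (0, 2, 1))
    scale = side.get("intensity_scale", 1.0)
    if side.get("dtype") == "uint16" and scale != 1.0:
        intensity = intensity.astype(np.float32) / scale
    return OCTVolume(
        intensity=intensity,
        axial_sampling_um=float(side["axial_sampling_um"]),
        transverse_extent_mm=tuple(side["transverse_extent_mm"]),
        timestamp_s=float(side["timestamp_s"]),
        meta=side.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Map I/O: CSV (NaN for invalid) + JSON sidecar.

def write_map(m: _MapBase, path: str | Path) -> None:
    path = Path(path)
    out = np.where(m.valid, m.values_um, np.nan)
    np.savetxt(path, out.astype(np.float32), delimiter=",", fmt="%.9g")
    side = {
        "band": m.band,
        "kind": "difference" if isinstance(m, DifferenceMap) else "thickness",
        "transverse_extent_mm": list(m.transverse_extent_mm),
        "fovea_mm": list(m.fovea_mm) if m.fovea_mm is not None else None,
        "timestamp_s": m.timestamp_s,
        "meta": m.meta,
    }
    _sidecar(path).write_text(json.dumps(side, indent=1))


def read_map(path: str | Path) -> _MapBase:
    path = Path(path)
    side_path = _sidecar(path)
    if not side_path.exists():
        raise FileNotFoundError(f"missing map sidecar {side_path}")
    side = json.loads(side_path.read_text())
    for key in ("band", "transverse_extent_mm"):
        if key not in side:
            raise KeyError(f"map sidecar missing field {key!r}")
    raw = np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2)
    valid = np.isfinite(raw)
    values = np.where(valid, raw, 0.0)
    cls = DifferenceMap if side.get("kind") == "difference" else ThicknessMap
    return cls(
        values_um=values,
        band=side["band"],
        valid=valid,
        transverse_extent_mm=tuple(side["transverse_extent_mm"]),
        fovea_mm=tuple(side["fovea_mm"]) if side.get("fovea_mm") else None,
        timestamp_s=float(side.get("timestamp_s", 0.0)),
        meta=side.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Configuration

def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> PipelineConfig:
    """Load a YAML pipeline configuration, applying defaults for omitted keys.

    An empty (or absent) file yields the all-defaults configuration.  Unknown
    keys and out-of-range values raise :class:`ConfigError` naming the key.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a YAML mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
    if "band_windows_um" in raw:
        raw["band_windows_um"] = {k: tuple(v) for k, v in raw["band_windows_um"].items()}
    if "roi_diameters_mm" in raw:
        raw["roi_diameters_mm"] = {k: tuple(v) for k, v in raw["roi_diameters_mm"].items()}
    try:
        return PipelineConfig(**raw)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
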