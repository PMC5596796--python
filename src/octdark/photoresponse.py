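"""Photoresponse extraction: baselines, difference maps, ROI time series.

The photoresponse of a band is the time course of its ROI-averaged
thickness change from the dark-adapted baseline.  The baseline is the
pixelwise mean of the (three) pre-flash thickness maps, valid where a
majority of them are valid.  Each post-flash map is translated so its fovea
coincides with the baseline fovea (translation only — same-session volumes),
subtracted, and averaged over the band's region of interest:

* CIZ (cone band): 3-mm-diameter circle centred on the fovea;
* RIZ (rod band): 1.5–5.5-mm-diameter annulus;
* RPE and BM: 5.5-mm-diameter circle;

plus inferior/superior hemifield splits of each region for the patterned
(half-field) exposures.  ROI means are computed on the unsmoothed difference
maps; the heavier Gaussian smoothing (sigma = 9 A-scans) is for display
maps only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy import ndimage

from .core_io import (
    BANDS,
    DifferenceMap,
    OCTVolume,
    PipelineConfig,
    ThicknessMap,
)
from .bands import build_thickness_maps, cscan_filter
from .segmentation import EZSurface, flatten_volume, segment_volume

__all__ = [
    "ROISpec",
    "PhotoresponseSeries",
    "SessionResult",
    "average_baseline",
    "find_fovea",
    "difference_map",
    "smooth_masked",
    "roi_mean",
    "process_volume",
    "process_session",
    "ez_jitter_px",
]


@dataclass
class ROISpec:
    """Circle or annulus about the fovea, optionally split to a hemifield.

    ``diameters_mm = (inner, outer)``; inner 0 makes it a circle.  Pixel
    centres are included when ``inner/2 <= r <= outer/2`` (boundary ties
    inside).  Hemifields split at the fovea row: inferior is +y.
    """

    diameters_mm: tuple[float, float]
    hemifield: str | None = None

    def __post_init__(self) -> None:
        d_in, d_out = self.diameters_mm
        if d_in < 0 or d_out <= d_in:
            raise ValueError("diameters must satisfy 0 <= inner < outer")
        if self.hemifield not in (None, "inferior", "superior"):
            raise ValueError("hemifield must be None, 'inferior', or 'superior'")

    @property
    def label(self) -> str:
        return self.hemifield or "full"

    def select(self, m: DifferenceMap | ThicknessMap) -> np.ndarray:
        """Boolean pixel-selection mask (ignores validity)."""
        r = m.radius_mm()
        d_in, d_out = self.diameters_mm
        sel = (r >= d_in / 2.0) & (r <= d_out / 2.0)
        if self.hemifield is not None:
            _, y = m.pixel_coords_mm()
            fy = m.fovea_mm[1] if m.fovea_mm is not None else 0.0
            rel = y[:, None] - fy
            sel &= (rel > 0) if self.hemifield == "inferior" else (rel < 0)
        return np.broadcast_to(sel, m.shape) if sel.ndim == 2 else sel


@dataclass
class PhotoresponseSeries:
    """Time-ordered ROI-averaged thickness differences for one band/ROI."""

    band: str
    roi: str
    times_s: np.ndarray
    mean_diff_um: np.ndarray
    n_pixels: np.ndarray
    condition: dict = field(default_factory=dict)
    session_id: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.mean_diff_um = np.asarray(self.mean_diff_um, dtype=np.float64)
        self.n_pixels = np.asarray(self.n_pixels, dtype=np.int64)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.n_pixels <= 0):
            raise ValueError("n_pixels must be > 0 at every time point")

    def times_min(self) -> np.ndarray:
        return self.times_s / 60.0


def average_baseline(maps: list[ThicknessMap]) -> ThicknessMap:
    """Pixelwise mean of co-registered baseline maps of one band.

    A pixel is valid (and averaged over the valid maps only) where it is
    valid in a strict majority of the inputs.
    """
    if not maps:
        raise ValueError("need at least one baseline map")
    band = maps[0].band
    if any(m.band != band or m.shape != maps[0].shape for m in maps):
        raise ValueError("baseline maps must share band and shape")
    valid_stack = np.stack([m.valid for m in maps])
    value_stack = np.stack([np.where(m.valid, m.values_um, 0.0) for m in maps])
    counts = valid_stack.sum(axis=0)
    majority = counts > len(maps) / 2.0
    if not majority.any():
        raise ValueError("no pixel is valid in a majority of the baseline maps")
    mean = np.divide(
        value_stack.sum(axis=0), counts, out=np.zeros_like(value_stack[0]), where=counts > 0
    )
    return ThicknessMap(
        values_um=np.where(majority, mean, 0.0),
        band=band,
        valid=majority,
        transverse_extent_mm=maps[0].transverse_extent_mm,
        fovea_mm=maps[0].fovea_mm,
        timestamp_s=float(np.mean([m.timestamp_s for m in maps])),
        meta={"baseline_of": len(maps)},
    )


def smooth_masked(values: np.ndarray, valid: np.ndarray, sigma_px: float) -> np.ndarray:
    """Normalized-convolution Gaussian smoothing: invalid pixels neither
    contribute to nor receive weight (no invalid-region bleed)."""
    w = valid.astype(np.float64)
    num = ndimage.gaussian_filter(np.where(valid, values, 0.0), sigma_px, mode="constant")
    den = ndimage.gaussian_filter(w, sigma_px, mode="constant")
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
    return np.where(valid, out, 0.0)


def find_fovea(
    ciz_map: ThicknessMap,
    smooth_mm: float = 0.25,
    search_halfwidth_mm: float = 1.0,
) -> tuple[float, float]:
    """Locate the fovea on a CIZ thickness map.

    The cone band is thickest at the foveal centre, so the fovea is the
    argmax of the heavily smoothed CIZ map within the central search window,
    refined by the centroid of the top-5% region.  Supply the position
    manually if the centre is invalid.
    """
    x, y = ciz_map.pixel_coords_mm()
    dx = x[1] - x[0] if len(x) > 1 else 1.0
    sm = smooth_masked(ciz_map.values_um, ciz_map.valid, smooth_mm / dx)
    central = (
        (np.abs(x)[None, :] <= search_halfwidth_mm)
        & (np.abs(y)[:, None] <= search_halfwidth_mm)
        & ciz_map.valid
    )
    if not central.any():
        raise ValueError(
            "no valid pixels in the central search window; supply the fovea manually"
        )
    masked = np.where(central, sm, -np.inf)
    peak = float(masked.max())
    lo = float(sm[central].min())
    top = masked >= peak - 0.05 * (peak - lo)
    weights = np.where(top, sm - lo, 0.0)
    total = weights.sum()
    fx = float((weights * x[None, :]).sum() / total)
    fy = float((weights * y[:, None]).sum() / total)
    return (fx, fy)


def _shift_map(values: np.ndarray, valid: np.ndarray, shift_px: tuple[float, float]):
    """Translate (bilinear) a masked map by ``(dy, dx)`` pixels."""
    w = valid.astype(np.float64)
    num = ndimage.shift(np.where(valid, values, 0.0), shift_px, order=1, mode="constant")
    den = ndimage.shift(w, shift_px, order=1, mode="constant")
    ok = den > 0.5
    vals = np.divide(num, den, out=np.zeros_like(num), where=ok)
    return vals, ok


def difference_map(
    map_t: ThicknessMap,
    baseline: ThicknessMap,
    fovea_t: tuple[float, float] | None = None,
    fovea_base: tuple[float, float] | None = None,
    smooth_sigma_px: float | None = None,
) -> DifferenceMap:
    """Thickness difference from baseline, fovea-aligned (translation only).

    ``smooth_sigma_px`` optionally applies the display smoothing
    (normalized convolution); leave ``None`` for the raw differences used in
    ROI averaging.  Fails if less than 10% of the baseline's valid area
    overlaps after alignment.
    """
    if map_t.band != baseline.band:
        raise ValueError("band mismatch between map and baseline")
    if map_t.shape != baseline.shape:
        raise ValueError("shape mismatch between map and baseline")
    fovea_t = fovea_t if fovea_t is not None else map_t.fovea_mm
    fovea_base = fovea_base if fovea_base is not None else baseline.fovea_mm
    x, _ = map_t.pixel_coords_mm()
    _, y = map_t.pixel_coords_mm()
    dx_mm = map_t.transverse_extent_mm[0] / map_t.shape[1]
    dy_mm = map_t.transverse_extent_mm[1] / map_t.shape[0]
    if fovea_t is not None and fovea_base is not None:
        shift = ((fovea_base[1] - fovea_t[1]) / dy_mm, (fovea_base[0] - fovea_t[0]) / dx_mm)
    else:
        shift = (0.0, 0.0)
    if abs(shift[0]) < 1e-12 and abs(shift[1]) < 1e-12:
        vals_t, valid_t = np.where(map_t.valid, map_t.values_um, 0.0), map_t.valid
    else:
        vals_t, valid_t = _shift_map(map_t.values_um, map_t.valid, shift)
    valid = valid_t & baseline.valid
    if valid.sum() < 0.10 * max(int(baseline.valid.sum()), 1):
        raise ValueError("less than 10% valid overlap after fovea alignment")
    diff = np.where(valid, vals_t - baseline.values_um, 0.0)
    if smooth_sigma_px is not None:
        diff = smooth_masked(diff, valid, smooth_sigma_px)
    return DifferenceMap(
        values_um=diff,
        band=map_t.band,
        valid=valid,
        transverse_extent_mm=map_t.transverse_extent_mm,
        fovea_mm=fovea_base,
        timestamp_s=map_t.timestamp_s,
        meta={"smooth_sigma_px": smooth_sigma_px},
    )


def roi_mean(diff: DifferenceMap | ThicknessMap, roi: ROISpec) -> tuple[float, int]:
    """Mean over valid pixels whose centres fall inside the ROI."""
    sel = roi.select(diff) & diff.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI contains no valid pixels")
    return float(diff.values_um[sel].mean()), n


def ez_jitter_px(ez: EZSurface, trend_window: int = 9) -> float:
    """Residual B-scan-to-B-scan EZ jitter (px RMS) about a smooth trend."""
    per_b = np.median(ez.z_ez, axis=1)
    if per_b.size < 3:
        return 0.0
    trend = ndimage.median_filter(per_b, size=min(trend_window, per_b.size), mode="nearest")
    return float(np.sqrt(np.mean((per_b - trend) ** 2)))


def process_volume(
    vol: OCTVolume, config: PipelineConfig
) -> tuple[dict[str, ThicknessMap], dict]:
    """Segment, flatten, filter, and detect bands on one volume.

    Returns the four thickness maps and a diagnostics dict (EZ jitter,
    per-B-scan path quality).
    """
    ez = segment_volume(vol, max_step=config.ez_max_step_px)
    jitter = ez_jitter_px(ez)
    target = config.ez_target_index
    hi_um = max(w[1] for w in config.band_windows_um.values())
    out_hi = target + int(np.ceil(hi_um / vol.axial_sampling_um)) + 24
    flat = flatten_volume(vol, ez, target_index=target, out_z=(0, out_hi))
    filtered = cscan_filter(flat, sigma=config.cscan_filter_sigma)
    maps = build_thickness_maps(filtered, float(target), config)
    diag = {"ez_jitter_px": jitter, "quality": ez.quality}
    return maps, diag


@dataclass
class SessionResult:
    """Everything extracted from one imaging session."""

    series: dict                      # (band, roi_label) -> PhotoresponseSeries
    baseline: dict                    # band -> ThicknessMap
    fovea_mm: tuple[float, float]
    condition: dict
    dropped: list = field(default_factory=list)

    def get(self, band: str, roi: str = "full") -> PhotoresponseSeries:
        return self.series[(band, roi)]


def process_session(
    volumes: Iterable[OCTVolume] | Iterator,
    config: PipelineConfig,
    hemifields: bool = True,
    session_id: str = "",
    track_fovea: bool = False,
) -> SessionResult:
    """Run the full pipeline over a time-ordered session of volumes.

    Accepts an iterable of volumes or of (volume, truth) pairs (truth is
    ignored), so a phantom session can be streamed without holding all
    volumes in memory.  Volumes with post-alignment EZ jitter above the QC
    threshold are dropped and reported in ``dropped``.

    All maps are aligned to the fovea found on the averaged baseline;
    ``track_fovea=True`` re-estimates the fovea on every time point instead,
    which handles transverse drift between volumes but is biased when a
    half-field response elevates the cone band asymmetrically.
    """
    rois: dict[str, list[ROISpec]] = {}
    for band in BANDS:
        specs = [ROISpec(config.roi_diameters_mm[band])]
        if hemifields:
            specs += [
                ROISpec(config.roi_diameters_mm[band], hemifield="inferior"),
                ROISpec(config.roi_diameters_mm[band], hemifield="superior"),
            ]
        rois[band] = specs

    baseline_maps: dict[str, list[ThicknessMap]] = {b: [] for b in BANDS}
    records: dict[tuple[str, str], list[tuple[float, float, int]]] = {}
    dropped: list[tuple[float, float]] = []
    baseline: dict[str, ThicknessMap] = {}
    fovea_base: tuple[float, float] | None = None
    condition: dict = {}

    for item in volumes:
        vol = item[0] if isinstance(item, tuple) else item
        if not condition:
            condition = {
                "bleach_fraction": vol.meta.get("bleach_fraction"),
                "field_mode": vol.meta.get("field_mode"),
            }
        maps, diag = process_volume(vol, config)
        if diag["ez_jitter_px"] > config.motion_qc_rms_px:
            dropped.append((vol.timestamp_s, diag["ez_jitter_px"]))
            continue
        if vol.timestamp_s < 0:
            for band in BANDS:
                baseline_maps[band].append(maps[band])
            continue
        if not baseline:
            if not baseline_maps["CIZ"]:
                raise ValueError("no baseline volumes before the first post-flash volume")
            baseline = {b: average_baseline(baseline_maps[b]) for b in BANDS}
            fovea_base = find_fovea(baseline["CIZ"], smooth_mm=config.fovea_smooth_mm)
        fovea_t = (
            find_fovea(maps["CIZ"], smooth_mm=config.fovea_smooth_mm)
            if track_fovea
            else fovea_base
        )
        for band in BANDS:
            diff = difference_map(maps[band], baseline[band], fovea_t, fovea_base)
            for spec in rois[band]:
                mean, n = roi_mean(diff, spec)
                records.setdefault((band, spec.label), []).append(
                    (vol.timestamp_s, mean, n)
                )

    if not records:
        raise ValueError("session contained no usable post-flash volumes")
    series = {}
    for key, rows in records.items():
        t, m, n = (np.asarray(col) for col in zip(*rows))
        series[key] = PhotoresponseSeries(
            band=key[0],
            roi=key[1],
            times_s=t,
            mean_diff_um=m,
            n_pixels=n,
            condition=condition,
            session_id=session_id,
        )
    assert fovea_base is not None
    return SessionResult(
        series=series,
        baseline=baseline,
        fovea_mm=fovea_base,
        condition=condition,
        dropped=dropped,
    )
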