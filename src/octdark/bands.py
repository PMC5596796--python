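"""Transverse C-scan filtering, four-band peak detection, thickness maps.

After flattening to the EZ, a 2-D transverse Gaussian filter (default
sigma = 2 A-scans) is applied at every depth of the linear-intensity volume
to suppress speckle and accentuate the four outer retinal bands.  Band
positions are then found per A-scan as local intensity maxima below the EZ:
candidate peaks are assigned to the ordered bands CIZ < RIZ < RPE < BM by a
dynamic program that maximizes total peak prominence subject to each band
lying inside its depth window, and each detection is refined to subpixel by
a 3-point parabolic fit, ``δ = ½(I₋ − I₊)/(I₋ − 2I₀ + I₊)``.

Prominence is measured as peak height above the per-A-scan floor (the
minimum filtered intensity over the search range); candidates below a
fraction (default 10%) of the strongest RPE-window candidate are rejected,
and of candidates closer together than the minimum band separation
(default 6 μm, about twice the axial resolution — residual speckle ripple
can split one band into two local maxima) only the strongest survives.
A band with no admissible peak — e.g. the foveal RIZ — is flagged invalid,
never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core_io import BANDS, OCTVolume, PipelineConfig, ThicknessMap

__all__ = [
    "BandSurfaces",
    "cscan_filter",
    "detect_bands",
    "detect_bands_volume",
    "assign_bands",
    "build_thickness_maps",
    "parabolic_delta",
]

_MAX_CANDIDATES = 6
DEFAULT_MIN_SEPARATION_UM = 6.0


def _suppress_close(depths_um: np.ndarray, heights: np.ndarray, sep_um: float) -> np.ndarray:
    """Non-maximum suppression: zero the height of any candidate that has a
    stronger candidate within ``sep_um`` (ties keep the shallower peak).
    Batched over leading axes; candidates are along the last axis."""
    d = depths_um[..., :, None] - depths_um[..., None, :]
    close = np.abs(d) < sep_um
    h_i = heights[..., :, None]
    h_j = heights[..., None, :]
    idx = np.arange(depths_um.shape[-1])
    stronger = (h_j > h_i) | ((h_j == h_i) & (idx[None, :] < idx[:, None]))
    suppressed = (close & stronger & (h_j > 0)).any(axis=-1)
    return np.where(suppressed, 0.0, heights)


@dataclass
class BandSurfaces:
    """Per-A-scan subpixel band depths below the EZ with validity masks."""

    depth_um: dict          # band -> (b, a) float μm
    valid: dict             # band -> (b, a) bool
    prominence: dict        # band -> (b, a) float

    def ordering_ok(self) -> bool:
        """CIZ < RIZ < RPE < BM wherever all four bands are valid."""
        all_valid = np.logical_and.reduce([self.valid[b] for b in BANDS])
        if not all_valid.any():
            return True
        stack = np.stack([self.depth_um[b][all_valid] for b in BANDS])
        return bool((np.diff(stack, axis=0) > 0).all())


def cscan_filter(vol: OCTVolume, sigma: float = 2.0) -> OCTVolume:
    """Gaussian-filter every constant-depth (C-scan) slice transversely.

    ``sigma`` is in A-scan units on both transverse axes; boundaries are
    reflective; the filter acts on linear intensity.  A constant volume is
    unchanged (DC preservation).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = ndimage.gaussian_filter(
        vol.intensity.astype(np.float32, copy=True),
        sigma=(sigma, sigma, 0.0),
        mode="reflect",
    )
    meta = dict(vol.meta)
    meta["cscan_filter_sigma"] = sigma
    return OCTVolume(
        intensity=out,
        axial_sampling_um=vol.axial_sampling_um,
        transverse_extent_mm=vol.transverse_extent_mm,
        timestamp_s=vol.timestamp_s,
        meta=meta,
    )


def parabolic_delta(im: np.ndarray, i0: np.ndarray, ip: np.ndarray) -> np.ndarray:
    """Subpixel offset of a 3-sample peak: ``½(I₋ − I₊)/(I₋ − 2I₀ + I₊)``.

    Exact for quadratic peaks; |δ| is clipped to 0.5 pixel.
    """
    denom = im - 2.0 * i0 + ip
    delta = np.where(np.abs(denom) > 1e-30, 0.5 * (im - ip) / np.where(denom == 0, 1, denom), 0.0)
    return np.clip(delta, -0.5, 0.5)


def _tie_penalty(depth_um, window: tuple[float, float], scale: float):
    """Positional prior: ``scale`` times the candidate's normalized distance
    from the band-window centre.  ``scale`` is ~1% of the reference peak
    height, so it decides only ties and near-ties between assignments of
    equal total prominence (e.g. a one-slot label shift when a band's peak
    is lost in a speckle null)."""
    lo, hi = window
    centre = 0.5 * (lo + hi)
    halfwidth = 0.5 * (hi - lo)
    return scale * np.abs(np.asarray(depth_um) - centre) / halfwidth


def assign_bands(
    depths_um: np.ndarray,
    prominences: np.ndarray,
    windows: dict[str, tuple[float, float]],
    tie_scale: float = 0.0,
) -> dict[str, int]:
    """Assign candidate peaks (sorted by depth) to the ordered bands.

    Maximizes total prominence (minus the positional tie-break penalty,
    see :func:`_tie_penalty`) subject to strictly increasing depths across
    assigned bands and each assigned peak inside its band window; a band may
    stay unassigned.  Returns band -> candidate index (or -1).  Solved by a
    sequence-alignment dynamic program over (band, candidate).
    """
    depths_um = np.asarray(depths_um, dtype=np.float64)
    prominences = np.asarray(prominences, dtype=np.float64)
    n = len(depths_um)
    bands = list(BANDS)
    m = len(bands)
    # dp[j][i]: best score using bands[:j] and candidates[:i]
    dp = np.zeros((m + 1, n + 1))
    choice = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 skip cand, 1 assign, 2 skip band
    for j in range(1, m + 1):
        lo, hi = windows[bands[j - 1]]
        for i in range(n + 1):
            best, ch = (dp[j - 1][i], 2)  # skip this band
            if i > 0 and dp[j][i - 1] > best:
                best, ch = dp[j][i - 1], 0  # candidate unused by bands[:j]
            if i > 0 and lo <= depths_um[i - 1] <= hi:
                score = prominences[i - 1] - _tie_penalty(
                    depths_um[i - 1], windows[bands[j - 1]], tie_scale
                )
                cand = dp[j - 1][i - 1] + score
                if cand > best:
                    best, ch = cand, 1
            dp[j][i], choice[j][i] = best, ch
    out = {b: -1 for b in bands}
    j, i = m, n
    while j > 0:
        ch = choice[j][i]
        if ch == 1:
            out[bands[j - 1]] = i - 1
            j, i = j - 1, i - 1
        elif ch == 0:
            i -= 1
        else:
            j -= 1
    return out


def detect_bands(
    ascan: np.ndarray,
    ez_index: float,
    windows: dict[str, tuple[float, float]],
    axial_sampling_um: float,
    prominence_frac: float = 0.10,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
) -> dict[str, tuple[float, bool, float]]:
    """Detect the four bands on one filtered, flattened A-scan.

    Returns band -> (depth_um below EZ, valid, prominence).  Fewer than two
    detectable peaks flags the whole A-scan invalid.
    """
    ascan = np.asarray(ascan, dtype=np.float64)
    lo_um = min(w[0] for w in windows.values())
    hi_um = max(w[1] for w in windows.values())
    z_lo = int(np.floor(ez_index + lo_um / axial_sampling_um)) - 1
    z_hi = int(np.ceil(ez_index + hi_um / axial_sampling_um)) + 2
    z_lo = max(z_lo, 1)
    z_hi = min(z_hi, len(ascan) - 1)
    invalid = {b: (np.nan, False, 0.0) for b in BANDS}
    if z_hi - z_lo < 3:
        return invalid
    seg = ascan[z_lo:z_hi]
    floor = float(seg.min())
    peaks, _ = signal.find_peaks(seg)
    if len(peaks) == 0:
        return invalid
    heights = seg[peaks] - floor
    depths = (peaks + z_lo - ez_index) * axial_sampling_um
    rpe_lo, rpe_hi = windows["RPE"]
    in_rpe = (depths >= rpe_lo) & (depths <= rpe_hi)
    ref = heights[in_rpe].max() if in_rpe.any() else heights.max()
    keep = heights >= prominence_frac * ref
    peaks, heights, depths = peaks[keep], heights[keep], depths[keep]
    if len(peaks) > _MAX_CANDIDATES:
        top = np.sort(np.argsort(heights)[-_MAX_CANDIDATES:])
        peaks, heights, depths = peaks[top], heights[top], depths[top]
    heights = _suppress_close(depths, heights, min_separation_um)
    keep = heights > 0
    peaks, heights, depths = peaks[keep], heights[keep], depths[keep]
    if len(peaks) < 2:
        return invalid
    assign = assign_bands(depths, heights, windows, tie_scale=0.01 * ref)
    out = {}
    for band in BANDS:
        i = assign[band]
        if i < 0:
            out[band] = (np.nan, False, 0.0)
            continue
        z = peaks[i] + z_lo
        delta = float(parabolic_delta(ascan[z - 1], ascan[z], ascan[z + 1]))
        depth = (z + delta - ez_index) * axial_sampling_um
        out[band] = (float(depth), True, float(heights[i]))
    return out


def detect_bands_volume(
    filtered: OCTVolume,
    ez_index: float,
    windows: dict[str, tuple[float, float]],
    prominence_frac: float = 0.10,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
) -> BandSurfaces:
    """Vectorized band detection over every A-scan of a flattened volume.

    Same candidate/prominence/assignment rules as :func:`detect_bands`; the
    assignment DP is evaluated batched across A-scans.
    """
    intensity = filtered.intensity.astype(np.float64)
    dz = filtered.axial_sampling_um
    n_b, n_a, n_z = intensity.shape
    lo_um = min(w[0] for w in windows.values())
    hi_um = max(w[1] for w in windows.values())
    z_lo = max(int(np.floor(ez_index + lo_um / dz)) - 1, 1)
    z_hi = min(int(np.ceil(ez_index + hi_um / dz)) + 2, n_z - 1)
    seg = intensity[:, :, z_lo:z_hi]
    floor = seg.min(axis=2)

    inner = seg[:, :, 1:-1]
    is_peak = (inner > seg[:, :, :-2]) & (inner >= seg[:, :, 2:])
    heights = np.where(is_peak, inner - floor[:, :, None], 0.0)

    # reference height: strongest candidate in the RPE window
    zz_um = (np.arange(z_lo + 1, z_hi - 1) - ez_index) * dz
    rpe_lo, rpe_hi = windows["RPE"]
    rpe_sel = (zz_um >= rpe_lo) & (zz_um <= rpe_hi)
    ref = heights[:, :, rpe_sel].max(axis=2)
    no_rpe = ref <= 0
    if no_rpe.any():
        ref = np.where(no_rpe, heights.max(axis=2), ref)
    thresh = prominence_frac * ref
    heights = np.where(heights >= thresh[:, :, None], heights, 0.0)

    k = _MAX_CANDIDATES
    flat_h = heights.reshape(-1, heights.shape[2])
    top = np.argpartition(-flat_h, kth=k - 1, axis=1)[:, :k]
    top.sort(axis=1)  # ascending depth
    cand_h = np.take_along_axis(flat_h, top, axis=1)
    cand_z = top + (z_lo + 1)  # absolute z of each candidate
    cand_depth = (cand_z - ez_index) * dz
    cand_h = _suppress_close(cand_depth, cand_h, min_separation_um)
    usable = cand_h > 0
    n_peaks = usable.sum(axis=1)

    # batched assignment DP over (band, candidate)
    n_scan = flat_h.shape[0]
    neg = -1e30
    bands = list(BANDS)
    ref_flat = ref.reshape(-1)
    dp = np.zeros((len(bands) + 1, k + 1, n_scan))
    choice = np.zeros((len(bands) + 1, k + 1, n_scan), dtype=np.int8)
    for j in range(1, len(bands) + 1):
        lo, hi = windows[bands[j - 1]]
        for i in range(k + 1):
            best = dp[j - 1, i].copy()
            ch = np.full(n_scan, 2, dtype=np.int8)
            if i > 0:
                better = dp[j, i - 1] > best
                best = np.where(better, dp[j, i - 1], best)
                ch = np.where(better, 0, ch)
                ok = (
                    usable[:, i - 1]
                    & (cand_depth[:, i - 1] >= lo)
                    & (cand_depth[:, i - 1] <= hi)
                )
                score = cand_h[:, i - 1] - _tie_penalty(
                    cand_depth[:, i - 1], windows[bands[j - 1]], 0.01 * ref_flat
                )
                cand = np.where(ok, dp[j - 1, i - 1] + score, neg)
                better = cand > best
                best = np.where(better, cand, best)
                ch = np.where(better, 1, ch)
            dp[j, i], choice[j, i] = best, ch

    assign = np.full((len(bands), n_scan), -1, dtype=np.int64)
    j_idx = np.full(n_scan, len(bands))
    i_idx = np.full(n_scan, k)
    for _ in range((len(bands) + 1) * (k + 1)):
        active = j_idx > 0
        if not active.any():
            break
        ch = choice[j_idx, i_idx, np.arange(n_scan)]
        take = active & (ch == 1)
        assign[j_idx[take] - 1, np.arange(n_scan)[take]] = i_idx[take] - 1
        j_idx = np.where(take, j_idx - 1, j_idx)
        i_idx = np.where(take, i_idx - 1, i_idx)
        skip_c = active & (ch == 0)
        i_idx = np.where(skip_c, i_idx - 1, i_idx)
        skip_b = active & (ch == 2)
        j_idx = np.where(skip_b, j_idx - 1, j_idx)

    scan_ok = n_peaks >= 2
    flat_i = intensity.reshape(-1, n_z)
    depth_um, valid, prom = {}, {}, {}
    rows = np.arange(n_scan)
    for bi, band in enumerate(bands):
        idx = assign[bi]
        has = (idx >= 0) & scan_ok
        safe = np.where(has, idx, 0)
        z = cand_z[rows, safe]
        im = flat_i[rows, z - 1]
        i0 = flat_i[rows, z]
        ip = flat_i[rows, z + 1]
        delta = parabolic_delta(im, i0, ip)
        d = (z + delta - ez_index) * dz
        depth_um[band] = np.where(has, d, np.nan).reshape(n_b, n_a)
        valid[band] = has.reshape(n_b, n_a)
        prom[band] = np.where(has, cand_h[rows, safe], 0.0).reshape(n_b, n_a)
    return BandSurfaces(depth_um=depth_um, valid=valid, prominence=prom)


def _fill_small_holes(values: np.ndarray, valid: np.ndarray, max_hole: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Median-fill invalid regions of <= max_hole pixels from valid 3x3
    neighbours; larger holes stay invalid."""
    invalid = ~valid
    if not invalid.any():
        return values, valid
    labels, n_lab = ndimage.label(invalid)
    if n_lab == 0:
        return values, valid
    sizes = ndimage.sum_labels(invalid, labels, index=np.arange(1, n_lab + 1))
    small = np.isin(labels, np.nonzero(sizes <= max_hole)[0] + 1)
    values = values.copy()
    valid = valid.copy()
    ys, xs = np.nonzero(small)
    n_y, n_x = values.shape
    for y, x in zip(ys, xs):
        y0, y1 = max(y - 1, 0), min(y + 2, n_y)
        x0, x1 = max(x - 1, 0), min(x + 2, n_x)
        neigh_valid = valid[y0:y1, x0:x1]
        if neigh_valid.sum() >= 3:
            values[y, x] = np.median(values[y0:y1, x0:x1][neigh_valid])
            valid[y, x] = True
    return values, valid


def build_thickness_maps(
    filtered: OCTVolume,
    ez_target_index: float,
    config: PipelineConfig,
    fovea_mm: tuple[float, float] | None = None,
) -> dict[str, ThicknessMap]:
    """Assemble per-band thickness maps from a filtered, flattened volume.

    Isolated invalid pixels (holes of <= 2 pixels) are median-filled from
    their valid 3x3 neighbours; larger holes (e.g. the foveal RIZ gap) are
    left invalid.
    """
    surfaces = detect_bands_volume(
        filtered,
        ez_target_index,
        config.band_windows_um,
        prominence_frac=config.prominence_frac,
        min_separation_um=config.band_min_separation_um,
    )
    maps = {}
    for band in BANDS:
        vals, valid = _fill_small_holes(surfaces.depth_um[band], surfaces.valid[band])
        maps[band] = ThicknessMap(
            values_um=np.where(valid, vals, 0.0),
            band=band,
            valid=valid,
            transverse_extent_mm=filtered.transverse_extent_mm,
            fovea_mm=fovea_mm,
            timestamp_s=filtered.timestamp_s,
            meta={"source": "detect_bands"},
        )
    return maps
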