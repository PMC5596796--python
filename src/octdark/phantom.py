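"""Synthetic outer-retina phantom with bleach-graded photoresponses.

The phantom renders the layered reflectance profile of the outer retina —
the ellipsoid zone (EZ) reference band and, below it, the cone
interdigitation zone (CIZ), rod interdigitation zone (RIZ, absent near the
fovea), apical RPE, and Bruch's membrane (BM) — as Gaussian axial peaks at
eccentricity-dependent depths, on a 6 × 6-mm scan grid.  Three
time-dependent photoresponses, graded by the rhodopsin bleach fraction F,
are injected as depth increments:

* cone (CIZ): an immediate elongation decaying exponentially, complete
  within ~5 minutes;
* rod (RIZ): a slow elongation peaking 5–7 minutes after the flash;
* RPE/BM: a biphasic response peaking ~3 minutes after the flash and
  undershooting the baseline near 10–15 minutes, applied identically to the
  RPE and BM depths.

Response amplitudes scale as ``F**p`` with ``p = ln 2 / ln(16/9)`` so that
the maximal response after a 96% bleach is exactly twice that after a 54%
bleach.  The RPE/BM waveform is a difference of two gamma-shaped pulses,
which has exactly one zero crossing on (0, 30] minutes for any positive
undershoot fraction (the pulse ratio is strictly monotone in time).

Noise: fully developed speckle is modelled as a unit-mean multiplicative
field (per-pixel Gamma(n_looks, 1/n_looks), optionally smoothed transversely
to give the speckle a grain size), applied to the noise-free mean intensity,
which includes a small additive pedestal; axial eye motion is a per-B-scan
random walk added to all surface depths.  Ground truth (EZ surface, band
depth maps, exposure mask, injected kinetics) accompanies every volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import (
    DEFAULT_AXIAL_SAMPLING_UM,
    DEFAULT_EXTENT_MM,
    AcquisitionSchedule,
    OCTVolume,
)

__all__ = [
    "ScanGrid",
    "RetinaModel",
    "PhotoresponseKinetics",
    "ExposureField",
    "NoiseModel",
    "PhantomTruth",
    "band_depths",
    "render_volume",
    "simulate_session",
    "adaptometry_curve",
    "AMPLITUDE_BLEACH_EXPONENT",
]

BANDS = ("CIZ", "RIZ", "RPE", "BM")

# Exponent p with (0.96/0.54)**p == 2: the maximal response doubles from a
# 54% to a 96% bleach.
AMPLITUDE_BLEACH_EXPONENT = math.log(2.0) / math.log(16.0 / 9.0)


@dataclass
class ScanGrid:
    """Sampling geometry of a rendered volume."""

    n_bscans: int = 400
    n_ascans: int = 400
    n_depth: int = 1024
    axial_sampling_um: float = DEFAULT_AXIAL_SAMPLING_UM
    transverse_extent_mm: tuple[float, float] = DEFAULT_EXTENT_MM

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        ex, ey = self.transverse_extent_mm
        x = (np.arange(self.n_ascans) + 0.5) * ex / self.n_ascans - ex / 2.0
        y = (np.arange(self.n_bscans) + 0.5) * ey / self.n_bscans - ey / 2.0
        return x, y


@dataclass
class RetinaModel:
    """Baseline anatomy: band depths below the EZ as linear functions of
    eccentricity from the fovea out to ``taper_radius_mm`` (constant beyond),
    with the RIZ midway between CIZ and RPE and absent near the fovea."""

    fovea_center_mm: tuple[float, float] = (0.0, 0.0)
    ez_depth_um: float = 140.0          # EZ depth below the volume top at the fovea
    ez_bowl_um: float = 10.0            # shallow posterior bowl out to taper_radius
    ciz_depth_um: tuple[float, float] = (32.0, 22.0)   # (fovea, taper_radius)
    rpe_depth_um: tuple[float, float] = (50.0, 42.0)
    bm_depth_um: tuple[float, float] = (62.0, 56.0)
    taper_radius_mm: float = 3.0
    riz_min_eccentricity_mm: float = 0.5
    band_amplitudes: dict = field(
        default_factory=lambda: {"EZ": 1.0, "CIZ": 0.55, "RIZ": 0.45, "RPE": 0.8, "BM": 0.5}
    )
    background_amplitude: float = 0.05
    axial_resolution_um: float = 3.0    # FWHM of rendered peaks, in tissue

    def _linear(self, pair: tuple[float, float], r) -> np.ndarray:
        frac = np.minimum(np.asarray(r, dtype=np.float64), self.taper_radius_mm) / self.taper_radius_mm
        return pair[0] + (pair[1] - pair[0]) * frac

    def baseline_depths_um(self, r) -> dict[str, np.ndarray]:
        """Band depths below the EZ (μm) at eccentricity ``r`` (mm)."""
        ciz = self._linear(self.ciz_depth_um, r)
        rpe = self._linear(self.rpe_depth_um, r)
        bm = self._linear(self.bm_depth_um, r)
        riz = 0.5 * (ciz + rpe)
        return {"CIZ": ciz, "RIZ": riz, "RPE": rpe, "BM": bm}

    def ez_profile_um(self, r) -> np.ndarray:
        frac = np.minimum(np.asarray(r, dtype=np.float64), self.taper_radius_mm) / self.taper_radius_mm
        return self.ez_depth_um + self.ez_bowl_um * frac**2


def _pulse(t_min, t_peak_min: float, kappa: float) -> np.ndarray:
    """Gamma-shaped pulse normalized to peak 1 at ``t_peak_min``; 0 for t<=0."""
    t = np.asarray(t_min, dtype=np.float64)
    u = np.where(t > 0, t / t_peak_min, 0.0)
    out = np.where(t > 0, u**kappa * np.exp(kappa * (1.0 - u)), 0.0)
    return out


@dataclass
class PhotoresponseKinetics:
    """Injected kinetic parameters for the three photoresponses.

    Amplitudes are the F = 1 values in μm; the effective amplitude at bleach
    fraction F is ``amp · F**bleach_exponent``.  Times in minutes.
    """

    cone_amp_um: float = 1.05
    cone_tau_min: float = 1.5
    rod_amp_um: float = 0.8
    rod_peak_base_min: float = 4.0
    rod_peak_slope_min: float = 3.0     # t_p(F) = base + slope·F
    rod_shape: float = 2.0
    osc_amp_um: float = 0.9
    osc_peak_min: float = 3.0
    osc_trough_min: float = 12.0
    osc_peak_shape: float = 2.0
    osc_trough_shape: float = 4.0
    osc_undershoot_frac: float = 0.3
    bleach_exponent: float = AMPLITUDE_BLEACH_EXPONENT

    def amplitude_scale(self, bleach_fraction: float) -> float:
        if bleach_fraction <= 0:
            return 0.0
        return float(bleach_fraction**self.bleach_exponent)

    def rod_peak_time_min(self, bleach_fraction: float) -> float:
        return self.rod_peak_base_min + self.rod_peak_slope_min * bleach_fraction

    def cone_response_um(self, t_min, bleach_fraction: float) -> np.ndarray:
        t = np.asarray(t_min, dtype=np.float64)
        amp = self.cone_amp_um * self.amplitude_scale(bleach_fraction)
        return np.where(t > 0, amp * np.exp(-np.maximum(t, 0.0) / self.cone_tau_min), 0.0)

    def rod_response_um(self, t_min, bleach_fraction: float) -> np.ndarray:
        amp = self.rod_amp_um * self.amplitude_scale(bleach_fraction)
        return amp * _pulse(t_min, self.rod_peak_time_min(bleach_fraction), self.rod_shape)

    def rpe_bm_response_um(self, t_min, bleach_fraction: float) -> np.ndarray:
        amp = self.osc_amp_um * self.amplitude_scale(bleach_fraction)
        return amp * (
            _pulse(t_min, self.osc_peak_min, self.osc_peak_shape)
            - self.osc_undershoot_frac * _pulse(t_min, self.osc_trough_min, self.osc_trough_shape)
        )

    def increments_um(self, t_min, bleach_fraction: float) -> dict[str, np.ndarray]:
        rpe_bm = self.rpe_bm_response_um(t_min, bleach_fraction)
        return {
            "CIZ": self.cone_response_um(t_min, bleach_fraction),
            "RIZ": self.rod_response_um(t_min, bleach_fraction),
            "RPE": rpe_bm,
            "BM": rpe_bm,
        }


@dataclass
class ExposureField:
    """Spatial bleaching pattern: full field, inferior half field, or none.

    The half-field boundary runs horizontally through the fovea; the mask
    ramps smoothly (cubic smoothstep) from 0 to 1 over ``transition_width_mm``
    and is exactly 0/1 outside the transition zone.  Inferior retina is +y.
    """

    mode: str = "full"
    bleach_fraction: float = 0.0
    transition_width_mm: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("full", "half_inferior", "none"):
            raise ValueError("mode must be 'full', 'half_inferior', or 'none'")
        if not 0.0 <= self.bleach_fraction <= 1.0:
            raise ValueError("bleach_fraction must be in [0, 1]")
        if self.transition_width_mm <= 0:
            raise ValueError("transition_width_mm must be > 0")

    def mask(self, y_rel_fovea_mm) -> np.ndarray:
        """Exposure weight in [0, 1] at signed vertical offset from the fovea."""
        y = np.asarray(y_rel_fovea_mm, dtype=np.float64)
        if self.mode == "none":
            return np.zeros_like(y)
        if self.mode == "full":
            return np.ones_like(y)
        u = np.clip((y + self.transition_width_mm / 2.0) / self.transition_width_mm, 0.0, 1.0)
        return 3.0 * u**2 - 2.0 * u**3


@dataclass
class NoiseModel:
    """Speckle and motion statistics of the rendered volumes."""

    speckle: bool = True
    grain_sigma_px: float = 0.75
    n_looks: int = 4
    additive_noise_floor: float = 0.02
    motion_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if self.n_looks < 1:
            raise ValueError("n_looks must be >= 1")
        if self.grain_sigma_px < 0 or self.additive_noise_floor < 0 or self.motion_sigma_px < 0:
            raise ValueError("noise parameters must be >= 0")

    @staticmethod
    def quiet() -> "NoiseModel":
        return NoiseModel(speckle=False, additive_noise_floor=0.0, motion_sigma_px=0.0)


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside each rendered volume."""

    ez_px: np.ndarray                      # (b, a) EZ depth in pixels (subpixel)
    band_depth_um: dict                    # band -> (b, a) depth below EZ, μm
    band_valid: dict                       # band -> (b, a) bool (RIZ absent at fovea)
    exposure_mask: np.ndarray              # (b, a) in [0, 1]
    bleach_fraction: float
    timestamp_s: float
    kinetics: PhotoresponseKinetics
    fovea_center_mm: tuple[float, float]


def band_depths(
    model: RetinaModel,
    kinetics: PhotoresponseKinetics,
    r_mm,
    position_mm: tuple[float, float],
    t_min: float,
    field_: ExposureField,
) -> dict[str, np.ndarray]:
    """Band depths below the EZ (μm) at time ``t_min`` after the flash.

    ``position_mm`` is the transverse location (x, y) relative to the volume
    centre; the exposure mask is evaluated at its vertical offset from the
    fovea.  Increments vanish for t <= 0 and where the mask is 0.
    """
    base = model.baseline_depths_um(r_mm)
    y_rel = np.asarray(position_mm[1], dtype=np.float64) - model.fovea_center_mm[1]
    m = field_.mask(y_rel)
    inc = kinetics.increments_um(t_min, field_.bleach_fraction)
    return {band: base[band] + m * inc[band] for band in BANDS}


def _speckle_field(shape, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative speckle, optionally transversely correlated."""
    w = rng.gamma(noise.n_looks, 1.0 / noise.n_looks, size=shape).astype(np.float32)
    if noise.grain_sigma_px > 0:
        gaussian_filter(
            w, sigma=(noise.grain_sigma_px, noise.grain_sigma_px, 0.0),
            mode="reflect", output=w,
        )
    return w


def render_volume(
    model: RetinaModel,
    kinetics: PhotoresponseKinetics,
    t_min: float,
    field_: ExposureField,
    noise: NoiseModel,
    grid: ScanGrid,
    rng: np.random.Generator | None = None,
    motion_px: np.ndarray | None = None,
) -> tuple[OCTVolume, PhantomTruth]:
    """Render one volume at ``t_min`` minutes after the flash.

    Each A-scan is a sum of Gaussian peaks (FWHM = the tissue axial
    resolution) at the EZ and the four band depths, over a constant
    background, plus the additive pedestal; speckle multiplies the mean.
    ``motion_px`` optionally supplies per-B-scan axial offsets (otherwise
    drawn as a random walk with the noise model's step sigma).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x, y = grid.coords_mm()
    fx, fy = model.fovea_center_mm
    r = np.hypot(x[None, :] - fx, y[:, None] - fy)
    dz = grid.axial_sampling_um

    mask = np.broadcast_to(field_.mask(y - fy)[:, None], r.shape)
    depths = band_depths(model, kinetics, r, (x[None, :], y[:, None]), t_min, field_)
    ez_um = model.ez_profile_um(r)

    if motion_px is None:
        if noise.motion_sigma_px > 0:
            steps = rng.normal(0.0, noise.motion_sigma_px, size=grid.n_bscans)
            motion_px = np.cumsum(steps)
        else:
            motion_px = np.zeros(grid.n_bscans)
    ez_px = ez_um / dz + motion_px[:, None]

    riz_valid = r >= model.riz_min_eccentricity_mm
    valid = {b: np.ones_like(riz_valid) if b != "RIZ" else riz_valid for b in BANDS}

    sigma_px = model.axial_resolution_um / (2.0 * math.sqrt(2.0 * math.log(2.0))) / dz
    band_px = {b: ez_px + depths[b] / dz for b in BANDS}
    peaks = [("EZ", ez_px, model.band_amplitudes["EZ"], None)] + [
        (b, band_px[b], model.band_amplitudes[b], valid[b]) for b in BANDS
    ]

    z_lo = int(np.floor(min(p[1].min() for p in peaks) - 6 * sigma_px))
    z_hi = int(np.ceil(max(p[1].max() for p in peaks) + 6 * sigma_px)) + 1
    if z_lo < 0 or z_hi > grid.n_depth:
        raise ValueError("band depths exceed the axial range of the grid")

    pedestal = model.background_amplitude + noise.additive_noise_floor
    zz = np.arange(z_hi - z_lo, dtype=np.float32)  # window-relative depth
    mean = np.full((grid.n_bscans, grid.n_ascans, z_hi - z_lo), pedestal, dtype=np.float32)
    inv2s2 = 1.0 / (2.0 * sigma_px**2)
    for name, z_px, amp, vmask in peaks:
        c = (z_px - z_lo).astype(np.float32)[..., None]
        g = np.exp((-(zz[None, None, :] - c) ** 2 * inv2s2).astype(np.float32))
        if vmask is not None and not vmask.all():
            g *= vmask[..., None].astype(np.float32)
        mean += np.float32(amp) * g
    del g

    if noise.speckle:
        window = mean * _speckle_field(mean.shape, noise, rng)
    else:
        window = mean

    intensity = np.full(
        (grid.n_bscans, grid.n_ascans, grid.n_depth), pedestal, dtype=np.float32
    )
    intensity[:, :, z_lo:z_hi] = window

    vol = OCTVolume(
        intensity=intensity,
        axial_sampling_um=dz,
        transverse_extent_mm=grid.transverse_extent_mm,
        timestamp_s=t_min * 60.0,
        meta={
            "phantom": True,
            "bleach_fraction": field_.bleach_fraction,
            "field_mode": field_.mode,
        },
    )
    truth = PhantomTruth(
        ez_px=ez_px,
        band_depth_um=depths,
        band_valid=valid,
        exposure_mask=np.asarray(mask),
        bleach_fraction=field_.bleach_fraction,
        timestamp_s=t_min * 60.0,
        kinetics=kinetics,
        fovea_center_mm=model.fovea_center_mm,
    )
    return vol, truth


def simulate_session(
    model: RetinaModel,
    kinetics: PhotoresponseKinetics,
    field_: ExposureField,
    schedule: AcquisitionSchedule,
    noise: NoiseModel,
    grid: ScanGrid,
    seed: int,
) -> Iterator[tuple[OCTVolume, PhantomTruth]]:
    """Yield the time-ordered volumes of one imaging session.

    Baseline volumes (t < 0) carry zero kinetic increments; per-volume random
    streams derive deterministically from the session seed.
    """
    times_s = schedule.times_s()
    children = np.random.SeedSequence(seed).spawn(len(times_s))
    for t_s, child in zip(times_s, children):
        rng = np.random.default_rng(child)
        vol, truth = render_volume(
            model, kinetics, t_s / 60.0, field_, noise, grid, rng=rng
        )
        vol.timestamp_s = t_s
        truth = replace(truth, timestamp_s=t_s)
        yield vol, truth


def adaptometry_curve(bleach_fraction: float, t_min) -> np.ndarray:
    """Two-branch dark-adaptation threshold-recovery curve (log10 units).

    The elevation of the psychophysical threshold above the dark-adapted
    level is the upper envelope of a fast cone branch (exponential decay to
    the plateau) and a delayed rod branch (plateau, then exponential
    recovery), both scaled with the bleach fraction.  For comparison plots
    only; not part of the OCT pipeline.
    """
    if not 0.0 <= bleach_fraction <= 1.0:
        raise ValueError("bleach_fraction must be in [0, 1]")
    t = np.asarray(t_min, dtype=np.float64)
    if bleach_fraction == 0.0:
        return np.zeros_like(t)
    s = math.sqrt(bleach_fraction)
    cone = 2.0 * s * np.exp(-np.maximum(t, 0.0) / 1.0)
    delay = 4.0 + 8.0 * bleach_fraction
    rod = 3.5 * s * np.exp(-np.maximum(t - delay, 0.0) / 2.0)
    return np.maximum(cone, rod)
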