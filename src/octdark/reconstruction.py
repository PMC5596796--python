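"""Spectral-domain OCT reconstruction.

Raw spectra are sampled uniformly in *wavelength* by the spectrometer; depth
structure lives in the Fourier domain of *wavenumber*.  Reconstruction is
therefore: cubic resampling onto a uniform k grid, numerical dispersion
compensation (a quadratic + cubic spectral phase about the centre
wavenumber), zero-padding, and an FFT whose magnitude is the A-scan.

Axial sampling arithmetic: with a uniform k grid of step ``δk`` (rad/μm) and
an ``n_fft``-point transform, one depth pixel corresponds to ``π/(n_fft·δk)``
μm of optical path; dividing by the tissue group index (1.336, water)
converts optical to geometric depth in tissue.  The system modelled here has
a 170-nm FWHM source centred at 870 nm, 3072 spectral pixels, a 2.86-mm
imaging range in air (2.14 mm in tissue), and zero-pads to 4096 depth
pixels, giving 0.52 μm per pixel in tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SpectralFrame",
    "DispersionCoefficients",
    "ReconstructedAScan",
    "gaussian_envelope",
    "resample_to_wavenumber",
    "apply_dispersion",
    "reconstruct_ascan",
    "axial_sampling_um",
    "tissue_scale",
    "TISSUE_GROUP_INDEX",
]

TISSUE_GROUP_INDEX = 1.336  # water; reproduces the 4→3 μm and 2.86→2.14 mm pairs

# Default spectral span synthesized for the 170-nm FWHM source: generous
# wings so the Gaussian envelope is well contained.
DEFAULT_SPAN_NM = 300.0


@dataclass
class SpectralFrame:
    """One detected spectrum, sampled uniformly in wavelength.

    ``samples`` may be omitted at construction and synthesized later; the
    wavelength grid spans ``center ± span/2`` over ``n_pixels`` samples.
    """

    samples: np.ndarray | None = None
    center_wavelength_nm: float = 870.0
    bandwidth_fwhm_nm: float = 170.0
    n_pixels: int = 3072
    span_nm: float = DEFAULT_SPAN_NM

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")
        if not 0 < self.bandwidth_fwhm_nm < self.center_wavelength_nm:
            raise ValueError("bandwidth must be positive and below the centre wavelength")
        if self.samples is not None:
            self.samples = np.asarray(self.samples)
            if self.samples.shape != (self.n_pixels,):
                raise ValueError("samples must have shape (n_pixels,)")

    def wavelengths_nm(self) -> np.ndarray:
        half = self.span_nm / 2.0
        return np.linspace(
            self.center_wavelength_nm - half,
            self.center_wavelength_nm + half,
            self.n_pixels,
        )

    def wavenumbers_rad_per_um(self) -> np.ndarray:
        """k = 2π/λ on the (non-uniform) wavelength grid, in rad/μm."""
        return 2.0 * np.pi / (self.wavelengths_nm() * 1e-3)


@dataclass
class DispersionCoefficients:
    """Second/third-order spectral phase about the centre wavenumber.

    Units: ``a2`` in rad·μm², ``a3`` in rad·μm³ (phase = a2·Δk² + a3·Δk³
    with Δk in rad/μm).
    """

    a2: float = 0.0
    a3: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a2) and np.isfinite(self.a3)):
            raise ValueError("dispersion coefficients must be finite")

    def inverse(self) -> "DispersionCoefficients":
        return DispersionCoefficients(-self.a2, -self.a3)


class ReconstructedAScan(NamedTuple):
    intensity: np.ndarray
    axial_sampling_air_um: float
    dc_guard_px: int

    @property
    def axial_sampling_tissue_um(self) -> float:
        return self.axial_sampling_air_um / TISSUE_GROUP_INDEX


def gaussian_envelope(frame: SpectralFrame) -> np.ndarray:
    """Source power envelope on the frame's wavelength grid (peak 1)."""
    lam = frame.wavelengths_nm()
    sigma = frame.bandwidth_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((lam - frame.center_wavelength_nm) / sigma) ** 2)


def resample_to_wavenumber(frame: SpectralFrame) -> tuple[np.ndarray, np.ndarray]:
    """Resample a wavelength-uniform spectrum onto a uniform wavenumber grid.

    Returns ``(k_grid, spectrum)`` with the same number of samples, spanning
    the same band (cubic-spline interpolation).
    """
    if frame.samples is None:
        raise ValueError("frame has no samples")
    k = frame.wavenumbers_rad_per_um()
    order = np.argsort(k)
    k_sorted = k[order]
    if np.any(np.diff(k_sorted) <= 0):
        raise ValueError("wavelength grid must be strictly monotone")
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], frame.n_pixels)
    spline = CubicSpline(k_sorted, np.asarray(frame.samples)[order])
    return k_uniform, spline(k_uniform)


def apply_dispersion(
    k_grid: np.ndarray, spectrum: np.ndarray, coeffs: DispersionCoefficients
) -> np.ndarray:
    """Multiply a k-uniform spectrum by the dispersion phase.

    The magnitude spectrum (hence total energy) is unchanged.
    """
    k_grid = np.asarray(k_grid, dtype=np.float64)
    spectrum = np.asarray(spectrum)
    if k_grid.shape != spectrum.shape:
        raise ValueError("k grid and spectrum must have the same shape")
    dk = k_grid - 0.5 * (k_grid[0] + k_grid[-1])
    phase = coeffs.a2 * dk**2 + coeffs.a3 * dk**3
    return spectrum.astype(np.complex128) * np.exp(-1j * phase)


def reconstruct_ascan(
    frame: SpectralFrame,
    coeffs: DispersionCoefficients | None = None,
    n_fft: int = 4096,
    dc_guard_px: int = 8,
) -> ReconstructedAScan:
    """Reconstruct the intensity A-scan from one spectral frame.

    Pipeline: λ→k resampling, dispersion phase, zero-padding to ``n_fft``,
    FFT magnitude.  The first ``dc_guard_px`` pixels contain the DC /
    autocorrelation terms and are flagged for exclusion from peak analysis.
    """
    if n_fft < frame.n_pixels:
        raise ValueError("n_fft must be >= the number of spectral pixels")
    k_grid, spec = resample_to_wavenumber(frame)
    if coeffs is not None:
        spec = apply_dispersion(k_grid, spec, coeffs)
    delta_k = k_grid[1] - k_grid[0]
    padded = np.zeros(n_fft, dtype=np.complex128)
    padded[: frame.n_pixels] = spec
    ascan = np.abs(np.fft.fft(padded))
    sampling_air = np.pi / (n_fft * delta_k)  # μm of optical path per pixel
    return ReconstructedAScan(ascan, sampling_air, dc_guard_px)


def axial_sampling_um(range_tissue_mm: float, n_pixels: int) -> float:
    """μm of tissue depth per pixel: 1000 · range / n_pixels."""
    if range_tissue_mm <= 0 or n_pixels <= 0:
        raise ValueError("range and pixel count must be > 0")
    return 1000.0 * range_tissue_mm / n_pixels


def tissue_scale(value_air: float, group_index: float = TISSUE_GROUP_INDEX) -> float:
    """Convert an optical length in air to geometric length in tissue."""
    if value_air <= 0 or group_index <= 0:
        raise ValueError("inputs must be > 0")
    return value_air / group_index


def synthesize_reflector_frame(
    depths_tissue_um,
    amplitudes=None,
    frame: SpectralFrame | None = None,
    coeffs: DispersionCoefficients | None = None,
    group_index: float = TISSUE_GROUP_INDEX,
) -> SpectralFrame:
    """Synthesize the spectral fringes of point reflectors at given tissue
    depths (μm), with the frame's Gaussian source envelope, on the wavelength
    grid.  Optional ``coeffs`` adds an uncompensated dispersion phase."""
    if frame is None:
        frame = SpectralFrame()
    depths = np.atleast_1d(np.asarray(depths_tissue_um, dtype=np.float64))
    amps = np.ones_like(depths) if amplitudes is None else np.atleast_1d(amplitudes)
    k = frame.wavenumbers_rad_per_um()
    env = gaussian_envelope(frame)
    dk = k - 0.5 * (k[0] + k[-1])
    phase_extra = 0.0
    if coeffs is not None:
        phase_extra = coeffs.a2 * dk**2 + coeffs.a3 * dk**3
    samples = np.zeros(frame.n_pixels)
    for depth, amp in zip(depths, amps):
        z_opt = depth * group_index  # optical path in μm
        samples += amp * env * np.cos(2.0 * k * z_opt + phase_extra)
    return SpectralFrame(
        samples=samples,
        center_wavelength_nm=frame.center_wavelength_nm,
        bandwidth_fwhm_nm=frame.bandwidth_fwhm_nm,
        n_pixels=frame.n_pixels,
        span_nm=frame.span_nm,
    )
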