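"""Flash photometry: field geometry, Maxwellian-view Troland-seconds, and
rhodopsin bleach-fraction arithmetic.

In a Maxwellian-view illuminator the source is imaged inside the dilated
pupil, so all of the light enters the eye and the time-integrated retinal
illuminance Q (Td·s) follows from the luminous exposure and the solid angle
of the illuminated field alone, independent of pupil area.  The fraction of
rhodopsin bleached by a brief flash follows first-order photochemistry,
``F = 1 − exp(−Q/Q_e)`` with the classical human half-bleach constant
``Q_e ≈ 6.93 × 10⁶`` scotopic Td·s (so that Q_e·ln 2 bleaches 50%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FlashExposure",
    "field_solid_angle",
    "maxwellian_trolands",
    "bleach_fraction",
    "required_exposure",
    "HALF_BLEACH_CONSTANT_TD_S",
]

# Standard scotopic photosensitivity constant for human rhodopsin (Td·s).
HALF_BLEACH_CONSTANT_TD_S = 6.93e6


def field_solid_angle(theta_deg: float) -> float:
    """Solid angle (sr) of a circular field with full cone angle ``theta_deg``."""
    if not 0.0 < theta_deg < 180.0:
        raise ValueError("field angle must be in (0, 180) degrees")
    return 2.0 * math.pi * (1.0 - math.cos(math.radians(theta_deg) / 2.0))


def maxwellian_trolands(flux_lm_s: float, omega_sr: float) -> float:
    """Integrated retinal illuminance Q (Td·s) for a Maxwellian-view flash.

    ``flux_lm_s`` is the luminous exposure entering the eye (lm·s) and
    ``omega_sr`` the solid angle of the retinal field.  Q = 10⁶ · Φ / ω.
    """
    if flux_lm_s < 0:
        raise ValueError("flux must be >= 0")
    if omega_sr <= 0:
        raise ValueError("solid angle must be > 0")
    return 1.0e6 * flux_lm_s / omega_sr


def bleach_fraction(q_td_s: float, q_e: float = HALF_BLEACH_CONSTANT_TD_S) -> float:
    """Rhodopsin fraction bleached by an exposure of ``q_td_s`` Td·s."""
    if q_td_s < 0:
        raise ValueError("exposure must be >= 0")
    if q_e <= 0:
        raise ValueError("half-bleach constant must be > 0")
    return 1.0 - math.exp(-q_td_s / q_e)


def required_exposure(f: float, q_e: float = HALF_BLEACH_CONSTANT_TD_S) -> float:
    """Exposure (Td·s) needed to bleach fraction ``f`` of the rhodopsin."""
    if not 0.0 <= f < 1.0:
        raise ValueError("bleach fraction must be in [0, 1)")
    if q_e <= 0:
        raise ValueError("half-bleach constant must be > 0")
    return -q_e * math.log(1.0 - f)


@dataclass
class FlashExposure:
    """A bleaching flash: luminous exposure, field geometry, derived Q and F.

    ``efficiency`` labels the luminous-efficiency weighting of the measured
    flux; the bleach computation is meaningful for the scotopic value.
    """

    flux_lm_s: float
    field_angle_deg: float = 40.0
    duration_s: float = 0.0
    efficiency: str = "scotopic"
    q_e_td_s: float = HALF_BLEACH_CONSTANT_TD_S
    omega_sr: float = field(init=False)
    q_td_s: float = field(init=False)
    bleach_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        if self.flux_lm_s < 0 or self.duration_s < 0:
            raise ValueError("flux and duration must be >= 0")
        if self.efficiency not in ("scotopic", "photopic"):
            raise ValueError("efficiency must be 'scotopic' or 'photopic'")
        self.omega_sr = field_solid_angle(self.field_angle_deg)
        self.q_td_s = maxwellian_trolands(self.flux_lm_s, self.omega_sr)
        if self.efficiency == "scotopic":
            self.bleach_fraction = bleach_fraction(self.q_td_s, self.q_e_td_s)
        else:
            self.bleach_fraction = float("nan")
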