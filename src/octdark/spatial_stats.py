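"""Radial and time-course statistics for photoresponse maps and series.

Radial analysis averages a fovea-centred difference map over concentric,
non-overlapping rings of equal area (each equal to a 0.75-mm-radius circle,
so the n-th outer boundary is ``r_base·√n``), and fits the ring means with a
continuous piecewise-linear ("hinge") regression with a knot at 2 mm:
``y = β₀ + β₁·r + β₂·max(0, r − knot)`` — slope 1 is β₁, slope 2 is β₁+β₂.

Time courses are smoothed with least-squares cubic B-splines whose knots are
uniform in √t (denser early, matching the acquisition schedule), and
conditions are compared with a label-permutation test on the integrated
squared difference between condition-mean smoothed curves — a
distribution-free stand-in for mixed-model spline inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import LSQUnivariateSpline

from .core_io import DifferenceMap
from .photoresponse import PhotoresponseSeries

__all__ = [
    "RingProfile",
    "PiecewiseFit",
    "equal_area_rings",
    "ring_profile",
    "piecewise_fit",
    "smooth_curve",
    "permutation_curve_test",
    "PermutationResult",
]


@dataclass
class RingProfile:
    """One equal-area ring: boundaries, valid-pixel mean, pixel count."""

    index: int
    r_inner_mm: float
    r_outer_mm: float
    mean_diff_um: float
    n_pixels: int

    @property
    def valid(self) -> bool:
        return self.n_pixels > 0


@dataclass
class PiecewiseFit:
    """Continuous two-segment linear fit with a fixed knot."""

    intercept: float
    slope1: float            # μm/mm on [r_min, knot]
    slope2: float            # μm/mm on [knot, r_max]
    knot_mm: float
    slope1_se: float
    slope2_se: float
    residual_se: float

    def predict(self, r_mm) -> np.ndarray:
        r = np.asarray(r_mm, dtype=np.float64)
        return (
            self.intercept
            + self.slope1 * r
            + (self.slope2 - self.slope1) * np.maximum(0.0, r - self.knot_mm)
        )


def equal_area_rings(r_base_mm: float = 0.75, r_max_mm: float = 2.75) -> np.ndarray:
    """Ring boundaries ``[0, r_base, r_base·√2, …]`` out to ``r_max``.

    Every ring (and the central disc) has area ``π·r_base²``; the number of
    rings is ``⌊(r_max/r_base)²⌋``.
    """
    if r_base_mm <= 0 or r_max_mm <= 0:
        raise ValueError("radii must be > 0")
    n = int(np.floor((r_max_mm / r_base_mm) ** 2))
    return r_base_mm * np.sqrt(np.arange(n + 1, dtype=np.float64))


def ring_profile(diff: DifferenceMap, rings: np.ndarray) -> list[RingProfile]:
    """Valid-pixel mean of a fovea-centred map per equal-area ring.

    Pixel-centre inclusion with half-open intervals ``[r_{n−1}, r_n)``; an
    empty ring yields an invalid entry (NaN mean, zero count), not an error.
    """
    rings = np.asarray(rings, dtype=np.float64)
    if len(rings) < 2:
        raise ValueError("need at least one ring")
    r = diff.radius_mm()
    out = []
    for i in range(1, len(rings)):
        sel = (r >= rings[i - 1]) & (r < rings[i]) & diff.valid
        n = int(sel.sum())
        mean = float(diff.values_um[sel].mean()) if n else float("nan")
        out.append(
            RingProfile(
                index=i,
                r_inner_mm=float(rings[i - 1]),
                r_outer_mm=float(rings[i]),
                mean_diff_um=mean,
                n_pixels=n,
            )
        )
    return out


def piecewise_fit(radii_mm, values_um, knot_mm: float = 2.0) -> PiecewiseFit:
    """Least-squares continuous hinge regression of values on radius.

    Requires at least three points on each side of the knot; standard
    errors come from the usual linear-model covariance.
    """
    r = np.asarray(radii_mm, dtype=np.float64)
    y = np.asarray(values_um, dtype=np.float64)
    if r.shape != y.shape or r.ndim != 1:
        raise ValueError("radii and values must be matching 1-D arrays")
    if (r <= knot_mm).sum() < 3 or (r >= knot_mm).sum() < 3:
        raise ValueError("need >= 3 points on each side of the knot")
    design = np.column_stack([np.ones_like(r), r, np.maximum(0.0, r - knot_mm)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design (degenerate radii)")
    fit = sm.OLS(y, design).fit()
    beta = fit.params
    cov = fit.cov_params()
    slope2_var = cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]
    return PiecewiseFit(
        intercept=float(beta[0]),
        slope1=float(beta[1]),
        slope2=float(beta[1] + beta[2]),
        knot_mm=knot_mm,
        slope1_se=float(np.sqrt(cov[1, 1])),
        slope2_se=float(np.sqrt(max(slope2_var, 0.0))),
        residual_se=float(np.sqrt(fit.scale)),
    )


def _series_tx(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, PhotoresponseSeries):
        sel = series.times_s > 0
        return series.times_min()[sel], series.mean_diff_um[sel]
    t, y = series
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sel = t > 0
    return t[sel], y[sel]


def smooth_curve(
    series,
    df: int = 8,
    t_grid_min: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cubic B-spline smoothing of a post-flash time course.

    ``series`` is a :class:`PhotoresponseSeries` or a ``(t_min, y)`` pair;
    only t > 0 samples are fitted.  ``df`` is the number of basis functions
    (df − 4 interior knots, uniform in √t so the early rapid phase gets the
    denser knots).  Returns ``(t_grid_min, smoothed_values)``.
    """
    t, y = _series_tx(series)
    if df < 4:
        raise ValueError("df must be >= 4 for a cubic spline")
    if len(t) < df + 2:
        raise ValueError(f"need at least df+2={df + 2} points, got {len(t)}")
    order = np.argsort(t)
    t, y = t[order], y[order]
    n_interior = df - 4
    su = np.sqrt(t)
    interior = np.linspace(su[0], su[-1], n_interior + 2)[1:-1] ** 2 if n_interior else []
    spline = LSQUnivariateSpline(t, y, t=np.asarray(interior), k=3)
    if t_grid_min is None:
        t_grid_min = np.linspace(t[0], t[-1], 121)
    t_grid_min = np.asarray(t_grid_min, dtype=np.float64)
    return t_grid_min, spline(np.clip(t_grid_min, t[0], t[-1]))


@dataclass
class PermutationResult:
    statistic: float
    p_value: float
    n_perm: int
    null_statistics: np.ndarray


def permutation_curve_test(
    series_set_a: list,
    series_set_b: list,
    n_perm: int = 999,
    seed: int = 0,
    df: int = 8,
    n_grid: int = 121,
) -> PermutationResult:
    """Compare two conditions' photoresponse curves by permutation.

    Each session's series is spline-smoothed onto a common time grid; the
    statistic is the integrated squared difference between the two
    condition-mean curves.  The null distribution permutes condition labels
    across sessions; ``p = (1 + #{perm ≥ obs}) / (1 + n_perm)``.
    """
    if len(series_set_a) < 2 or len(series_set_b) < 2:
        raise ValueError("need at least 2 sessions per condition")
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for usable p-value resolution")
    pairs = [_series_tx(s) for s in list(series_set_a) + list(series_set_b)]
    t_lo = max(t.min() for t, _ in pairs)
    t_hi = min(t.max() for t, _ in pairs)
    if t_hi <= t_lo:
        raise ValueError("sessions share no common time range")
    grid = np.linspace(t_lo, t_hi, n_grid)
    curves = np.stack([smooth_curve(p, df=df, t_grid_min=grid)[1] for p in pairs])
    n_a = len(series_set_a)
    labels = np.zeros(len(pairs), dtype=bool)
    labels[:n_a] = True

    def stat(lab: np.ndarray) -> float:
        d = curves[lab].mean(axis=0) - curves[~lab].mean(axis=0)
        return float(np.trapezoid(d * d, grid))

    obs = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat(rng.permutation(labels))
    p = (1.0 + float((null >= obs).sum())) / (1.0 + n_perm)
    return PermutationResult(statistic=obs, p_value=p, n_perm=n_perm, null_statistics=null)
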