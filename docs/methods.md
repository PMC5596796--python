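# Methods

This note documents the models, parameters, and numerical choices behind
`octdark`, and what the phantom-based validation does and does not show.

## 1. Imaging geometry and units

Volumes are `[b, a, z]` arrays: `b` the slow (B-scan) axis, `a` the fast
(A-scan) axis, `z` depth increasing posteriorly.  Defaults follow the
modelled instrument: 6 × 6 mm scans of 400 × 400 A-scans (15 μm transverse
pitch, assumed isotropic), spectra of 3072 pixels zero-padded to 4096 depth
pixels giving 0.52 μm/pixel axial sampling in tissue, 3 μm axial resolution
in tissue (4 μm in air; group index 1.336, which also maps the 2.86-mm air
imaging range to 2.14 mm in tissue).  Public interfaces use mm (transverse,
origin at the volume centre or the fovea where stated) and μm (depth below
the EZ, positive posteriorly); the inferior retina is +y.

## 2. Spectral reconstruction

The spectrometer samples uniformly in wavelength; depth lives in the
Fourier domain of wavenumber.  Reconstruction is cubic-spline resampling
onto a uniform k grid spanning the same band, multiplication by a
second/third-order dispersion phase exp(−i[a₂Δk² + a₃Δk³]) about the centre
wavenumber (coefficients are inputs; the phase changes no magnitudes, so
spectral energy is conserved exactly), zero-padding, and an FFT magnitude.
One depth pixel is π/(n_fft·δk) μm of optical path.  The synthetic source
envelope is Gaussian (870 nm centre, 170 nm FWHM) over a 300-nm sampled
span; reflector fringes synthesized on that grid alias beyond ≈ 0.47 mm of
tissue depth at 1024 spectral pixels, so reconstruction tests place targets
inside that range (the native 3072-pixel frame triples it).

## 3. Phantom

### 3.1 Anatomy

Band depths below the EZ taper linearly from the fovea to 3 mm eccentricity
and are constant beyond: CIZ 32→22 μm, RPE 50→42 μm, BM 62→56 μm, RIZ
midway between CIZ and RPE and absent inside 0.5 mm (the foveal rod-free
zone).  The EZ itself sits 140 μm below the volume top with a 10-μm
posterior bowl.  Relative band reflectances: EZ 1.0, CIZ 0.55, RIZ 0.45,
RPE 0.8, BM 0.5 over a 0.05 background.  Each A-scan is a sum of Gaussian
axial peaks (FWHM = the 3-μm tissue resolution) at these depths.  These
values are configuration, chosen to reproduce the qualitative appearance of
ultrahigh-resolution outer-retina B-scans; they are not fits to any
measured reflectance.

### 3.2 Photoresponse kinetics

No closed-form kinetics exist for these responses in the literature the
package models, so the phantom uses minimal smooth forms that satisfy the
reported timing and scaling phenomenology (t in minutes after flash offset,
zero for t ≤ 0 and for F = 0):

* cone (added to CIZ depth): Δ(t) = A_c·e^(−t/τ_c), τ_c = 1.5 min — decays
  below 5% of peak by 5 min;
* rod (added to RIZ depth): Δ(t) = A_r·(t/t_p)^κ·e^(κ(1−t/t_p)), κ = 2,
  t_p(F) = 4 + 3F min — unit peak exactly at t_p, in 5–7 min for the
  bleaches studied;
* RPE/BM (added identically to both): Δ(t) = A_o·[g(t; 3, 2) −
  0.3·g(t; 12, 4)] with g the same normalized pulse — peak ≈ 3 min,
  undershoot trough ≈ 12–13 min.  Because the two pulses' exponential decay
  rates satisfy κ₁/t₁ > κ₂/t₂, their ratio is strictly monotone and the
  waveform has **exactly one** zero crossing on (0, 30] for any positive
  undershoot fraction.  A damped sinusoid was rejected for this role: it
  recrosses zero every half period, which would make "the response
  undershoots once" untestable against noise.

Amplitudes scale with bleach fraction as A(F) = A·F^p with
p = ln 2 / ln(16/9) ≈ 1.204, so the maximal response after a 96% bleach is
exactly twice that after a 54% bleach — the scaling the study design is
built around.  Defaults A_c = 1.05, A_r = 0.8, A_o = 0.9 μm (values at
F = 1) put responses at realistic sub-micron magnitudes; they are injected
parameters to be recovered, not measured constants.

The half-field exposure mask is 1 on the inferior side of a horizontal
boundary through the fovea, 0 on the superior side, with a cubic smoothstep
over a 0.2-mm transition (optical blur at the retina); it is exactly 0/1
outside the ramp so "no increment in the unexposed hemifield" is a strict
statement.  A two-branch dark-adaptometry threshold curve (fast cone
exponential, delayed rod branch, upper envelope, √F amplitude scaling) is
provided for comparison plots only.

### 3.3 Noise

Speckle is a unit-mean multiplicative field: per-voxel Gamma(L, 1/L) with
L = 4 looks, smoothed transversely with a 0.75-pixel Gaussian to give the
speckle a transverse grain (filtering preserves the mean; the Monte-Carlo
mean test verifies E[I] equals the noise-free intensity including the
additive pedestal of 0.02).  Axial eye motion is a per-B-scan random walk
(step σ = 1 pixel by default) added to every surface.  Noise and rendering
are confined to the axial window containing the retina; outside it the
volume is the constant pedestal.

What the phantom does **not** emulate: cone-mosaic structure, vascular
shadows, transverse eye motion and torsion, rolloff/defocus with depth,
multiple scattering, and session-to-session biological variability.
Passing recovery tests therefore demonstrates the correctness of the
*pipeline machinery* under realistic speckle and axial motion, not clinical
performance on patient data.

## 4. Segmentation

The EZ cost image scores each depth by its log-intensity minus the mean
log-intensity of a 5-pixel window starting 6 pixels above it; the positive
part is normalized and inverted to [0, 1].  For a symmetric peak over dark
background the response is maximized at the peak centre (the gap clears the
peak flank); for a dark-to-bright step it plateaus from the edge on, and
the smallest-depth tie-break pins the path to the edge.  The surface is the
minimum-cost left-to-right path with per-column |Δz| ≤ 2 pixels, found by
dynamic programming over the column DAG (equivalent to the single-surface
graph cut with a step bound; verified against exhaustive enumeration on 8×8
grids), then refined to subpixel by a 3-point parabola on the
linear-intensity peak within ±7 pixels.  On deep volumes the search is
restricted to a window anchored at the first strong rise of the volume-mean
log profile (60 above, 120 below) — the anterior edge of the
outer-retina complex — which is robust to whichever band is brightest.
Flattening shifts each A-scan by linear interpolation so the EZ sits at a
common index (48 by default); B-scan alignment removes residual per-B-scan
offsets by cross-correlation of mean profiles.

## 5. Band detection

On the flattened, C-scan-filtered (σ = 2 A-scans, reflective boundaries,
linear intensity) volume, candidate peaks below the EZ are local maxima
within the union of the band windows (CIZ [15, 40], RIZ [30, 55],
RPE [40, 65], BM [55, 85] μm below the EZ; configurable).  Candidate
prominence is height above the per-A-scan floor of the search range;
candidates under 10% of the strongest RPE-window candidate are rejected.
Two algorithmic safeguards matter in speckle:

* **minimum band separation** (6 μm ≈ 2× the axial resolution): residual
  speckle ripple can split one band into two local maxima ~1 μm apart, and
  without suppression the assignment can harvest both by shifting every
  label one slot;
* **positional tie-break**: when a band's true peak drops below the
  prominence threshold, the correct assignment and the one-slot label shift
  have *exactly equal* total prominence.  The assignment score is therefore
  prominence minus 1% of the reference height times the candidate's
  normalized distance from its band-window centre — large enough to break
  ties toward anatomically plausible positions, far too small to override
  any real prominence difference.

Peaks are assigned to the ordered bands (CIZ < RIZ < RPE < BM, each inside
its window, bands may stay unassigned) by a sequence-alignment dynamic
program maximizing that score, verified against brute-force enumeration.
Subpixel refinement is the same 3-point parabola (exact for quadratic
peaks; ≤ 0.05 pixel bias for Gaussian peaks at 0.52 μm sampling).  A-scans
with fewer than two candidates are invalid; missing bands (the foveal RIZ)
stay invalid rather than extrapolated.  In maps, invalid holes of ≤ 2
pixels are median-filled from valid 3×3 neighbours.  The batched
(volume-level) implementation is tested for equality with the per-A-scan
reference path.

## 6. Photoresponse extraction

The baseline is the pixelwise mean of the (three) pre-flash maps, valid
where a strict majority is valid.  The fovea is the argmax of the
0.25-mm-smoothed CIZ thickness map in the central 2 × 2 mm, refined by the
centroid of the top-5% region (the cone band is thickest at the foveal
centre).  All maps of a session are aligned to the **baseline** fovea by
translation; per-time-point fovea tracking is available (`track_fovea`) but
off by default, because a half-field response elevates the CIZ map
asymmetrically and drags a per-map tracker ~0.3 mm toward the exposed side,
corrupting hemifield means — with no transverse drift in the phantom,
baseline alignment is exact.  Differences use bilinear shifting with
validity weighting; display smoothing (σ = 9 A-scans) is normalized
convolution so invalid regions neither give nor receive weight.  ROI means
are computed on *unsmoothed* differences (smoothing is for maps and
figures): CIZ 3-mm circle, RIZ 1.5–5.5-mm annulus, RPE/BM 5.5-mm circle,
pixel-centre inclusion with boundary ties inside, hemifields split strictly
at the fovea row.  Volumes whose EZ surface jitters > 5 px RMS about its
smooth trend after alignment are dropped (motion QC; the threshold is a
configuration choice — the protocol this mirrors excluded motion-artifact
volumes without stating a criterion).

## 7. Radial and time-course statistics

Equal-area ring boundaries are rₙ = r_base·√n (r_base = 0.75 mm), giving
13 rings to 2.75 mm; rings are half-open [rₙ₋₁, rₙ) so pixels are counted
once.  The radial trend is fit by continuous hinge regression
y = β₀ + β₁r + β₂·max(0, r − 2 mm) via ordinary least squares (slope 2 =
β₁ + β₂, its SE from the coefficient covariance).  The mixed-effects
(random-subject) variant is deliberately not implemented: at the scale of a
handful of sessions the pooled fixed-effects slopes are the quantities of
interest.  Time courses are smoothed by least-squares cubic B-splines with
df = 8 basis functions and interior knots uniform in √t, matching the
sampling schedule (20-s spacing early, 60-s late).

Condition comparison replaces generalized-mixed-model spline inference with
a **label-permutation test**: each session's post-flash series is smoothed
onto a common grid, the statistic is ∫(mean_A − mean_B)² dt, the null is
built by permuting condition labels across sessions, and
p = (1 + #{perm ≥ obs})/(1 + n_perm).  This is distribution-free, exactly
specified, and testable by Monte-Carlo.  Calibration note: with 4 sessions
per arm only 35 distinct partitions exist and randomly sampled permutations
frequently re-draw the observed split, making the test visibly conservative
(measured type-I ≈ 1% at α = 0.05); the calibration experiments therefore
use 6 sessions per arm (924 splits), where the measured type-I error is
4–8% and power at a 0.45-μm rod-shaped effect (3× the 0.15-μm noise floor,
per-point σ = 0.05 μm) exceeds 90%.

## 8. Photometry

Field solid angle ω = 2π(1 − cos θ/2); in Maxwellian view all flash light
enters the dilated pupil, so the integrated retinal illuminance is
Q = 10⁶·Φ/ω Td·s independent of pupil area.  Bleaching follows first-order
photochemistry F = 1 − exp(−Q/Q_e) with the classical human scotopic
constant Q_e = 6.93×10⁶ Td·s (both configurable); `required_exposure` is
the exact inverse.  Photopic-weighted exposures carry a label and no bleach
value.

## 9. Problem sizes and reproducibility

The validation study processes four conditions (96%, 54%, 0% full-field,
54% inferior half-field) on the full 43-volume schedule; the test suite
runs it at 200 × 200 A-scans × 1024 depth pixels, and
`scripts/acceptance.py` at 160 × 160 × 1024 — both comfortably resolve
sub-0.05-μm ROI-mean noise floors because each ROI averages thousands of
A-scans.  All randomness flows from a single seed per run (per-volume
streams are spawned deterministically from the session seed), so any
reported number is reproducible bit-for-bit from its seed.

## 10. Known limitations

* The pipeline assumes one dominant bright complex (the outer retina) per
  A-scan; pathology that disrupts band ordering or creates competing bright
  complexes would defeat the window-based assignment.
* Transverse registration is translation-only to the fovea; rotation,
  scale, and vascular-landmark registration are out of scope.
* The EZ cost function is a re-derivation of a graph-based single-surface
  segmenter, not a port of any published implementation's weights.
* Phantom realism limits are listed in §3.3; in particular, recovery
  accuracy on the phantom is an upper bound on what identical settings
  would achieve on real data.
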