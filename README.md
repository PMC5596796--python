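# octdark

Analysis pipeline for **outer-retinal-band photoresponses in dark-adaptation
OCT**: from (synthetic) spectral-domain OCT volumes of the human retina,
segment the ellipsoid zone (EZ, the IS/OS junction), detect the four
hyperreflective bands below it — cone interdigitation zone (CIZ/COST), rod
interdigitation zone (RIZ/ROST), apical RPE, and Bruch's membrane (BM) —
and track their thickness relative to the EZ over a 30-minute dark-adaptation
time course after a rhodopsin-bleaching flash.

After a flash that bleaches a fraction *F* of the rhodopsin, three distinct
photoresponses appear in the band thicknesses:

* **cone** (EZ–CIZ): an immediate elongation that recovers to baseline in
  under 5 minutes;
* **rod** (EZ–RIZ): a slow elongation peaking 5–7 minutes after the flash;
* **RPE/BM** (EZ–RPE ≈ EZ–BM): a biphasic response peaking ~3 minutes after
  the flash and undershooting baseline at 10–15 minutes.

Their maximal amplitudes double from a 54% to a 96% bleach, and a half-field
exposure confines them to the exposed hemiretina.  The package is aimed at
researchers building or validating OCT-based dark-adaptometry pipelines: no
human data ship with it; instead a **phantom module** generates volumes with
known injected kinetics so every processing stage is verifiable by parameter
recovery.

## What is inside

| module | contents |
| --- | --- |
| `octdark.core_io` | `OCTVolume`/`ThicknessMap` containers, TIFF+JSON and CSV I/O, YAML pipeline configuration |
| `octdark.reconstruction` | λ→k resampling, dispersion compensation, zero-padded FFT A-scan reconstruction, axial-sampling arithmetic |
| `octdark.phantom` | layered outer-retina renderer: eccentricity-dependent band depths, bleach-graded kinetics, speckle, axial motion, exposure masks |
| `octdark.segmentation` | EZ segmentation (min-cost DP path with step constraint), flattening, B-scan alignment |
| `octdark.bands` | C-scan transverse Gaussian filtering, ordered four-band peak detection (assignment DP + subpixel parabola), thickness maps |
| `octdark.photoresponse` | baseline averaging, fovea finding, difference maps, ROI/hemifield means, session time series |
| `octdark.spatial_stats` | equal-area radial rings, knotted piecewise-linear (hinge) regression, B-spline curve smoothing, permutation curve test |
| `octdark.photometry` | field solid angle, Maxwellian-view Troland-seconds, rhodopsin bleach-fraction arithmetic |
| `octdark.evaluation` | standard phantom study (96%/54%/0% full-field + 54% half-field) with parameter-recovery metrics |

A `click` CLI exposes the pipeline as `octdark simulate | reconstruct |
segment | bands | respond | stats | photometry`.

## The measurement model in brief

Thickness of band *X* at transverse position (x, y) is the depth of its
intensity peak below the EZ after flattening, detected on C-scan-filtered
linear intensity (2-D transverse Gaussian, σ = 2 A-scans) and refined to
subpixel with δ = ½(I₋ − I₊)/(I₋ − 2I₀ + I₊).  Photoresponses are
ROI-averaged differences from the mean of three dark baselines: CIZ over a
3-mm-diameter foveal circle, RIZ over a 1.5–5.5-mm annulus, RPE/BM over a
5.5-mm circle, optionally split into inferior/superior hemifields.  Radial
structure is summarized over concentric equal-area rings (boundaries
rₙ = 0.75·√n mm) with a continuous hinge regression
y = β₀ + β₁·r + β₂·max(0, r − 2 mm); conditions are compared by a
label-permutation test on the integrated squared difference between
spline-smoothed condition means.  Bleach fractions follow first-order
photochemistry F = 1 − exp(−Q/Qₑ) with Qₑ = 6.93×10⁶ scotopic Td·s.

## Worked example

```python
import octdark as od
from octdark import phantom as ph

# photometry: flash flux -> retinal exposure -> bleach fraction
exp = od.FlashExposure(flux_lm_s=2.0, field_angle_deg=40.0, duration_s=0.2)
print(f"Q = {exp.q_td_s:.3g} Td*s  ->  F = {exp.bleach_fraction:.2f}")

# phantom session: 3 dark baselines + two post-flash volumes at 20 and 40 s
# after a 96% full-field bleach, processed blind end to end
grid = ph.ScanGrid(n_bscans=120, n_ascans=120, n_depth=768)
sched = od.AcquisitionSchedule(fast_window_s=40.0, total_s=40.0)
field = ph.ExposureField(mode="full", bleach_fraction=0.96)
session = ph.simulate_session(ph.RetinaModel(), ph.PhotoresponseKinetics(),
                              field, sched, ph.NoiseModel(), grid, seed=0)
result = od.process_session(session, od.PipelineConfig())
for band in ("CIZ", "RIZ", "RPE", "BM"):
    s = result.get(band)
    for t, d in zip(s.times_s, s.mean_diff_um):
        print(f"{band}  t={t:5.0f} s   mean diff = {d:+.3f} um")
```

Output:

```
Q = 5.28e+06 Td*s  ->  F = 0.53
CIZ  t=   20 s   mean diff = +0.803 um
CIZ  t=   40 s   mean diff = +0.682 um
RIZ  t=   20 s   mean diff = +0.035 um
RIZ  t=   40 s   mean diff = +0.064 um
RPE  t=   20 s   mean diff = +0.083 um
RPE  t=   40 s   mean diff = +0.212 um
BM  t=   20 s   mean diff = +0.065 um
BM  t=   40 s   mean diff = +0.213 um
```

Reading it: the cone band has already elongated by ~0.8 μm at the first
post-flash volume and is visibly decaying by 40 s (time constant 1.5 min);
the rod band is still near baseline (its peak comes at ~7 min); the RPE and
BM move together, rising toward their ~3-minute peak.  With default
phantom kinetics the injected cone amplitude at F = 0.96 is 1.0 μm, so the
20-s sample at exp(−⅓/1.5) ≈ 0.80 of peak is recovered almost exactly.

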