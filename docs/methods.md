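# Methods

## Scope and model

`petharm` studies how a change of PET harmonisation standard — from an older
specification ("EARL1") to an updated one admitting resolution-recovered
reconstructions ("EARL2") — shifts quantitative lesion metrics, and whether a
Gaussian post-filter applied to the sharper images restores old-standard
reads. Vendor reconstruction is **emulated, not modelled**: the two standards
differ only in effective isotropic Gaussian resolution. An "EARL2-like" image
is the ideal activity distribution convolved with a Gaussian PSF of 5 mm
FWHM; an "EARL1-like" image uses √(5² + 7²) ≈ 8.6 mm. Because Gaussian widths
add in quadrature, a 7 mm post-filter is, by construction, the bridge between
the two — the pipeline's task is to *recover* that value from phantom
measurements and to *verify* metric equivalence on a cohort — the same logic
a harmonisation programme applies to real scanners whose PSFs are unknown.

### Coordinates and grids

Arrays are `(z, y, x)`; spacing and origin are in mm; the origin is the
center of voxel `(0,0,0)`; world position of voxel `(i,j,k)` is
`origin + index·spacing`. All masks live on their image's grid. The default
grid is 4 mm isotropic, matching the reconstruction grid of the emulated
study.

### Gaussian filtering

`gaussian_postfilter` applies the exact Gaussian transfer function
`exp(−2π²σ²f²)` in the frequency domain (σ = FWHM / (2√(2 ln 2)), per axis in
world units). This choice is deliberate: at 4 mm voxels a 5 mm FWHM kernel
has σ ≈ 0.53 voxel, and spatially sampled kernels then violate quadrature
composition by ~0.3–0.5% (aliasing), which would masquerade as a systematic
difference between an EARL1-like rendering and "EARL2 ⊛ 7 mm". The spectral
filter composes to machine precision, conserves total activity exactly (unit
DC gain), and its effective spatial kernel — the periodised Gaussian — is
strictly positive, so maxima never increase. Boundary handling is periodic;
simulated bodies have quiet borders, so wrap-around is negligible. The
impulse response agrees with the analytic sampled Gaussian to ~1e-11 at
σ = 2 voxels (tested).

### Fractional-voxel geometry

Sphere masks weight each voxel by the fraction of its volume inside the
sphere, estimated by a regular 5×5×5 subvoxel grid (documented constant;
analytic overlap would be unnecessary precision at 4 mm voxels). The 1.2-cm
SUVpeak sphere's volume is reproduced within 1% of the analytic 0.9048 ml.
The phantom body outline (elliptical cylinder) uses an exact 1-D slab overlap
along z times a ≥25×25-point 2-D ellipse sampling — the body cross-section
dominates the total-activity budget, and coarse sampling there biased the
total by ~0.5%.

### SUVpeak

Candidate sphere centers are the voxel centers with tumor weight > 0
(continuous placement is deliberately not attempted); the reported SUVpeak is
the maximum fractional-weighted 1.2-cm-sphere mean over all candidates. Peak
spheres clipped by the image boundary are renormalised to in-bounds weights.
The implementation is an exhaustive search with bounding-window arithmetic;
it agrees with an independent full-grid brute-force oracle to ≤1 ulp on
hundreds of random fixtures.

## Synthetic data

### Phantom

NEMA NU2-2007 IQ body phantom: six zero-wall spheres (10, 13, 17, 22, 28,
37 mm) on a 57 mm ring in the central slice, background 2 kBq/ml, spheres
20 kBq/ml (10:1), body 300×220 mm elliptical cross-section, 140 mm long.
Noise is stationary Gaussian, smoothed with the same PSF and rescaled to
`noise_sd_fraction × background` — a pragmatic stand-in for reconstruction
noise (Poisson projection noise is out of scope). Noise-free and unblurred,
the measured sphere-to-background ratio is exactly 10 and total activity
matches the analytic geometry to <0.1%.

### Cohort

Two arms (13 lung-cancer-like, 17 lymphoma-like subjects; lesion-count
distributions tuned to means of 1.5 and 2.1 lesions/subject, capped at 3).
Each subject is an elliptical-cylinder torso at background SUV 1.0 with a
liver-like ellipsoid (SUV 2.5), an aorta-like cylinder (blood pool, SUV 2.0),
and spherical lesions of uniform uptake: diameters uniform in 12–38 mm
(spanning the <10 ml / ≥10 ml volume strata) and SUV uniform in 4.5–14
(spanning the ≤7 / >7 contrast strata). Lesions are placed away from the
reference organs and each other, and their centers are **snapped to voxel
centers** so the recorded seed voxel is the exact lesion center and
partial-volume behaviour is not confounded by sub-voxel placement (at 4 mm
voxels an off-grid center alone can depress SUVmax by several percent).
Reference VOIs: 3-cm liver sphere at the liver center, 1.5-cm blood-pool
sphere inside the aorta lumen.

Per subject, the EARL2-like image gets smoothed noise with standard
deviation 8% of background SUV; the EARL1-like image is rendered from the
ideal object at the quadrature-widened PSF with **independent** noise. With
the `exact_match` flag the EARL1-like image is instead the EARL2-like image
(noise included) filtered with the extra 7 mm — the construction under which
downstream pipeline equivalence is exact and used as such in tests.

What the generator does *not* emulate: heterogeneous lesion texture,
non-stationary or Poisson noise, Gibbs overshoot of resolution-recovery
reconstruction, attenuation/scatter artefacts, respiratory motion, and
inter-scanner variation beyond a configurable PSF spread. Passing tests
therefore demonstrate the pipeline's internal correctness and the direction
of standard-change effects under an idealised imaging model — not clinical
effect magnitudes, which depend on the real lesion-size mix and
reconstruction physics (the synthetic SUVmax shifts, for instance, are
smaller than clinical reports because pure Gaussian blur lacks
resolution-recovery overshoot).

## Phantom analysis

RCmax is the hottest voxel within 1.5 sphere radii of the known center ÷
true concentration (tolerating small offsets). RCmean uses a
background-corrected 50% isocontour: threshold `bg + 0.5·(max − bg)`, with
`bg` the mean in a 15–25 mm shell outside the sphere surface (other spheres
excluded), grown 26-connected from the hottest voxel — an SOP-style stand-in,
since the accreditation tooling's exact delineation is not public.
Specification bands are inclusive per-sphere `[min, max]` limits for both RC
flavours; compliance requires all spheres to pass both. The shipped
`synthetic_band` (reference phantom RCs ± 10%, the same magnitude as the
programme's SUV-bias tolerance) is a labelled synthetic stand-in for the
published limits, which are user-supplied configuration. `select_filter`
reports the full histogram and the argmax *set* (ties are preserved).

## Lesion quantification

All three VOI methods grow 26-connected regions with inclusive (≥)
thresholds:

* **SUV4** — absolute SUV ≥ 4.0; seeds below threshold raise a distinct
  "not quantifiable" error, recorded as a NaN row by the workflows.
* **MAX41** — ≥ 41% of SUVmax, with SUVmax resolved by fixed-point iteration
  from the seed neighbourhood's maximum (the point iterated is whether SUVmax
  is global or region-restricted, which the method description leaves open);
  the maximum is non-decreasing so the iteration terminates (cap 50).
* **A50P** — ≥ `BG + 0.5·(SUVpeak − BG)`, SUVpeak computed on the provisional
  region, BG the mean in a 2-voxel-thick shell starting 2 voxels outside it,
  iterated to a mask fixed point (cap 50); no contrast (peak ≤ BG, or a
  flooded region with no shell) raises "not quantifiable".

MATV is binary voxel counting (fractional weights are used only for
sphere-defined VOIs: SUVpeak, liver, blood pool); TLG = MATV × SUVmean
exactly by construction.

## Statistics

Relative differences are `100·(x − x_EARL1)/x_EARL1`; summaries report
medians and 25th/75th percentiles (numpy's default linear, i.e. type-7,
interpolation), per VOI method × metric × reconstruction × arm × stratum,
with strata on the lesion's baseline values (MATV < / ≥ 10 ml,
SUVmean ≤ / > 7). Paired contrasts use the Wilcoxon signed-rank test; group
contrasts use Mann–Whitney U (the conventional pairing of tests to paired
and independent data). Zero differences follow the Pratt convention (ranked,
then dropped from the statistic). For ≤12 nonzero pairs (or ≤12 pooled
observations) the exact conditional permutation null is enumerated, with
midranks for ties and the doubled-tail two-sided convention
`p = min(1, 2·min(P(T≤t), P(T≥t)))`; larger samples use scipy's
tie-corrected normal approximations. All-zero difference vectors return
p = 1 with a warning. No multiple-testing correction is applied (matching
the comparison design). Significance is flagged at p < 0.05.

## Problem sizes and determinism

Default problem sizes: 40×60×80 phantom grid and 52×56×72 cohort grid at
4 mm voxels; 5 phantom datasets in the selection workflow; 30 subjects
(~54 lesions) in the cohort. A fine 2 mm phantom grid is used where a test
needs every sphere to contain a fully-interior voxel. All randomness flows
through explicit integer seeds (`numpy.random.default_rng` /
`SeedSequence.spawn` per subject); identical config + seed reproduces
byte-identical outputs, and output tables carry config-hash, seed and
version provenance columns.

## Known limitations

* The emulation cannot reproduce clinical effect magnitudes (no
  resolution-recovery overshoot; uniform spherical lesions), only their
  directions and orderings.
* RCmean delineation and the A50P iteration scheme are declared
  interpretations of practice, not vendor-exact reimplementations.
* Periodic filter boundaries assume quiet image borders.
* DICOM support is read-only and limited to single-frame series with
  rescale tags.
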