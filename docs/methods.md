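# Methods

This note documents the models, conventions and numerical choices behind
goniohcrf, and what the synthetic tests do and do not establish about
real field data.

## Reflectance chain

The measured quantity is the hemispherical conical reflectance factor
(HCRF): the target is illuminated by the whole sky hemisphere and viewed
through a finite cone (8.5° IFOV), so neither the illumination nor the
observation is truly directional.  The chain estimates it as

    HCRF(λ) = L_r(λ; t_x) / ( L_ref(λ; t_0) · c_diff(λ; t_x) · c_ref(λ, θ_i) ).

Assumptions, in decreasing order of importance:

1. **Shared illumination.** Panel and target see the same irradiance at
   any instant; radiance of a surface with reflectance factor R is
   R·E/π.  Direct and diffuse illumination are not separated, so the
   output is HCRF, not HDRF or BRF; no conversion to BRDF is attempted.
2. **Spectrally proportional drift.** Irradiance changes between t_0 and
   t_x act multiplicatively on the panel radiance in each wavelength
   region, so the per-wavelength ratio c_diff = E(t_x)/E(t_0) from the
   second (cosine-receptor) radiometer transfers the panel measurement
   through time.  For purely multiplicative drift this cancellation is
   an algebraic identity; spectrally selective changes (e.g. changing
   water vapour) violate the assumption and are exactly what the drift
   indicator is designed to flag.
3. **Panel non-Lambertian response.** A real Spectralon panel viewed at
   nadir returns slightly less than its 8°-geometry calibration value,
   increasingly so at large sun zenith.  Because the chain *divides* by
   the correction term, `PanelCalibration.r_ref` is stored in
   reciprocal form (1/panel-reflectance, ≈1.008 for a 99 % panel) and
   `c_ref(λ, θ_i)` extends it with the sun-zenith dependence.  The
   published correction coefficients for this effect are not
   redistributable here, so the correction is pluggable: an identity
   built-in (r_ref only), a user-supplied table, and a synthetic table
   (in `synthetic.synthetic_panel_calibration`, clearly labelled
   synthetic) whose slope (−3×10⁻⁴ per degree of sun zenith) mimics the
   published magnitude.  Disabling the anisotropy correction on the
   simulator's output leaves a ~1.2 % systematic at θ_i = 47°, which is
   the realistic cost of ignoring the effect.

Two panel measurements bracket a session.  Following the estimator's
definition the chain anchors on the start panel; the end panel is
reserved for the session consistency score (below).  HCRF values above 1
are physical (backscatter) and never clipped; smoothing is never applied
implicitly.

### Anisotropy summaries

ANIF divides each position's HCRF by the nadir HCRF per wavelength
(nadir row ≡ 1 by construction).  ANIX is max/min HCRF over an azimuth
plane, per wavelength; a plane is the set of positions within ±7.5° of
either of two opposite azimuths, plus nadir, which belongs to every
plane (7.5° is half the smallest default ring spacing, so each plane
captures exactly one azimuth column per side).  Region summaries use
visible = 400–700 nm and NIR = 700–1050 nm (grid-limited).  Angular NDVI
uses band-averaged HCRF over ±5 nm windows at 672 and 864 nm by default.

### Drift indicator

The per-position indicator is |mean_λ c_diff(t_x) − 1|: the broadband
magnitude of the temporal interpolation the HCRF at that position relied
on.  Positions above a 2 % threshold (configurable) are flagged
"caution".  The session score predicts the end panel from the start
panel and c_diff(t_end) and reports the broadband relative mismatch with
the measured end panel; it is exactly 0 for spectrally uniform
multiplicative drift and grows with spectrally selective change.  The
exact functional form of this indicator is an engineering choice, not a
reconstruction of any particular instrument's software.

## Geometry

* **Scheme.** Nadir + 12 azimuths at 5° + 16 each at 10°, 20°, 30° view
  zenith (61 positions).  Azimuths are principal-plane referenced (0° =
  backward scatter) and symmetric, containing the principal and
  orthogonal planes with spacing tightened toward 0°/180°; the exact
  angle lists are a configurable convention — the tested constraints are
  the counts, the ring zeniths and plane membership.
* **Ephemeris.** The low-precision Astronomical Almanac algorithm
  (Michalsky 1988), ~0.01° accuracy over 1950–2050, refraction off.  The
  test suite cross-checks 1,000 random (lat, lon, time) draws against an
  independently implemented second algorithm (PSA, Blanco-Muriel et al.
  2001) with a 0.1° gate.  All timestamps carry explicit UTC offsets;
  computation is in UTC.
* **Principal-plane correction.** The scheme is aligned with the solar
  principal plane at the session start; each ring's correction offset is
  the solar azimuth change accumulated by that ring's start time.  For
  the Arctic case-study session (69°40′28″N, 148°43′15″W, 13:48 local,
  25 min) the cumulative change is 7.85° ≈ 8°.  Note the printed session
  azimuth of 180° corresponds to apparent solar noon, which falls at the
  session midpoint; at 13:48 sharp the azimuth is 176°.
* **Footprint.** Edge-ray construction: sensor at slant distance d along
  the view direction (d = 2.02 m fixed by the arc; height above ground
  d·cosθ), cone of half-angle IFOV/2 intersected with the ground plane.
  Major extent = distance between the ground hits of the rays at
  θ ± IFOV/2; the cross-track extent has the closed form
  2·h·sin(α)·sinψ*/(cosα·cosθ − sinα·cosψ*·sinθ) with
  cosψ* = tanα·tanθ.  Both axes are reported as *full* extents: at
  d = 2.02 m and IFOV 8.5° this gives 30.0 cm at nadir and 34.8 cm at
  30°, which is the only reading consistent with both published numbers.
* **Hot spot.** Reachable iff the minimum sun zenith is within the 30°
  view-zenith range.  A year-long 5-minute ephemeris sweep at the Arctic
  circle gives a minimum of 43.1° (≈ latitude − obliquity), so the
  hot-spot geometry is never reachable there.

## Synthetic sessions

The generator emulates the acquisition sequence exactly: start panel
(nadir), 61 targets in scheme order, end panel, one irradiance spectrum
per radiance acquisition (63), at a 17 s cadence (≈18 min per
hemisphere).  Defaults, with units and origin:

| parameter | default | meaning |
|---|---|---|
| base spectrum | vegetation-like | chlorophyll wells, green bump, red edge at ~716 nm, NIR plateau ≈0.36, 970 nm water dip |
| backscatter strength B | 0.30 visible / 0.08 NIR | linear-in-θ·cos(φ) backward term of the angular kernel |
| bowl darkening D | 0.12 visible / 0.05 NIR | quadratic-in-θ falloff |
| drift rate | 0.002 min⁻¹ | smooth multiplicative irradiance trend (~3.6 % per session); optional step events |
| noise_sd | 0.005 | multiplicative Gaussian per channel, bracketing the instrument's 0.20–1.59 % reflectance uncertainty |
| pointing_jitter_sd | 0.03 m | ground-plane jitter of the footprint centre; ±6 cm ≈ 2σ envelope |
| pp_misalignment_sd | 1.75° | compass uncertainty of the principal-plane alignment |

The angular kernel k = 1 + B·(θ/30)·cosφ − D·(θ/30)² is a smooth test
fixture reproducing the qualitative anisotropy of low vegetation
(brighter backward, darker forward, stronger in the visible where
absorption suppresses multiple scattering); it is **not** a canopy
radiative-transfer model.  Consequences: passing recovery tests shows
the chain's algebra and drift correction are correct, not that any real
canopy follows this kernel.  Real data additionally contain spectrally
selective atmospheric change, wind-moved canopies, spatial heterogeneity
inside the footprint, and hot-spot physics, none of which the generator
produces.

Pointing jitter is mapped to an effective view direction by displacing
the viewed ground point and recomputing the sensor→point direction; on
the spatially homogeneous scene its only effect is this small angular
perturbation (~0.85° for 3 cm at 2.02 m), which the tests show stays
below the sensor-noise floor.

`conical_average` samples the ground-truth BRF uniformly in solid angle
over the sensor cone (checked against the closed-form cone integral for
a linear-in-angle field); for the default smooth scene the 8.5° conical
average differs negligibly from the directional value, which is the
standing assumption when HCRF is interpreted as an HDRF estimate.

## Error budget and test tolerances

The dual-beam chain stacks four noisy spectra (L_r, L_ref, E(t_x),
E(t_0)), so the corrected-HCRF noise floor is ≈ 2× the per-channel
noise: measured 1.0 % relative RMS at the 0.5 % default, 2.0 % at 1 %.
Tolerances in the tests follow this budget: recovery is asserted exact
(≤1e-9) in noiseless configurations, <1 % for per-channel noise ≤0.25 %,
and bounded by ~3× the floor under defaults.  A corollary worth stating:
at small drift amplitudes (≈1 % per session) the irradiance-channel
noise the correction imports can exceed the drift bias it removes — the
correction's benefit is guaranteed only once drift exceeds the noise
floor, which the tests demonstrate at 5 % and 10 % session drift.

## Quality screening

Noise test: median |second difference| of a spectrum relative to its
median level, threshold 0.02 (clean field spectra at 1.5 nm sampling are
smooth at that scale; the simulator's clean output sits orders of
magnitude below, alternating ±10 % noise far above).  Outlier test:
broadband mean vs the view-zenith ring's median, gate 5× the ring median
absolute deviation; rings with <3 members (the nadir singleton) are
flagged untestable rather than silently passed.  Both thresholds are
engineering defaults, configurable, and permutation-invariant within a
ring.

## Serialization

Spectra: two-column ASCII with a `# key: value` header; values printed
with 17 significant digits so write∘read is bit-exact.  Manifests:
YAML.  Hemisphere datasets: tab-separated tables with a metadata header
(sun geometry, panel-correction provenance, processing switches), one
row per position, one column per wavelength.  All plots are rendered
from interpolated fields for presentation only; every statistic is
computed on raw scheme nodes.

## Known limitations

* c_ref ships as structure + synthetic table; quantitative panel
  correction of real data requires the user's own panel measurements.
* The drift indicator's form is one defensible construction among
  several; its threshold is a default, not a calibration.
* No diffuse/direct irradiance partition, hence no HCRF→HDRF/BRF
  conversion and no BRDF model inversion.
* The ephemeris neglects refraction (irrelevant at ≥43° zenith) and ΔT
  (sub-0.01° at these precisions).
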