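# Methods

`swirsfdi` implements the processing chain of a structured-illumination
(spatial frequency domain) diffuse optical imaging system working in the
shortwave infrared, together with a synthetic forward model of the
instrument so that every stage can be verified quantitatively on a desk.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## Measurement model

A projector illuminates the sample with planar (DC, spatial frequency
fx = 0) and sinusoidal (AC, fx = 0.1 mm⁻¹ by default) patterns at three
wavelengths (970, 1050, 1200 nm). The camera records, per wavelength,
a light-on/light-off pair for DC and four frames with projected phases
0°/90°/180°/270° for AC. Demodulation recovers per-pixel envelope
amplitudes

    M_DC = I_ON − I_OFF
    M_AC = ½ √[(I_90 − I_270)² + (I_0 − I_180)²]

The quadrature form is exact for ideal sinusoids (any offset A > amplitude
B > 0 gives M_AC ≡ B) and invariant to a common phase offset; both
demodulators are homogeneous of degree one in the raw counts, so overall
gain cancels later. Negative M_DC pixels (sensor noise) are clamped to
zero with a logged count.

Calibration uses a reference phantom with known optical properties imaged
under identical conditions. The lookup table predicts the phantom's true
diffuse reflectance R_phantom at each (wavelength, fx), and

    R_sample = R_phantom · M_sample / M_phantom

is applied per pixel, which simultaneously flat-fields the illumination
profile. Pixels whose phantom signal falls below a noise floor (default 1%
of the phantom median) or whose calibrated value exceeds 1.2 are masked
invalid — never silently clipped — and masks propagate downstream.

## Monte Carlo transport and the lookup table

The forward model is variance-reduced photon transport in a semi-infinite
homogeneous medium: pencil beam normally incident, Henyey–Greenstein
scattering (g = 0.9 by default), absorption deposited by albedo weighting
at interaction sites, Russian roulette below weight 10⁻⁴ (survival 1/10),
and angle-resolved unpolarized Fresnel coefficients at the boundary.
Boundary escape is *sampled* (the photon leaves with probability 1 − R(θ))
rather than weight-split; each photon therefore produces at most one
escape record (exit radius r, total geometric pathlength L, weight w),
which is what makes the White Monte Carlo rescaling below exact per
photon. Specular reflection at the entry point is removed before launch
(the crossed-polarizer geometry rejects it), so the launch weight is
1 − R_specular and all reported reflectance is diffuse-only.

Anisotropy and refractive index are not observable through this pipeline's
reduced-scattering parameterization to first order (a similarity test
verifies g = 0 and g = 0.9 agree within a few percent at equal μs′);
defaults are g = 0.9, n = 1.33 for liquid phantoms and 1.4 for tissue.
A lookup table is valid only for samples matching its recorded n.

**Pathlength censoring.** At zero absorption, escape times of a recurrent
random walk have a heavy (square-root) tail with infinite mean, so the
kernel truncates photons whose pathlength exceeds `l_max` (5000 mm for
direct runs, 1000 mm for table builds). A censored photon at μa = 0 still
escapes almost surely — nothing can absorb it — so its weight is counted
in the total diffuse reflectance; this is why the matched-boundary,
zero-absorption total equals 1.0 exactly. Under rescaling to μa > 0 a
censored record contributes at most exp(−μa·l_max) of its weight; the
worst-case bound (censored fraction × that factor, evaluated at the grid's
absorption floor) is stored in the table metadata. At the default floor
μa = 0.001 mm⁻¹ and l_max = 1000 mm the bound is at the percent level and
applies only to that corner; at μa ≥ 0.01 mm⁻¹ it is negligible
(e^−10 ≈ 5·10⁻⁵). Because the same table is used for forward rendering
and inversion, this bias cancels identically in round-trip and
end-to-end analyses.

**White Monte Carlo.** The table is built from one zero-absorption run per
reduced-scattering grid value; each absorption grid value is filled by
weighting every escape record with exp(−μa·L). All μs′ runs share one
seed: a zero-absorption walk is scale-free, so the shared ensemble makes
the table *exactly* monotone increasing in μs′ (common random numbers),
while the exp(−μa·L) factor makes it strictly decreasing in μa. The
equivalence of rescaling with direct simulation at μa > 0 is tested at
3× the combined Monte Carlo standard error.

**Frequency domain.** The spatial-frequency reflectance is the zero-order
Hankel transform of the radial point response. Radial profiles expose a
binned midpoint-rule transform (`hankel_reflectance`); the table builder
instead evaluates the exact Monte Carlo quadrature
R(fx) = E[w·e^(−μa·L)·J₀(2π·fx·r)] over the raw records, which avoids
binning and radial-truncation artifacts in the oscillatory integrand
(censored photons, whose final radius is unknown, enter the DC channel
only). Default grids are μa ∈ [0.001, 0.5] mm⁻¹ and μs′ ∈ [0.3, 5] mm⁻¹,
48 log-spaced points each (tests and the acceptance script use a coarse
24×24 build at 10⁵ photons per scattering value, which resolves all
monotonicity margins above Monte Carlo noise; ~6 minutes on one core).

All built tables are validated at build time: R ∈ [0, 1], strictly
decreasing in μa, non-decreasing in μs′, and AC ≤ DC. The μs′ floor of
the default grid is a well-posedness boundary, not a coverage choice:
when the transport mean free path approaches the projection period
(μs′ ≲ 0.1 mm⁻¹ at fx = 0.1 mm⁻¹) the AC reflectance genuinely loses its
monotone dependence on absorption — Monte Carlo and the diffusion closed
form both show the sign change — so a bidirectional table there would be
ill-posed and the build-time assertion would rightly fail. At μs′ ≥ 0.3
mm⁻¹ the monotone margins exceed Monte Carlo noise at 10⁵ photons/node by
a comfortable factor, and every medium the emulated experiments produce
(Intralipid dilutions down to ~0.42 mm⁻¹ at 1200 nm, skin-like scenes
near 1–2 mm⁻¹) lies inside the restricted domain with margin.

**Diffusion oracle.** An independent closed-form check uses the standard
semi-infinite diffusion approximation with extrapolated-boundary
parameter A = (1 − R_eff)/(2(1 + R_eff)) and scalar attenuation
μ_eff′ = √(3·μa·μtr + (2π·fx)²). Monte Carlo and diffusion agree to ~2%
at fx = 0 and within 10% at fx = 0.1 mm⁻¹ in the diffusive regime
(μs′/μa = 100); the residual gap is the known bias of the diffusion
approximation at higher spatial frequency, not Monte Carlo noise.

## Inversion

Each pixel's (R_DC, R_AC) pair is matched to the table by least squares on
bilinearly interpolated reflectance in (log μa, log μs′) coordinates,
where the surface is closest to linear. A coarse scan over all table
nodes seeds a local 5×5 search window that contracts by half whenever its
minimum is interior (a minimum on the window edge keeps the width, so the
search can walk out of a poor seed), terminating at 10⁻⁶ relative step.
Ties break toward smaller μa (candidates are enumerated in ascending μa
and the first minimum wins) — the conservative-absorption convention.
The residual reflectance mismatch is returned per pixel; pixels above the
tolerance (default 10⁻³, appropriate for noiseless data — for data with
~1% reflectance noise a tolerance near 0.05 is appropriate and is
exposed as a configuration override) are flagged out-of-gamut with a
reason code instead of being assigned values. Noiseless forward→invert
round trips recover 200 random interior points to ≲0.1% per axis; with 1%
multiplicative reflectance noise the median errors are ~3% in μa and ~1%
in μs′.

## Chromophore unmixing

Absorption maps at the three wavelengths are decomposed per pixel by
ordinary least squares into water and lipid volume fractions,
μa(λ) = ε_w(λ)·C_w + ε_l(λ)·C_l, an overdetermined 3×2 system. The
solution is deliberately unconstrained: negative concentrations are
retained and flagged in a negativity mask, preserving diagnosability.
Extinction coefficients are standardized to pure-substance absorption
(mm⁻¹ at 100% volume fraction), so weights are volume fractions and
percent maps are 100× those; the conventional molar equivalences (55.6 M
water, 0.9 g/mL lipid) convert molar inputs. The packaged CSV carries
values digitized from the standard pure-water and soybean-oil absorption
spectra with provenance strings; they are replaceable data, not ground
truth, and any table with the same schema can be substituted.

## Synthetic scenes and the acquisition model

The renderer inverts the physics: scene water/lipid fractions give μa(λ)
through the extinction table, a power law μs′(λ) = a·(λ/λ₀)^(−b) gives
scattering, the lookup table gives per-pixel (R_DC, R_AC), and raw frames
are synthesized as illumination × gain × (R_DC + R_AC·sin(2π·fx·x + φ)) +
ambient, with Gaussian read noise (default σ = 10 counts), a shot-noise
term (variance = expected counts), and 16-bit quantization
(`bit_depth=None` models an ideal sensor for closed-form checks). The
camera defaults (gain 30 000 counts per unit reflectance) put typical
signals at ~1% relative noise per frame — a realistic InGaAs operating
point. Renders are deterministic per seed.

Scenario generators emulate the three laboratory experiments:

- **Dilution series** — homogeneous scenes at lipid fractions
  5/10/15/20% (water 95/90/85/80%), with μs′ proportional to lipid
  fraction from a 10%-Intralipid reference (1.2 mm⁻¹ at 970 nm, spectral
  power 1.62, literature-lineage configurable values).
- **Desiccation** — water decremented per step (default 0.667% relative
  per hour over 4 timepoints ≈ 2% total); scattering coupled through
  Δμs′/μs′ = k·ΔC_w/C_w. The coupling k is a modeling stand-in for the
  collagen-packing mechanism, default k = 2, user-settable; whether water
  loss is expressed relative or in absolute percentage points is an
  explicit `convention` switch because mass-loss bookkeeping supports
  either reading.
- **Exercise** — five identical baseline timepoints, a relative dermal
  water step (default 5%) at the exercise boundary with coupled μs′, and
  exponential recovery (default time constant 8 minutes), while an
  in-frame reference-phantom region never changes. Ten post-exercise
  timepoints mirror the per-minute protocol.

ROI analytics use 0-based, row-major, half-open rectangles. Percent
change is reported against either the first timepoint or the mean of the
pre-event timepoints (the default for exercise runs, switchable); an
absolute-value variant matches the usual presentation of drift analyses.

## What the synthetic tests show — and what they do not

The synthetic pipeline is closed over the same lookup table used for
inversion, so end-to-end recoveries (water within 0.5 percentage points
noiseless, ~1–3 points under realistic noise) verify the *software chain*:
demodulation exactness, calibration cancellation, inversion conditioning,
and unmixing algebra, at the few-percent error scale typical of physical
SFDI instruments measuring known dilutions. They
do not validate instrument physics that the renderer does not model:
projector/camera transfer functions, surface curvature and profile
effects, specular leakage, inter-frame motion, chromatic focus, or any
mismatch between the packaged extinction spectra and the actual
chromophores. Equally, the scattering–hydration coupling k is an input to
the desiccation/exercise generators, not a measured constant, so those
runs demonstrate signature detection (monotone μs′ decline, step drop with
recovery, phantom-anchored drift separation) rather than physiology.

## Numerical choices and degenerate inputs

- Roulette threshold 10⁻⁴, survival 1/10; seeds are mandatory at every
  public entry point and sub-seeds derive by fixed offsets (all < 2³¹).
- Radial binning: r_max = 100 mm, 2000 uniform annuli; weight beyond
  r_max enters totals but not binned profiles.
- Interpolation and inversion run in log coordinates; inversion descent
  terminates at 10⁻⁶ relative step or 200 iterations.
- Division by a zero/noise-floor phantom pixel masks the pixel; a fully
  invalid ROI returns a flagged statistic, not a number; a zero baseline
  flags the trend row rather than dividing.
- Degenerate linear systems (duplicate wavelengths) are rejected before
  the solve; the extinction design-matrix condition number is exposed.
- HDF5 outputs carry config hash, lookup-table hash and seeds, so a rerun
  with the same configuration is verifiably byte-identical.

## Known limitations

Semi-infinite homogeneous media only (no layers, no tomography);
normal-incidence pencil-beam geometry; two spatial frequencies; no
polarization or time-of-flight physics; unmixing limited to two
chromophores by default (the table schema is extensible); image
registration across timepoints is out of scope (synthetic series are
generated pre-registered). The censoring bias at the absorption-grid
floor, while bounded and reported, makes the lowest-μa column of a table
slightly conservative in absolute terms.
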