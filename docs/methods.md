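# Methods

## The measurement this package models

A lyotropic chromonic liquid crystal (LCLC) biosensor reads out analyte
binding optically. The sensing cell is an aqueous nematic film of
disodium cromoglycate (DSCG) between two rubbed-polyimide glass
substrates, planar-aligned so that with no analyte the director lies
along the rubbing direction. Biomolecules immobilized at the LC-glass
interface twist the director azimuthally; the twist grows with analyte
load. Placed between parallel or crossed polarizers with the rubbing
direction along the analyzer axis, the cell transmits

    I_par(λ)   = 1 − sin²(2φ) · sin²(δ(λ)/2)
    I_cross(λ) =     sin²(2φ) · sin²(δ(λ)/2)

with azimuthal angle φ between director and analyzer axis, and phase
retardation δ = 2πdΔn(λ)/λ for cell gap d and birefringence
Δn = n_eff − n⊥. At pretilt θ the effective index is
n_eff = n⊥n∥ / √(n∥²sin²θ + n⊥²cos²θ), so Δn vanishes at vertical
alignment (θ = 90°) and is maximal in the planar state (θ = 0). DSCG is
optically negative (n∥ < n⊥, Δn < 0); because Δn enters only through
sin², every transmittance is invariant under Δn → −Δn and the sign
needs no special handling.

The uniform-director closed forms above are the primary model. The real
perturbed cell is twisted through its thickness with no closed-form
transmittance, so a multi-slab Jones-matrix stack is provided both as
an independent numerical oracle (a uniform stack must collapse to the
closed forms, which the tests enforce to 1e−10) and as an optional
forward model for twisted profiles. Reflection losses, polarizer
extinction ratios, scattering by textures and full 4×4 electromagnetic
treatment are out of scope.

## Reduced transmittance

Raw spectra are normalized against an analyte-free reference cell so
that the blank maps to (1, 0):

    T_par   = (S_par   − T⊥ʷ/ᵒ) / (T∥ʷ/ᵒ − T⊥ʷ/ᵒ)
    T_cross = (S_cross − T⊥ʷ/ᵒ) / (T∥ʷ/ᵒ − T⊥ʷ/ᵒ)

per wavelength. Requirements and choices:

- Exact grid match is required; resampling exists but must be invoked
  explicitly (silent interpolation would hide instrument drift).
- The reference contrast |T∥ʷ/ᵒ − T⊥ʷ/ᵒ| must exceed 1e−6 at every
  wavelength, else the reduction is refused as degenerate.
- No clipping: noisy reduced values may fall slightly outside [0, 1]
  and are preserved.
- The ratio T_par/T_cross is reported as NaN where |T_cross| < 1e−9;
  near the blank T_cross → 0 and the ratio diverges, which is why
  ratio calibrations use only analyte-bearing concentrations.
- Reduction is applied per replicate, then replicates are averaged
  (sample sd, n−1 denominator); a single replicate yields sd = 0 with
  a warning.
- Spectra are assumed to be transmittances already (the spectrometer's
  own normalization); no dark/lamp correction stage is included.

## Calibration and limit of detection

Responses at selected wavelengths (450–800 nm in 50 nm steps by
default) are regressed on x = log10(c / (g/mL)) by unweighted OLS:
cubic for T_par and T_cross (the dose response saturates at both ends,
so a straight line underfits the full 8-decade series), linear for the
ratio. R² is always 1 − SS_res/SS_tot, no adjustment. True blanks
(c = 0) are inadmissible in fits; they enter only through the
reference spectra. Monotonicity of a fitted cubic over its range is
checked at fit time and a warning recorded — a cubic fitted to a
saturating S-curve typically has shallow turning points near the range
ends, which is expected and harmless for mid-range inversion.

The limit of detection uses the 3s/m rule with s the standard error of
the fitted intercept and m the slope of a linear calibration. With a
logarithmic abscissa 3s/|m| carries log10-concentration units, so two
conventions exist behind a mandatory flag:

- `abscissa-domain`: LOD = 10^(3s/|m|) g/mL (dimensional anchor
  1 g/mL). Invariant under affine response rescaling.
- `signal-domain`: the same points are re-regressed against linear
  concentration and LOD = 3s/|m| directly in g/mL.

Neither is a silent default because the rule is convention-dependent
under a log abscissa; the pipeline records which was used. The default
linear range for LOD regressions is the three lowest concentrations
above blank (the dose response is closest to linear there), and it is
user-configurable.

Inverse prediction solves the fitted polynomial inside the fitted
abscissa range: no in-range root and multiple in-range roots both fail
loudly (out-of-range and non-monotone-calibration errors). Prediction
intervals are first-order, dx = z·σ_y/|dy/dx| at the root; the
pipeline reports z = 1.96 (~95%) intervals with σ_y combining the
calibration residual sd and the median replicate sd.

## Azimuth estimation

With δ(λ) known from the cell optics, sin²(2φ) is the least-squares
amplitude of both channels' signals against w(λ) = sin²(δ(λ)/2):
s* = Σwy/Σw², y ∈ {1−I_par, I_cross}. Wavelengths with w < 1e−3 are
excluded (near half-wave nulls φ is unidentifiable; if all wavelengths
fall below the floor the estimator raises instead of guessing).
Estimates are reported on [0°, 45°]; sin²(2φ) is symmetric about 45°,
so larger twists alias into that branch and the ambiguity is
documented, not resolved.

## Cell-gap interferometry

An empty cell is a low-finesse etalon, T ∝ 1 + cos(4πd/λ), maxima at
λ = 2d/m. Maxima are detected by prominence-thresholded peak picking
(prominence relative to the value range, default 0.1) with parabolic
sub-sample refinement, and the gap follows from interval counting:
d = Nλ₁λ_N / (2n(λ_N − λ₁)). Absolute fringe orders are never
assigned, so smooth envelopes do not bias the estimate. The quoted
uncertainty propagates a per-peak wavelength resolution (default
0.5 nm). On a 2048-sample 400–800 nm grid, gaps of 5–30 µm are
recovered within 0.5% noiseless and 2% at 1% multiplicative noise.

## Synthetic experiments

The generator emulates the measurement campaign end to end so the
whole chain is testable without instruments: a decade dilution series
(1e−12 … 1e−5 g/mL), n = 3 replicates, a 400–800 nm grid with 401
samples, plus analyte-free reference replicates, all from one seeded
random stream in a documented draw order (references first, then
concentrations ascending; parallel before crossed; multiplicative
before additive noise), so a fixed seed reproduces every file byte for
byte.

The dose→twist link is a logistic in log10 c,
φ(c) = φ_max / (1 + 10^(−h·(log10 c − log10 c50))), with φ(0) = 0.
This is a synthetic stand-in, not a measured relationship: the physics
fixes only that φ rises monotonically from 0 and saturates, and the
logistic is the simplest such curve. Defaults: φ_max = 40° (below the
45° identifiability cap), c50 = 10⁻⁸·⁵ g/mL (the geometric middle of
the series), h = 0.25 decades⁻¹ — a gentle S whose composite response
sin²(2φ(x)) is cubic-representable to R² ≈ 0.9995, consistent with the
near-unity cubic fits such assays report. Noise is per-wavelength,
multiplicative sd 0.02 and additive sd 0.005, giving reduced-response
scatter of roughly 0.02.

Dispersion defaults are package constants, not measured values: Cauchy
n⊥ = 1.3850 + 2400/λ², n∥ = 1.3720 + 1000/λ² (λ in nm), giving
|Δn| ≈ 0.0199 at 450 nm falling to 0.0152 at 800 nm — magnitude and
wavelength trend characteristic of nematic DSCG. With the 15 µm gap
this puts the half-wave null near 527 nm, between analysis
wavelengths, and makes the short-wavelength channel the most
sensitive, mirroring the behaviour of the real sensor.

What the generator does not emulate: antibody-antigen binding
kinetics, spatial heterogeneity of the sensing spot, wavelength-
correlated (pink) instrument noise, baseline drift, and any true φ(c)
law. Passing tests therefore demonstrate the correctness of the
analysis chain under the stated statistical assumptions, not the
biochemical fidelity of the link.

## Problem sizes used in tests

The default suite runs synthetic experiments of 8 concentrations × 3
replicates × 2 schemes on 101- or 401-point grids; parameter-recovery
studies use 50-seed batches and the LOD-stability study 100 seeds.
These sizes were chosen so each property is measured with comfortable
statistical margin while the whole suite stays fast enough to run on
every commit.

## Known limitations

- The uniform-φ closed forms are an approximation to the truly twisted
  perturbed cell; the Jones stack is available when a through-thickness
  profile matters.
- The abscissa-domain LOD is a convention with a dimensional anchor,
  not a physically derived concentration; compare LODs only within one
  convention.
- φ estimates above 45° alias; the package reports the first-octant
  branch only.
- The fringe-counting gap estimator assumes a non-dispersive medium
  between the substrates (valid for the empty cell it is intended for).
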