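# Methods

`coilassay` models a non-contact electrotaxis platform: a driven multilayer
coil induces a weak azimuthal electric field at Transwell membranes placed
beside it (or at a culture-plate bottom above it), without electrodes
touching the medium. The package computes that field from first principles
and quantifies the two biological readouts such experiments use —
transmembrane migration counts and F-actin orientation — with synthetic
generators standing in for lab data.

## Coil model

The coil (3 mm ID, 1.4 cm OD, 10.5 cm long, 35 layers × 159 turns of AWG32;
measured 50.45 Ω and 14.25 mH at 1 kHz) is idealised as 5565 coaxial
circular filament loops. Layer radii are spaced **uniformly between the
printed inner and outer winding radii** rather than stacked at one
insulated-wire diameter per layer: 35 layers × 0.268 mm would build 9.4 mm
of radial depth, contradicting the printed 1.4 cm OD, so the printed
envelope is taken as the only self-consistent constraint. Turn centres
within a layer occupy uniform bins along the length, symmetric about the
midplane.

The printed winding counts and the measured electricals are not mutually
consistent either: the geometric DC-resistance estimate
(ρ_Cu = 1.68×10⁻⁸ Ω·m at 20 °C) is **77.9 Ω, ~54 % above the measured
50.45 Ω**, while the inductance estimate (loop self-terms
μ₀a(ln(8a/r_w)−2) plus all pairwise Maxwell mutual terms) is **14.28 mH,
within 0.2 % of the measured 14.25 mH** — strong support for the
uniform-envelope geometry. An `effective_turn_scale` reconciles either
measurement on request (`match_R` scales linearly, `match_L` by square
root); it multiplies the per-loop current weight, leaving geometry fixed,
so R scales linearly and L quadratically in it. Field reconstructions
default to `match_L` (scale 0.9989) because the field, like the
inductance, is a magnetic quantity. Which printed number is authoritative
cannot be decided from the available text; both calibrations are exposed.

## Field solver

A loop's azimuthal vector potential uses the closed form in complete
elliptic integrals with the *parameter* convention m = k² =
4aρ/((a+ρ)²+z²) (scipy's `ellipk`/`ellipe`); the test-suite pins the
convention against a 10⁵-segment Biot–Savart line-integral oracle to 10⁻⁶
relative, the classic k-vs-m bug being the most common silent error in
loop-field code. Below m = 10⁻⁴ a series expansion
(πm²/32)(1 + 3m/4) replaces the catastrophically cancelling bracket and
supplies the dipole far field. Points within one bare-wire radius of a
filament are rejected — the filament model is unphysical there.

Geometry and time factor exactly: E_θ(p,t) = −A_unit(p)·di/dt(t), with the
per-unit-current stack potential cached per point. Faraday bookkeeping
(2πρE_θ = −dΦ/dt), on-axis closed forms, the infinite-solenoid interior
limit, and the ρ⁻² far-field decay are all verified against independent
routes in the tests.

## Drive circuit

The drive is a 20 Vpp, 100 kHz zero-offset sawtooth (linear rise, 50 ns
fall) behind the generator's 50 Ω output impedance, feeding the coil's
series R–L branch (measured values), with an optional parasitic
self-capacitance C_p in parallel with that branch. The periodic steady
state is solved exactly per Fourier harmonic; di/dt comes from spectral
differentiation, so traces are periodic with zero-mean derivative to
machine precision. Default N = 8192 samples/period puts ~41 samples across
the 50 ns fall. All grid-representable harmonics are retained (the Nyquist
bin's derivative is dropped; its phase is undefined on the grid). The
sinusoidal drive converges spectrally under grid doubling (<10⁻¹⁵); the
sawtooth corner limits convergence to ~6×10⁻⁶ per doubling at the default
grid.

With ωL ≫ R at 100 kHz the branch is inductance-dominated, so di/dt ≈
V_L/L and the migration-direction duty fraction of the induced field is
**≈ 50.3 %, not the ~60/40 split the modelled apparatus reports**. A C_p
scan over 10 pF–10 nF moves the fraction by under 2 points; no plausible
self-capacitance produces 60/40, so the asymmetry's origin remains an open
gap of the model and both the series-RL and C_p-augmented values are
reported rather than forced. Likewise, the honest enclosed-flux field
maxima at the default membrane placement are ~520–530 μV/cm — two orders
of magnitude above the ~2.3–3.8 μV/cm the apparatus documentation prints.
The discrepancy cannot come from the circuit (the printed values would
need di/dt ≈ 3 A/s where the printed drive and measured L imply ~700 A/s);
an estimate based on the *local* exterior B at the membrane,
E = (ρ/2)·dB/dt, rather than the enclosed interior flux, would produce
numbers of the printed order, but the original derivation is not available
to check. The package reports what Faraday's law gives for its configured
geometry.

### Sign conventions

The azimuthal field at membrane height is vertical; "migration direction"
is downward through the membrane (top chamber → bottom chamber). North and
South sides see opposite vertical signs at equal magnitude. The winding
handedness — unobservable from the printed geometry — is fixed so that the
longer duty lobe maps to *downward on the North side*, matching how the
modelled apparatus labels its own sides; `winding_handedness=+1` flips it.

## Assay geometry

The exact membrane distances and well axial positions are unpublished.
Defaults: three wells per side at z = −30, 0, +30 mm; membranes level with
the coil centreline, starting 2 mm beyond the winding and spanning one
6.5 mm Transwell insert diameter. All field maxima depend on this choice;
the radial profile (strictly decreasing beyond the winding, slope → −2 on
log–log in the far field) reports the sensitivity. The duty-fraction
reference point is the innermost radius of the central well. Across-well
uniformity (relative spread of per-well peak |E|) is ~2 % for the
reference coil, consistent with each well seeing the same exposure. In the
plate layout the coil axis is horizontal and a plate point at (x, y) maps
to (ρ, z) = (√(y² + h²), x) with h = outer radius + plate-bottom offset.

## Migration statistics

A well's score is the sum of cells over its 5 contiguous radially-outward
fields; scores are normalised to the control-condition mean (control ≡
100 %) and summarised as mean ± sample SD over replicates. The replicate
unit is switchable — wells pooled across experiments (default) or
per-experiment means — because published summaries of this assay are
ambiguous about which convention their SDs use. Comparisons use the
two-tailed pooled-variance Student t-test (Welch behind a flag); star
annotation uses the half-open bins '*' [0.01, 0.05), '**' [0.001, 0.01),
'***' < 0.001.

The calibration suite verifies type-I error (0.05 ± 0.01 over 10⁴ null
simulations from the count generator) and strictly increasing power over
effect sizes 1.0 → 0.8 → 0.6 at n = 9 wells. These run at a control rate
of 5 cells/field: at realistic ~40 cells/field the test's power saturates
at 1.0 for both effects, which would make the monotonicity check
uninformative; the low-count regime keeps the power curve interior.

## Actin quantification

The original quantification method for actin-distribution claims is not
available; the package substitutes an explicit, documented metric. Cells
are segmented by global Otsu threshold → connected components → area
filter (min 200 px). Within a cell, per-pixel orientation comes from the
structure tensor smoothed at σ = 2 px; filament direction is the gradient's
perpendicular. Orientations are axial (mod π), so circular statistics use
doubled angles: the **anisotropy index** is the gradient-energy-weighted
resultant length (0 = no preferred direction, 1 = parallel filaments) and
the dominant orientation is half the resultant angle, binned into 36-bin
histograms. Region pixels are eroded by ~2σ before analysis so the
segmentation boundary — whose gradients track the cell outline, not the
filament texture — cannot bias the statistics. Because the claim being
operationalised might alternatively concern the radial fluorescence
distribution, a radial intensity profile is emitted alongside. The index
is invariant under global intensity scaling and under rotation to within
binning error.

## Synthetic generators

All generators are pure functions of (model, seed).

*Counts*: per-field counts are iid Poisson with rate control_rate ×
condition effect (5 fields/well, wells grouped 3 per experiment). Poisson
is the simplest model consistent with count data; no dispersion
information exists for the emulated assay, and real counts may be
overdispersed — passing calibration here does not certify behaviour under
overdispersion.

*Fiber images*: elliptical cells containing short line-segment fibers whose
axial orientations follow a doubled-angle von Mises law (κ = 0 isotropic),
plus Gaussian background noise and detector-style saturation. Two
generator properties were calibrated deliberately and are worth knowing:
(i) the anisotropy index of a genuinely isotropic texture has a floor set
by the number of independent tensor patches, ≈ √(π/4 · (4σ)²/area), so
cells must be large (default axes 60 × 42 px in 448² images) for isotropy
to register below 0.1; (ii) long fiber chords clipped by the cell mask
inherit the body's aspect ratio as spurious anisotropy, so fibers are
short (12 px) and numerous (600/cell). With the defaults, κ = 0 cells
average index ≈ 0.09 and the dominant orientation is recovered within
1–3° for κ ≥ 1. The images emulate texture statistics only — not
filopodia, leader-cell morphology, 3-D structure, or staining variability —
so passing tests demonstrate metric correctness, not performance on real
micrographs.

*Waveforms*: analytic waveforms sampled with optional Gaussian amplitude
jitter, exercising the sampled-waveform path of the circuit solver.

## Numerical choices and problem sizes

SI units internally; fields convert to μV/cm (1 V/m = 10⁴ μV/cm).
Default grids: 8192 time samples/period, 5 radial membrane samples/well.
The pairwise mutual-inductance sum over all 15.5 M loop pairs evaluates in
a few seconds (chunked, vectorised elliptic integrals); coincident loops
contribute self-terms in place of the singular mutual term. Degenerate
inputs are defined explicitly: empty stacks have zero R and L; a
zero-resistance loop returns the zero-mean periodic current (its DC
component has no steady state); blank images segment to nothing;
zero-gradient regions return a uniform histogram with index 0;
zero-variance equal-mean t-tests return p = 1.

## Known limitations

- Skin/proximity effects, temperature dependence, eddy currents in the
  medium and incubator hardware, and magnetic materials are out of scope;
  fields are filament-loop magnetostatics modulated by the drive.
- The printed ~60/40 duty asymmetry and the ~2.3–3.8 μV/cm field maxima of
  the modelled apparatus are *not* reproduced by this model (see Drive
  circuit above); the package reports its own first-principles values and
  the gap rather than fitting to the printed numbers.
- Membrane placement defaults are explicit stand-ins, not the original
  apparatus' (unpublished) dimensions.
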