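# Methods

This note records the physical models, numerical choices and known
limitations of `plasmonsheet`, in the order the pipeline runs them.

## Evanescent reference field

The TIRF reference is the scalar evanescent intensity
`I(z) = I0 exp(-z/d)` with `d = λ / (4π √(n₁² sin²θ − n₂²))`. `I0` is
normalized to 1: no Fresnel transmission factor at z = 0 is applied, so
all curves are *relative* intensities and only the depth dependence is
meaningful. Angles are degrees at the API, radians internally. Refractive
indices are wavelength-independent scalars supplied by the caller
(defaults: glass 1.52 against water 1.33 or a glycerol-based mounting
medium 1.46). With dispersive indices the critical angles would shift by
a few tenths of a degree; we do not model dispersion. Below the critical
angle the penetration depth is undefined and the code raises rather than
returning a complex or infinite value.

## Gold permittivity

The bundled table (`data/au_johnson_christy.csv`) is the standard Johnson
& Christy (1972) n, k tabulation for gold converted to complex relative
permittivity, 381–1937 nm. The solver uses a Drude fit
`ε(ω) = ε∞ − ωp²/(ω² + iγω)` obtained by joint least squares on real and
imaginary parts over a 500–650 nm window bracketing the two laser lines;
the fit reproduces the tabulated points within |Δε| < 1.5 there. A
free-electron model cannot represent the interband transitions that set
in below ~520 nm, so 488 nm sits outside the fit window and the model is
only order-of-magnitude there — acceptable, because the sheet physics of
interest (collective resonance, gap enhancement) is probed at 561 nm.
Direct table interpolation is available (`table_permittivity`) and serves
as the oracle for the fit in the tests.

## Coupled-dipole sheet solver

Each gold core is a point dipole with the quasi-static Clausius–Mossotti
polarizability `α = r³(ε − ε_m)/(ε + 2ε_m)` in a host of index 1.33
(water side; the supporting substrate is neglected — no image dipoles).
Dipoles couple through the static tensor `(3ûû − I)/d³`; the 3N × 3N
system is LU-factorized once per (sheet, wavelength) and solved per
polarization. Retardation is neglected: the pitch (15.2 nm) and the
probed distances (≲ 200 nm) are far below λ. The collective red shift of
the sheet resonance emerges from the coupling, not from any imposed
spectral shift.

Choices that matter:

* **Patch.** Default 13 × 13 particles (169) in a hexagonal lattice with
  the probed nearest-neighbour pair straddling the origin. The peak
  enhancement converges with patch size (the 13-patch peak is within
  ~11% of the 17-patch value; the increments shrink monotonically).
  Intermediate-height intensities carry a coherent percent-level deficit
  from the missing outer rings of an infinite sheet; the far-field
  recovery property is therefore demonstrated on a 21 × 21 patch.
  The unity-crossing distance of the profile is the quantity most
  sensitive to patch size, because the profile approaches 1 shallowly;
  with the default patch it lands at 10.9 nm at 561 nm.
* **Probe line.** Normal to the sheet through the midpoint of two
  adjacent particle centers, with D = 0 in the plane of centers; the
  nearest particle surface is √(D² + (pitch/2)²) − r away, i.e. gap/2 =
  1.3 nm at D = 0. Energy-transfer attenuation along the line always
  uses this nearest-surface distance, not D itself.
* **Polarization.** Reported profiles average the two orthogonal
  in-plane linear polarizations, modeling unpolarized epi-illumination.
* **Singularities.** A lossless material tuned onto a collective
  resonance makes the coupling matrix singular; the solver estimates the
  reciprocal condition number after factorization and raises a dedicated
  error naming the resonant condition instead of returning garbage.

A grid-based time-domain reference for this geometry exists in the
literature of such sheets; we deliberately use the coupled-dipole route —
deterministic, seconds-fast, and checkable against closed forms (the
one-particle solution equals the quasi-static sphere; a dimer equals an
independent 6 × 6 solve to machine precision). Agreement with grid
solvers is expected in peak position and order of magnitude, not in
digits; no time-domain cross-check is bundled.

## Energy transfer

One model type covers both laws: transfer rate
`k = (1/τ_D)(x₀/x)^n` with n = 4 (surface energy transfer, default) or
n = 6 (FRET-like), and the attenuation factor `[1 + (d₀/d)^n]⁻¹`. The
characteristic distance d₀ is not pinned by the source material, so the
profile study sweeps d₀ ∈ {2, 5, 7, 10} nm and labels every output by
d₀; the imaging study uses d₀ = 5 nm, a typical dye-to-gold NSET scale.
Spectral-overlap-dependent transfer (PIRET) is not modelled. Quantum-yield
and lifetime modification near the metal (Purcell physics) and
emission-side spectra are out of scope; emission enhancement is folded
into a single configurable scalar gain (default 1).

`fit_distance_exponent` inverts the attenuation law:
`log(1/A − 1) = n log d₀ − n log d` is fitted by *weighted* least squares
with weights (1 − A)², because under multiplicative noise the variance of
the transformed variable grows as 1/(1 − A)² and unweighted fitting lets
near-saturated far points bias the slope. The returned confidence
interval is the t-based interval on the slope.

## Synthetic cell

The generator emulates a fixed, actin-labelled adherent cell as point
fluorophores with structure tags; z is measured from the top surface of
the imaging substrate (glass, capping layer or spacer top), positive into
the sample. Defaults (all overridable; the literature provides morphology
but no absolute z coordinates, so these are declared assumptions):

| structure | geometry | z range (nm) | labelling |
|---|---|---|---|
| ventral layer | disk, r = 5 µm | 5–50 | 40 µm⁻² |
| dorsal layer | disk | 300–600 | 120 µm⁻² |
| stress fibers | 8 chords, 150 nm width | 10–60 | 30 µm⁻¹ |
| focal adhesions | 12 spots, r = 300 nm, 2/3 at the rim, 1/3 central | 5–30 | 80 per spot |

The dorsal density deliberately exceeds the ventral one: widefield images
of adherent cells are dominated by out-of-focus dorsal/apical actin, and
that is precisely the background a depth-selective modality must beat.
Counts are Poisson (mean = density × measure), positions uniform within
each structure, brightness lognormal with CV 0.2, and every draw comes
from one seeded generator, so a seed fixes the population exactly.
Calibration beads are uniformly filled spheres resting on a configurable
z offset.

What the generator does *not* emulate: connected filament networks,
membranes and receptors, label stoichiometry chemistry, photophysics
(blinking/bleaching), and live-cell dynamics. Passing the imaging
orderings on this phantom therefore shows that the *excitation models*
rank modalities correctly for a geometry with a genuine near/far split —
it does not certify performance on real specimens.

## Image formation

Excitation weights per modality: epi → 1; oblique (sub-critical) →
homogeneous 1 plus an elevated Poisson background in the rendered frame
(a deliberate simplification of highly-inclined illumination); TIRF →
`exp(-z/d)`, refusing angles at or below critical (and the oblique path
refuses super-critical angles, pointing at TIRF).

For sheet excitation the weight at height h above the particle top plane
(h = z + spacer thickness; the SiO₂ spacer is a rigid offset that keeps
fluorophores at least its thickness from the metal) is the unit-cell
lateral average of the *scattered-field* intensity |E − E₀|² times the
SET attenuation at the nearest-surface distance, tabulated once on a
geometric height grid (36 lateral samples × 48 heights) and interpolated.
Two modeling decisions are embedded here:

* **Lateral averaging.** The field's lateral structure (15.2 nm pitch) is
  far below the pixel size (65–160 nm), so hot spots are not resolved and
  the average is the physically observable weight.
* **Scattered field, not total field.** The modality models excitation by
  the plasmon-confined component only; the directly transmitted
  propagating beam appears as a configurable uniform background with
  default 0 (ideal rejection). Under total internal reflection — the
  sheet's native operating condition — there is no propagating
  transmitted beam, and this idealization also makes the weights
  independent of incidence angle, which is the substrate-bound-field
  behaviour the modality exists to express. At normal incidence on a
  real sheet a transmitted component does excite the cell body; raising
  `transmitted_background` above zero restores it. With the default the
  sheet's ventral fraction is an upper bound.

Rendering: expected photons = brightness × weight × exposure × gain,
spread with an error-function-integrated 2-D Gaussian PSF of width
σ = 0.21 λ_em/NA (Gaussian fit to the Airy core) over a ±6σ stamp (PSF
mass deficit < 1e-8, so the noiseless frame conserves the photon budget
to better than 1e-6 when the PSF fits the frame). A σ below 0.1 pixel
triggers an undersampling warning. Noise is Poisson shot noise plus
additive Gaussian read noise (σ = 1 count), then rounding and clipping to
a 16-bit range; clipping at zero biases empty pixels up by a fraction of
a count, which is real digitization behaviour and is accounted for in the
tests. All noise comes from the setup's seed.

Metrics: `ventral_fraction` is the substrate-proximal share (ventral +
fiber + adhesion tags) of the brightness-weighted excitation budget;
`signal_to_background` is (mean in-mask − mean out-mask)/std out-mask
against the ground-truth structure mask; `compare_modalities` reports
both per setup and evaluates two booleans — sheet metrics spread < 5%
relative across angles, glass metrics ratio > 2× across angles.

## Studies, sizes, determinism

The profile study runs on a 2001-point grid to 200 nm at 488 and 561 nm.
The imaging study renders a 5 µm-radius cell (~15,000 fluorophores) on a
192 × 192 frame at 65 nm/pixel under eight setups (glass at 0°/65°/75°,
mounting medium at 65°/75°, sheet at 0°/65°/75°) plus a spacer sweep at
0/10/20 nm reporting total brightness per thickness (emission-side
interference, which can favour a particular thickness, is not modelled —
the sweep reports, it does not rank). Both studies derive all randomness
from the single configured seed and write byte-stable JSON; outputs are
never overwritten without an explicit flag. The whole default pipeline
runs in well under a minute on one CPU.

## Known limitations

* Quasi-static dipoles only: no retardation, no multipoles, no substrate
  image-dipole correction. Gap fields between 12.6 nm spheres at 1.3 nm
  separation have multipolar structure the dipole model underestimates;
  the reported enhancements are indicative, not quantitative.
* The unity-crossing distance is patch-size sensitive (shallow approach
  to 1); it is reported at the default 13 × 13 patch.
* Scalar fields throughout; no polarization-dependent evanescent
  amplitudes or vectorial high-NA PSF.
* The synthetic cell is a geometric phantom, not a biophysical model.
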