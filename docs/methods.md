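# Methods

`htplan` plans focused microwave hyperthermia of a breast tumor heated by a
ring of eight dipole antennas. This note documents the models, the numerical
choices, and what the synthetic test bed does and does not establish.

## Physical chain

1. **Phantom.** A voxelized breast (skin, subcutaneous fat, interstitial
   breast fat, gland, pectoral muscle) with an embedded spherical tumor.
2. **Electromagnetics.** Each dipole, driven alone at 1 GHz with 1 W
   accepted port power, produces a complex field volume Ê_n(r).
3. **SAR algebra.** The array's deposition for any drive is
   SAR(r) = σ(r)/(2ρ(r)) |Σ_n A_n Ê_n(r)|², a Hermitian quadratic form in
   the complex amplitudes A_n = √P_n e^{jϕ_n}.
4. **Optimization.** Maximize mean tumor SAR over mean healthy-tissue SAR —
   a generalized Rayleigh quotient, solved exactly by the principal
   generalized eigenvector.
5. **Thermals.** The optimized deposition Q = ρ·SAR drives a transient
   Pennes bioheat solve for a 30-minute exposure plus cool-down.

## Synthetic phantom

The generator emulates the bulk composition of a heterogeneously dense
breast rather than any individual anatomy: a hemisphere (default radius
70 mm) on a muscle slab, with concentric skin (2 mm nominal; widened to one
voxel at coarse grids) and subcutaneous-fat (4 mm) shells and a lobulated
interior. The gland/breast-fat interleaving is thresholded Gaussian noise
with an 8 mm correlation length — a scale chosen to caricature lobes and
ducts, not to reproduce them. The slab thickness and the noise threshold
are solved so the muscle/gland/fat split of the soft tissue lands on the
composition-class target (HD: 20/60/20; PF, SFG, ED likewise); realized
fractions sit within ±5 percentage points after voxelization. The tumor is
a sphere assigned by the center-of-voxel-inside-sphere rule at
(0, −12, 12) mm, inside the glandular interior, and carries muscle
dielectric/thermal constants with temperature-dependent perfusion.

What this phantom does **not** have: real ductal/lobular topology, skin
curvature detail, chest-wall anatomy, or the fine dielectric texture of
tissue interfaces. Consequences: the pipeline's *trends* (optimized-vs-
uniform contrast, growth of peak SAR and temperature with tumor radius,
sub-42 °C operation at 8 W) are meaningful, but absolute peak SAR and the
specific optimal phase/power pattern are phantom-specific and are not
comparable voxel-for-voxel with results on any anatomical model.

Tissue constants (1 GHz): permittivity, conductivity, density, specific
heat, thermal conductivity, heat transfer rate HTR (mL/min/kg) and
metabolic rate HGR (W/kg) per tissue; the volumetric Pennes sink
coefficient is ρ_b C_b ρ · HTR·10⁻⁶/60 with blood ρ_b = 1050 kg/m³,
C_b = 3617 J/kg/K.

## FDTD solver

Standard Yee grid, cubic cells (default 3 mm), single-precision fields,
time step snapped slightly below the 3-D Courant limit so one source
period is an integer number of steps. Boundaries are 8-cell convolutional
PML on every face (cubic grading, σ_max = 0.8(m+1)/(η₀Δ), α = 0.05 S/m),
preceded by a configurable air gap. Antenna arms are one-cell PEC edge
chains along x; the feed is a one-cell resistive voltage source (50 Ω)
using the standard lumped-element update. Port voltage is the gap-edge
field times the cell size; port current is the discrete Ampère loop around
the gap edge. A continuous-wave run ramps the source with a raised cosine
over 6 periods, then demodulates the field at the drive frequency over
4-period windows until the full-field phasor changes by less than 10⁻³
between windows (re-runs abort after 60 periods with a convergence error).
Edge phasors are averaged to cell centers, and the volume is rescaled to
1 W accepted port power (P = ½Re(V I*)), which makes amplitudes carry
watts: A_n = √P_n.

Verification. Against the exact field of a single-cell current element
(Hertzian dipole) the solver is accurate to 1–2% in magnitude at 0.3–0.7
wavelengths. Against the closed-form sinusoidal-current thin-wire dipole,
the discrepancy is dominated by the effective electrical length of the
discrete wire (end-cap fringing of order half a cell), shrinking
first-order with the spacing: ~11% at 5 mm, ~5% at 2.5 mm for the
production dipole. The port sweep of the shortened dipole (Gaussian pulse,
FFT of V and I) puts the resonance near 1.35 GHz with S11 ≈ −15 dB — a
shortened half-wave dipole resonating above its 1 GHz operating point, as
designed. Grids are required to resolve ≥10 cells per wavelength in the
densest tissue (3 mm gives ~13 in gland at 1 GHz).

Choice of validation distances: desk-scale domains cannot reach several
vacuum wavelengths at 1 GHz, so amplitude agreement is asserted at
0.25–0.3 λ (where the closed form is still exact for its assumed current),
and the axial null is demonstrated at 2 GHz out to 2.5 λ. Note that a
finite dipole's on-axis field vanishes only asymptotically — the residue
falls off as ~2h/r relative to the equatorial field because the wire tips
remain in their near zone — so the test asserts that the measured
axial/equatorial contrast (in which wire-model normalization cancels)
tracks the thin-wire prediction and keeps deepening with distance, rather
than an arbitrary absolute floor.

No water bolus or applicator shell is modeled; air fills the gap between
skin and antennas. Tissue dispersion is ignored: single-frequency constants
only. Antenna feeds are treated as uncoupled; mutual S-parameters are out
of scope.

## SAR quadratic forms

Region-averaged SAR is held as the N×N Hermitian matrix
H_mn = (1/M) Σ_l [σ_l/(2ρ_l)] Σ_i Ê*_{m,i}(r_l) Ê_{n,i}(r_l), computed as a
complex average; the classical amplitude/phase pair (β′, Ω′) is exposed as
|H| and arg H. Working with the complex average rather than separate
arctan-based phase bookkeeping avoids quadrant errors and makes Hermitian
symmetry and positive semidefiniteness structural. Voxels are equal
volume, so the plain voxel mean implements the volume average (no mass
weighting). The module's core test drives the form against brute-force
trigonometric superposition at 10⁻⁹ relative error.

## Excitation optimization

The ratio of two Hermitian forms is maximized exactly by the principal
generalized eigenvector of (H_tumor, H_healthy); `scipy.linalg.eigh` solves
the pencil, with a relative ridge on H_healthy as a fallback for singular
denominators. Because the ratio is invariant to overall amplitude and
phase, the solution is rescaled post hoc so ΣP_i equals the 8 W budget
exactly and rotated so antenna 8 has zero phase — matching the reporting
convention of the bundled reference table. The healthy region is all
non-tumor, non-air tissue (skin, fat, breast fat, gland, muscle). A seeded
differential-evolution search over (P, ϕ) confirms on every tested fixture
that no feasible excitation beats the eigen solution by more than 10⁻⁶
relative — the search documents optimality; it is never the solver.

## Bioheat solver

Explicit finite-volume forward Euler on the phantom grid: harmonic-mean
face conductivities (flux-conserving across tissue interfaces; exact
discrete energy conservation on insulated sink-free domains), Robin flux
h(T − T_ext) on tissue–air faces, insulation on the computational box
(the +x face is the chest side; the torso continues beyond it). Air voxels
are not solved. The perfusion sink is ρ_bC_bρHTR_SI·(T_b − T) for normal
tissues and C_b·ω(T)·(T_b − T) in the tumor, with ω evaluated explicitly
at the current temperature (at 37 °C, C_b·ω = 2.9 kW/m³/K, consistent in
magnitude with the muscle coefficient). The time step defaults to half the
per-voxel stability bound ρC/(Σ_f k_f/Δ² + n_air h/Δ + P_max); steps above
the bound raise rather than silently diverge. Benchmarks: uniform-medium
Pennes balance to <0.5%, 1-D Fourier-series slab transient to <1%.

Parameters not fixed by the study conventions: the convective coefficient
h defaults to 10 W/m²/K (typical effective natural convection with
radiative/evaporative losses lumped in) and the cool-down to 600 s; both
are configuration fields. Ambient and arterial temperatures are 25 °C and
37 °C; exposure is 1800 s.

## Pipeline and problem sizes

The default study runs at 3 mm voxels: phantom ≈ 30×53×53 cells, FDTD
domain ≈ 47×89×89 cells, eight unit-field solves ≈ 1–2 minutes total on
one core, thermal transient ≈ seconds. The radius sweep {2,…,12} mm offers
two modes: faithful (fields re-solved per radius, since the tumor's muscle
dielectrics differ from the gland it displaces) and fast (`reuse_fields`,
one solve on the largest-radius phantom shared across the sweep — an
approximation that only perturbs the dielectric contrast inside the tumor
sphere and leaves the thermal tumor model exact per radius). At 3 mm the
2 mm tumor is a single voxel; its statistics are correspondingly coarse.
Finer grids (down to 1 mm) are configuration choices with cubically
growing cost.

Determinism: phantom noise, the optimizer cross-check, and the pipeline are
seeded; regenerated reports are byte-identical.

## Known limitations

- The one-cell thin-wire model leaves a grid-dependent amplitude scale
  (few percent at 2.5 mm) and shifts the port impedance; port metrics are
  validated at band level, not to fractions of a dB.
- The eight-fold mirror symmetry of the array is not regression-tested
  (it would double the EM test cost); field correctness is covered by the
  analytic and Hertzian oracles instead.
- Explicit thermal stepping is simple and robust but wasteful for long
  exposures at fine grids; an implicit scheme would lift the Δ² step
  restriction.
- Absolute SAR/temperature magnitudes depend on the synthetic phantom's
  composition and the no-bolus air coupling; they characterize the method,
  not any patient.
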