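# Methods

This note records the models implemented in `monofilm`, the defaults they
ship with, the numerical choices behind them, and what the synthetic-data
generators do and do not emulate.

## Specular reflectivity

Reflectivity of a stratified interface is computed by the Parratt recursion
over interface Fresnel coefficients, with interfacial roughness entering as
Nevot–Croce damping `exp(-2 k_i k_j σ²)` on each coefficient. The momentum
transfer q is normal to the surface, in Å⁻¹; SLDs are complex Å⁻² with the
imaginary (absorption) part defaulting to zero. Nevot–Croce is accurate
while σ is small compared with the slab thicknesses — the fitted monolayers
have σ ≈ 3–4.2 Å against 6–16.5 Å slabs, comfortably inside that regime. A
micro-slicing fallback (`microslice=True`, default 0.5 Å slices of the
erf-broadened profile) exists for rougher interfaces; a regression test
keeps the two routes within 3 % at modest roughness. The roughness profile
is assumed error-function shaped, the standard choice where the original
analysis software does not state one.

Resolution smearing is Gaussian in q with FWHM = (dq/q)·q, evaluated by
17-point Gauss–Hermite quadrature. Model curves are smeared by evaluating
the exact model at the quadrature nodes (`smeared_reflectivity`); sampled
curves are smeared through a log-space interpolant with edge clamping
(`apply_resolution`). The neutron default is dq/q = 0.07 (time-of-flight
instruments); a per-point `dq` column (also FWHM) overrides the global
fraction when present. A brute-force numerical convolution oracle in the
test suite bounds the quadrature error at the 0.5 % level.

The test suite checks the engine against an independently coded
transfer-matrix (Abeles) implementation on random stacks; agreement is at
machine precision, far below the 10⁻⁸ requirement used in the acceptance
run.

## Two-slab monolayer model

A floating monolayer is air | tail slab | headgroup slab | subphase with a
single roughness σ at all three interfaces. The tail slab holds only the
hydrocarbon chains (C₁₃H₂₇ per myristoyl chain); glycerol backbone,
carbonyls, phosphate and the polar group belong to the headgroup slab. That
atom-level split is a choice, not a measurement — it is recorded in
`data/lipids.json` and editable without code changes. It is consistent with
treating carbonyl hydration as headgroup-region behaviour, which is how the
IR analysis reads it.

All per-molecule quantities are normalised per pair of chains; a four-chain
cardiolipin contributes two pairs, which keeps its parameters directly
comparable with the two-chain lipids.

Scattering length densities come from an embedded coherent-scattering-length
table (H, D, C, N, O, P, Na) and element counts; X-ray SLDs use
r_e = 2.818×10⁻⁵ Å times electron counts, with anomalous corrections
neglected (light elements at 12.5 keV). Water volume is fixed at 30.0 ų
(19.5 °C), configurable per call. ACMW is 8 % v/v D₂O in H₂O, giving a
neutron SLD within 0.01×10⁻⁶ Å⁻² of zero.

H/D exchange is an explicit scenario — a mapping from lipid name to the
number of labile headgroup hydrogens exchanged — and is *required* whenever
the subphase carries deuterium; it is never defaulted silently, because the
choice moves the derived headgroup volume by tens of ų. The registry stores
the chemical maxima (PG: 2 hydroxyls; PE: 3 ammonium hydrogens; CL: the
central hydroxyl); analyses of these films typically compare 0–2 exchanged
hydrogens for PG and 0–1 for PE, and both remain available because the data
alone cannot settle the PE count. Exchanged hydrogens take the subphase
deuterium fraction (1.0 in D₂O, 0.08 in ACMW).

The headgroup slab SLD is the linear volume mix of headgroup material and
subphase. By default the unsolvated material is taken to fill the
non-solvent part of the slab, V_hg = (1−f)·A_M·d_hg, which makes the slab
volume balance exact and lets `derive_structure` invert a fitted slab SLD
into V_hg and n_w in closed form; an explicit `V_hg_material` pins the
material volume instead. The derivation flags (rather than clips) solutions
where the implied hydration is negative beyond tolerance.

## Grid co-refinement and model selection

Reflectivity of a thin film cannot determine σ, V_tail, the thicknesses and
the solvation simultaneously from one curve, so the fit is a scan over fixed
(σ, V_tail) pairs — default grids σ = 3.0–4.5 Å (step 0.1) and
V_tail = 650–685 ų (step 2.5), bracketing the condensed-phase values these
lipids refine to. At each grid point d_tail, d_hg, the solvent fraction f
and one intensity scale per dataset are refined by bounded least squares
(trust-region reflective, 5 seeded starts by default) jointly across
contrasts; d_tail, d_hg, σ, the tail SLD (through V_tail and composition)
and f — hence n_w — are shared between contrasts, since they describe one
physical film. χ² = Σ((R_model − R_data)/dR)², with reduced χ² reported.
Points below 1.05× the subphase critical edge are excluded for
total-reflection contrasts (normalisation region), configurable.

Model selection: among grid points within a relative χ² band (default 2 %)
of the minimum, the one whose A_M lies closest to an independent reference
area — from diffraction for condensed phases, from the isotherm otherwise —
is selected, and both criteria are reported. The band plus area tie-break
makes an otherwise judgement-based two-criterion choice deterministic. For
PG- and CL-rich films the χ² surface versus V_tail is shallow, which is
exactly why the independent area matters.

Confidence ranges are Δχ² profiles (3.84 for 95 %, one parameter),
re-optimising the nuisance parameters at every profile point; ranges that
hit a parameter bound before crossing are flagged open-ended. Profiling was
chosen over posterior sampling because the reported quantities are
single-parameter ranges; a linear-model closed form validates the profiler
in the tests.

## GIXD

The q_z-integrated profile I(q_xy) is fitted with pseudo-Voigt peaks (the
stated instrument lineshape is a Voigt; the pseudo-Voigt weight is fitted)
on a linear background; candidates come from a median-noise threshold
(default 5σ) unless a peak count is given. Bragg-rod q_z positions are
fitted for all peaks *jointly*: the slice for peak j contains leakage from
peak k in proportion to the integral of k's fitted in-plane profile over j's
window (±3 FWHM), so the rods are modelled together as mirrored Gaussians —
symmetric under q_z → −q_z, as a 2D powder is — with the amplitudes and
offsets projected out linearly. The mirrored profile removes the
near-horizon bias of a plain Gaussian, and the joint fit removes the
Lorentzian-tail cross-talk that otherwise shifts rod centres by ~0.02 Å⁻¹.

Indexing: q_hk = 2π/d_hk; tilt by angle t toward in-plane direction û puts
the rod maximum of reflection G at q_z = tan t · (G·û). One peak on the
horizon is untilted hexagonal packing (A_chain = 2d²/√3). Two peaks are the
nearest-neighbour-tilt distorted hexagonal cell; the peak with the smaller
|q_z| is taken as {1̄1} and the cell follows in closed form. Three peaks are
an oblique cell, solved by a bracketed 1D root search in tan t over label
permutations and sign choices, enforcing the reciprocal-triangle closure
G₁̄₁ = G₀₁ − G₁₀; the permutation with the smallest closure residual wins and
an inconsistent peak set raises an indexing error carrying that residual.
Cell areas come from the reciprocal cross product A = (2π)²/|G₁₀ × G₀₁|;
A_pair = 2A_chain, A_xs = A_chain·cos t. Tilts below q_z ≈ 0.05 Å⁻¹ in rod
position (about 2° for these lattices) are reported as untilted — the
mirrored-rod fit cannot resolve centres closer to the horizon than that.
The tilt azimuth is only defined up to lattice symmetry for a 2D powder, so
round-trip validation compares d-spacings, area, tilt and regenerated peak
positions, not the raw azimuth.

Excess mixing areas are A_mix − Σ xᵢAᵢ, with mole fractions convertible to
chain fractions (cardiolipin counts four chains) when the component areas
are per chain.

## Isotherms

C_s⁻¹ = −A_M (∂Π/∂A_M) is evaluated by centred differences on a uniform
resampling of the area axis, optionally after local-cubic (Savitzky–Golay,
default window 9) smoothing; raw differentiation is available. Transition
extraction works on the compressibility modulus: the coexistence plateau is
the longest low-modulus run (default threshold 15 mN m⁻¹) bracketed by
sustained stiffer branches (median test over adjacent windows, which is what
makes the detector ignore the zero-pressure lift-off region and isolated
noise spikes). The Lₑ–L꜀ onset is the intersection of tangents fitted to the
liquid-expanded branch and to the plateau — an operational definition,
recorded here because published onset pressures rarely state one — and the
L꜀–S kink is the breakpoint of a two-segment broken-line fit over the
condensed region, accepted only when the solid branch is at least 1.4×
steeper. Absent features are reported as absent, never fabricated. Both
criteria are invariant to rescaling the area axis. Area cleaning drops
barrier-reversal points so compression is strictly monotone.

## Electrochemistry

Potential-step transients integrate (trapezoid) to the charge flowing
between each potential and the shared desorption state, so the relative
charge density is minus that integral. Absolute referencing anchors the
desorbed state so that the *bare* curve crosses zero exactly at the bare
pzc; the film curve shares the same desorbed-state anchor because the film
is desorbed at the step potential. (The alternative — offsetting the film
curve at the bare pzc directly — is not equivalent and is not used; the
shared-desorbed-state convention is the one implemented.) The pzc of any
curve is the zero crossing nearest the positive limit, linearly
interpolated, with a warning when several crossings exist.

Film pressure is the Lippmann double integral Π(E) = ∫(σ_film − σ_bare)dE′
from the desorption potential, film interpolated onto the bare grid, with
the exact unit constant 1 μC cm⁻²·V = 10 mN m⁻¹ (unit-tested). Π is zero at
the desorption potential by construction and dΠ/dE returns the charge
difference, the zero-frequency capacitance view of the same data. Lock-in
capacitance uses the series-RC inversion C = (i_ip² + i_q²)/(ω·ΔE·i_q),
which reduces to i_q/(ω·ΔE) for a purely capacitive cell; a non-positive
quadrature component is rejected rather than inverted. Potentials are
stored as given — reference-electrode shifts are metadata, not automatic
conversions. Cathodic currents are negative; σ_M is positive above the pzc.

## Synthetic-data generators

All generators take a seed (NumPy PCG64; identical seed ⇒ bit-identical
output, platform-stable) and return the dataset plus a truth record that the
recovery tests consume directly. Noise models, chosen because the source
measurements do not state any: multiplicative Gaussian with σ = noise_rel·R
for reflectivity (counting statistics at high rates; dR is the σ actually
used), Poisson counts for diffraction images, additive Gaussian for
isotherms and current transients.

* Reflectivity: forward two-slab model → 7 % dq/q smearing → noise, over
  q = 0.018–0.6 Å⁻¹ (120 points), matching the measured range.
* GIXD: pseudo-Voigt(q_xy) × mirrored-Gaussian(q_z) peaks from a specified
  2D cell on a smooth background; default FWHMs 0.02 Å⁻¹ in-plane and
  0.25 Å⁻¹ along the rod; azimuth defaults to the nearest-neighbour (a+b)
  direction so the canonical two-peak pattern appears.
* Isotherms: piecewise-linear branches (liquid-expanded, plateau,
  condensed, solid) with rounded corners; defaults place the plateau at
  12 mN m⁻¹, the kink at 27 mN m⁻¹ and the solid phase near 40 Ų with
  C_s⁻¹ ≈ 240 mN m⁻¹, the regime these myristoyl films occupy.
* Chronocoulometry: two ideal capacitors (film 2, bare 25 μF cm⁻²) with
  state-dependent pzc; each step is a single exponential with τ = R·C_bare
  on a geometric time grid (a uniform grid at 600 samples per 0.15 s pulse
  undersamples the 0.25 ms decay and biases trapezoidal charges by ~8 %).
* IR: pseudo-Voigt band envelopes for the C=O doublet (H-bonded 1728 /
  free 1742 cm⁻¹) and the C–H region including Fermi-resonance components.

What the generators deliberately do not emulate: beam-damage drift, Yoneda
wings and diffuse background in scattering images, adsorption/desorption
hysteresis and kinetics in the electrochemistry (the capacitor film stays
adsorbed at every potential, so generated film pressures at very negative
potentials exceed what a desorbing bilayer shows), multilayer collapse in
isotherms, and PM-IRRAS optics (the random-orientation reference absorbance
is an input, computed externally). Passing recovery tests therefore
demonstrate correctness of the inference chain under the stated noise
models, not robustness to every instrument artefact in real data.

## IR band analysis

Bands are pseudo-Voigt on a linear baseline, centres constrained within
±8 cm⁻¹ of their templates; the solvated-carbonyl fraction is
area(H-bonded)/area(total C=O). Fermi-resonance components in the C–H
region are fitted as extra bands and excluded from the tilt algebra. Chain
tilt uses the metal-surface selection rule cos²θ = A/(3·A_random) per CH₂
mode and closes the orthogonal triad with cos²t = 1 − cos²θ_sym − cos²θ_asym
(exact by construction); isotropic input reproduces the magic angle 54.7°,
and cos²θ = 0.01 on both modes gives t ≈ 8.1°. The factor 3 is the standard
isotropic-reference convention; if a reference computed under a different
normalisation is supplied, the measured/random ratio must use the same one.
Implied cos² values outside [0, 1] raise rather than clip.

## Problem sizes in the standard runs

The shipped tests and the acceptance script use 100 random stacks for the
reflectivity oracle, 20 seeded co-fit replicates (two contrasts, 120 q
points each, single grid point, 3 starts), 50 random cells plus
400×180-pixel noisy maps for diffraction, 20 isotherm seeds at σ_Π = 0.15,
and 29-step chronocoulometry sequences — sizes at which every stage's
recovery error is measured well below its tolerance while the whole chain
re-runs in seconds.
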