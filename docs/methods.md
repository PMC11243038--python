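# Methods

This note documents the models implemented in `rrsolv`, the choices made
where several conventions exist, and what the synthetic data generator does
and does not emulate.

## Scope and overall design

`rrsolv` is a desk-scale re-implementation of the computational chain used
to model the optical spectra of a hydrogen-bonded chromophore (the running
example is caffeine-like) in water:

1. solvated-sphere snapshot ensembles (synthetic, with planted structure),
2. geometric solvation analysis (RDFs, running coordination numbers,
   hydrogen-bond statistics),
3. fluctuating-charge (FQ) polarizable embedding of the solvent,
4. UV-Vis / spontaneous Raman / resonance Raman (RR) spectra with ensemble
   averaging, RR excitation profiles (RREP) and enhancement factors.

No molecular dynamics and no electronic-structure calculations are
performed anywhere: frames are stochastic constructions and all
excited-state data (energies, transition dipoles, gradients) are inputs,
generated synthetically with known ground truth.  This is deliberate: every
downstream algorithm can then be verified against planted values or
independent oracles instead of against unavailable quantum-chemistry
output.

## Synthetic data generator

**Solvated frames.**  A rigid multi-site solute sits at the center of a
sphere (default radius 17 Å) filled with rigid 3-site waters
(O–H 0.9572 Å, H–O–H 104.52°, the standard 3-site geometry; configurable).
Oxygen–oxygen exclusion defaults to 2.4 Å.  A requested number of waters is
*planted* in hydrogen-bonding geometry at chosen acceptor sites: distance
drawn uniformly in [2.6, 3.4] Å and acceptor angle in [0°, 25°], safely
inside the geometric H-bond criterion d(X···Ow) ≤ 3.5 Å,
θ(Hw–Ow–X) ≤ 30°.  All remaining waters are uniform in the sphere but
rejected from every acceptor's acceptance sphere (guard radius 3.55 Å), so
the planted H-bond count is exact ground truth, not an expectation value.
Trajectories are rigid-body perturbations (Gaussian translation + rotation
per water, scale = `jitter`) of a base frame with rejection of any move
that would break an invariant; `jitter=0` reproduces the base frame
bit-identically.  Randomness uses one master seed with counter-based
substreams (`SeedSequence(seed, spawn_key=(i,))`) so frame *i* is
reproducible in isolation.

**Chromophores.**  A harmonic model carries orthonormal mass-weighted
normal modes, frequencies, Raman polarizability-derivative invariants and a
list of excited states.  Excited-state Cartesian gradients are constructed
by inverting the projection used by the spectra engine, so the
dimensionless displacements Δ_k are planted exactly.  The packaged
caffeine-like default has nine modes at the frequencies of the vibrations
tracked in the enhancement analysis (1049–1624 cm⁻¹), an S1 state placed so
the low-energy absorption band peaks at 267 nm and a cluster of three
higher states producing the stronger band near 206 nm.  Its displacements
and Raman invariants are synthetic: band *positions* are calibrated to the
real system, intensities are not.

**Ensembles.**  Snapshot-to-snapshot variability is modeled as independent
Gaussian jitter of excitation energies (default σ = 500 cm⁻¹), mode
frequencies (σ = 5 cm⁻¹) and gradients (5% multiplicative), with the
production ensemble size fixed at 200 snapshots.  The true
snapshot-to-snapshot distribution of a solvated chromophore is not
characterized by any data we consume, so normality and these magnitudes are
modeling choices; they control the inhomogeneous broadening and the
convergence behavior but nothing else downstream.  Consequently, passing
tests demonstrate the correctness of the analysis chain on data with this
statistical structure — they do not validate the noise model against real
solvent dynamics.

## Solvation analysis

RDFs are computed on finite spheres, not periodic boxes: g(r) is only
defined for r ≤ R/2 (requests beyond that margin are rejected), and the
bulk density is estimated from the mean solvent count inside the R/2 ball
around the solute centroid.  This avoids shell-truncation bias without
analytic sphere-intersection volumes; the cost is that the accessible r
range is half the sphere radius.  Histogram bin width defaults to 0.05 Å.

Running coordination numbers integrate n(r) = ρ ∫ 4πr′² g(r′) dr′ by
trapezoidal quadrature on the bin grid; the first-shell value is n(r_cut)
with r_cut a configuration parameter (the integration bound used for the
published site-resolved values is not printed anywhere we consume, so it is
deliberately not hard-coded).  Site-resolved first-shell values add to a
total water budget (`aggregate_first_shell`); "around the carbonyl oxygens"
is read as the summed coordination of both O sites.

H-bond detection emits one record per qualifying (acceptor, water, H)
triple; the per-frame count de-duplicates to distinct (acceptor, water)
pairs by default (a water-contact count), with the every-hydrogen
convention switchable (`count_mode="record"`).  For rigid 3-site waters
both hydrogens of one water can never qualify simultaneously at a single
acceptor (they are 104.52° apart and the cutoff is 30°), so the two
conventions differ only in exotic multi-acceptor geometries.

## Fluctuating charges

Charges minimize E(q) = χᵀq + ½qᵀJq + qᵀV_ext under one total-charge
constraint per water, solved as a bordered symmetric linear system.
Conventions: J_ii = 2η_i (self-energy η_iq_i²); off-diagonal interactions
default to the Ohno-damped kernel 1/√(r² + c_ij²), c_ij = 2/(η_i+η_j),
which removes the polarization catastrophe at H-bond distances and tends to
the hardness scale at r → 0; bare Coulomb is selectable.  The shipped χ/η
defaults are a Rick-style water parametrization converted from kcal/mol;
they are configuration inputs and no test depends on their values — all FQ
tests use symmetry, variational and oracle properties.  Only the solvent is
polarizable; the solute enters as fixed point charges.  There is no
QM↔FQ self-consistency loop because there is no QM region.

The reaction potential of the solved charges at probe points uses the bare
Coulomb kernel by default (the potential a quantum solute would feel from
classical point charges).  Solvatochromic shifts are linear response:
Δε = Σ_a (q_a^ex − q_a^gs) V(r_a), with ground/excited solute charge sets
supplied by the caller.

## Spectra engine

**VG|FC / IMDHO.**  The excited surface is the ground-state harmonic
surface displaced along the excited-state gradient; modes and frequencies
are shared, Duschinsky rotation is absent by construction, and transition
dipoles are geometry-independent (no Herzberg–Teller terms).  Projection:
g_k = L_kᵀM^(−1/2)∇E, Δ_k = −g_k/ω_k^{3/2} in atomic units, S_k = Δ_k²/2.
The adiabatic origin is ε₀₀ = ε − Σ_k S_kω_k, which keeps the
vertical-gradient surface self-consistent.

**RR amplitudes.**  Time-independent sum over vibronic states with
Franck–Condon overlaps from the stable two-term recursion
(⟨0|0⟩ = e^{−S/2}); only fundamentals (0→1) are computed, matching the
reported assignments — no overtones or combinations.  The multimode sum is
truncated at 10 total quanta plus a per-term weight cutoff of 1e-10 (both
configurable); a per-mode completeness deficit is used as a tail bound and
raises a warning when above 1e-8.  The damping Γ (default 200 cm⁻¹) is the
imaginary term in the resonance denominators, i.e. a homogeneous
HWHM-type constant; this convention is named in the config because others
(FWHM, Gaussian σ) exist in the literature.

An independent oracle evaluates the same amplitude as a damped
half-Fourier integral of the closed-form IMDHO correlation function,

α_j(ω₀) = iμ² ∫₀^∞ dt e^{i(ω₀−ε₀₀)t−Γt} (Δ_j/√2)(e^{−iω_jt}−1)
Π_k exp[S_k(e^{−iω_kt}−1)],

by composite Simpson quadrature refined to 1e-8 relative.  The two routes
are algebraically identical (generating function
Σ_v⟨1|v⟩⟨v|0⟩z^v = (Δ/√2)(z−1)e^{S(z−1)}) but numerically independent;
agreement to better than 1e-6 relative across resonance and pre-resonance
excitation is enforced by tests.

**Cross-sections and intensities.**  σ_j ∝ ω₀ω_s³|α_j|² with ω_s = ω₀−ω_j
and a single package-wide prefactor; the absolute experimental unit
(cm² cm mol⁻¹ sr⁻¹) is not reconstructed, so every reported enhancement
factor is a prefactor-free ratio.  Spontaneous Raman sticks use the Placzek
activity 45a′² + 7γ′² with a 1/ω_k harmonic amplitude factor and the same
prefactor and incident frequency convention (ω₀ = 1064 nm by default;
vacuum conversion 10⁷/λ throughout, 266 nm → 37 593.98 cm⁻¹).

**Broadening and averaging.**  UV-Vis bands are oscillator-strength-
weighted Gaussians of FWHM 0.6 eV on the vertical excitation sticks; Raman
and RR sticks are convolved with unit-area Lorentzians (or Gaussians) of
FWHM 8 cm⁻¹.  Ensemble averages of convolved spectra are pointwise means
on a common grid; stick spectra with snapshot-jittered positions are
averaged mode-by-mode (`average_sticks`).  Both orders — convolve-then-
average and average-then-convolve — are available; on a common axis they
commute exactly (linearity), and the pipeline convolves the mode-averaged
sticks.  Spectral convergence is quantified by the normalized overlap
integral between prefix averages and the full-ensemble average.

**Excitation profiles.**  The RREP grid defaults to 15 points uniform in
wavenumber over 30 000–65 000 cm⁻¹ (only a subset of the published grid
wavelengths is known, so a uniform wavenumber grid is used).  An IMDHO
absorption line shape built from the same Δ, ω, ε₀₀ as the RR engine serves
as the internal consistency partner: profile maxima must track
absorption-band maxima within one grid step, which is the mechanism behind
choosing excitation wavelengths at the absorption maxima.

**Short-time diagnostics.**  `shift_intensity_check` reports the Spearman
correlation between ω_k²Δ_k² and RR stick intensities.  Far below
resonance (flagged at ω₀ < ε₀₀ − 5Γ) the fundamental amplitudes reduce to
α_j ∝ ω_jΔ_j and the correlation is exactly 1; at strict resonance
multimode interference can break the ordering, so the correlation is
reported, not asserted.

## Numerical choices and degenerate inputs

* Water rigidity is validated to 1e-8 Å / 1e-6° on every frame
  construction; XYZ round trips hold coordinates to 1e-10 Å.
* Packing failures (too many waters for the exclusion distance, or an
  unplaceable planted water) raise explicit errors naming the constraint
  after a bounded number of rejection attempts.
* The FQ bordered system is solved directly; a residual above 1e-8
  (relative) or a singular factorization raises an error carrying a
  condition estimate.  Coincident sites are rejected for the bare kernel.
* Zero-displacement states give exactly zero RR amplitude (no spurious
  numerical floor); modes with degenerate frequencies are allowed in stick
  containers and ranked-correlation ties are reported as undefined rather
  than coerced.
* Enhancement ratios with a zero Raman denominator are NaN (undefined),
  never infinite.

## Problem sizes

Default pipeline and test sizes are chosen for interactive desk use: 120
waters per frame, 20 frames, 20-snapshot spectral ensembles, 10 snapshots
for excitation profiles; the convergence and statistics checks use 200
snapshots / 200 frames and ~1e5 pair samples, where the relevant law (CLT,
χ², overlap convergence) is already sharply resolved.  Full production
conditions (200-snapshot spectra everywhere) run in minutes rather than
seconds and change no conclusion of the test suite.

## Known limitations

* Frames are stochastic, not dynamical: no kinetics, no H-bond lifetimes,
  no velocity correlations.
* The solute is rigid and classical; solute flexibility, charge
  penetration and mutual QM/solvent polarization are absent.
* Synthetic intensities (Raman invariants, displacements) are not
  calibrated to any real chromophore, so absolute synthetic enhancement
  factors are not comparable to measured ones; only the packaged reference
  table carries physical cross-sections.
* The finite-sphere RDF normalization limits g(r) to r ≤ R/2 and assumes
  near-central solute sites; strongly off-center sites would need
  sphere-intersection corrections.
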