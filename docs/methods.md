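# Methods

This note documents the physical model, its parameters and the deliberate
approximations behind `xspidam`. Everything quantitative below is computed
by the package (tests or `scripts/acceptance.py`); nothing is transcribed
from elsewhere.

## Samples

`build_toy_protein` generates a compact globular pseudo-protein: atoms
placed uniformly in a ball (default radius 20 Å for 800 atoms, which
reproduces the heavy-atom number density of a ~70 Å protein) with a hard
minimum pair distance of 1.2 Å, elements drawn from the 2NIP heavy-atom
stoichiometry C:N:O:S:Fe = 2712:735:859:46:4. Two allocation modes exist:
`multinomial` (a random draw, the statistical default) and `exact`
(largest-remainder rounding). The pipeline uses `exact` so the rare species
(8 S, 1 Fe at 800 atoms) are always present — with a multinomial draw Fe
(expected count 0.73) would be absent from roughly half the realizations,
and the heavy-atom ionization ledger would be undefined for them.
`load_pdb` (backed by gemmi) accepts a real structure instead; water
residues are dropped and everything else is labelled protein.

The water tamper is geometric, not equilibrated: oxygens are placed at
liquid density (0.0334 molecules/Å³) wherever the distance to the nearest
protein atom lies in (r_contact, r_contact + thickness], r_contact = 2.8 Å,
with a hard 2.6 Å O–O core, and dressed with two rigid-geometry hydrogens
(0.9572 Å, 104.52°) in a random orientation. The damage and diffraction
observables depend on the amount and radial position of the water, not on
its hydrogen-bond network, so skipping force-field equilibration keeps the
pipeline self-contained; the price is the loss of realistic short-range O–O
structure (a ~3% effect on the water elastic term at the resolutions probed
here, and none on the component-selected analyses, which exclude it).

## Atomic data

`data/atomic_data.yaml` ships everything the ionization and scattering
models need for H, C, N, O, S, Fe:

* **Elastic form factors** — 4-Gaussian Cromer–Mann fits from the standard
  crystallographic compilations, rescaled at load time so f₀(0) = Z exactly.
  Ions use f_ion(q) = f₀(q) − (Z − n_bound)·exp(−b_v s²) with b_v the most
  diffuse Gaussian of the fit (the valence profile); this pins
  f_ion(0) = n_bound and captures the leading low-q suppression of damaged
  atoms. It replaces per-configuration ab-initio ionic form factors; the
  error is concentrated at q ≳ 1 Å⁻¹, beyond this detector's corner.
* **Incoherent (Compton) functions** — grids generated from the same fits
  via S(s) = Z(1 − (f₀(s)/Z)²); exact for hydrogen, a few-percent-level
  approximation for heavier species at the small s probed here (s ≤ 0.1).
  Ions scale S by n_bound/Z.
* **Photoionization** — per-subshell cross sections tabulated at 5 keV
  (XCOM-scale values), scaled within the shipped 4–6 keV window by the
  photoelectric E⁻³ law, with per-electron proportionality in the occupancy
  and a hard threshold at the subshell binding energy (Fe 1s at 7.1 keV is
  closed at 4.96 keV, so iron ionizes through its L/M shells).
* **Binding energies** — neutral-atom subshell values. Charge-state shifts
  of the levels are *not* modelled; this makes deep sequential ionization
  slightly too cheap, which matters only in the strong-plasma regime, not
  at the single-digit mean charges of this study.
* **Auger decay** — one effective core-hole lifetime per element (6.6, 5.1,
  4.1, 1.1, 0.55 fs for C, N, O, S, Fe, from tabulated K-level widths).
  The decay takes the two least-bound electrons (filler + emitted), giving
  e.g. a 262 eV C KLL electron; atoms without two outer electrons relax
  radiatively. Fluorescence branching is folded into a single parameter
  (default: pure Auger), since the charge budget, not the photon budget,
  drives the observables.
* **Electron impact** — binary-encounter-Bethe (BEB) cross sections per
  subshell, with mean kinetic energies set to U = 1.3·B (stored explicitly;
  the model's observables are insensitive to U at the tens-of-percent
  level).

## Damage dynamics

One trajectory covers 26 fs in 963 steps of 0.027 fs (Δt = 0.27 fs = 10
timesteps is the diffraction binning), recording 100 snapshots, the first
pristine. Each step interleaves:

1. **Photoabsorption** — per atom, probability 1 − exp(−σ_ph φ dt) with φ
   the instantaneous flux (pulse photons per cm² in the bin, focus area =
   FWHM_x·FWHM_y); subshell chosen ∝ partial cross sections; photoelectron
   launched isotropically with KE = hv − B. Isotropy is justified by the
   observation that polarization effects on charge/displacement observables
   are negligible in this geometry.
2. **Auger clocks** — exponential decay per registered core hole.
3. **Collisional ionization** — for every active quasi-free electron, atoms
   whose centers lie within a cylinder of radius r_c = 5 Å around the
   step's path segment are tested with per-pair probability σ_BEB/(π r_c²),
   which reproduces the kinetic-theory rate nσv exactly (verified against
   that oracle in the tests); the first triggered atom on the path loses
   its least-bound electron. The energy KE − B is split between the pair by
   the asymmetric binary-encounter spectrum dσ/dW ∝ 1/(W + B)² ("mott"
   mode, the default): the physically standard strongly-peaked secondary
   spectrum, under which fast primaries keep most of their energy and
   leave the finite sample — the mechanism that keeps heavy-atom
   collisional ionization at the few-percent level. A flat split
   ("uniform") is available; it overpopulates the trapped 100–300 eV
   window where the BEB cross section peaks and roughly quadruples the
   cascade yield.
4. **Recombination** (default on) — an electron within 1 Å of an ion with
   negative pair energy is captured into the least-bound vacancy. Switch
   off (`recombination=False`) for monotone-charge audits.
5. **Motion** — velocity-Verlet for ions and active electrons under
   pairwise softened Coulomb forces, F ∝ r/(r² + a²)^{3/2} with a = 0.5 Å
   (regularizes close encounters at this timestep; symplectic energy
   conservation is verified to <0.1% over 1000 steps on an orbiting pair).
   Neutral atoms feel no force. Electrons beyond 3× the sample bounding
   radius with positive total energy are removed and counted in the escape
   ledger. Electron speeds are non-relativistic (≤1% error at 4.7 keV).

Charge bookkeeping — Σ(ion charges) − (active electrons) − (escaped) = 0 —
is exact at every step and asserted at every snapshot in the tests.
Omitted physics: elastic electron–atom scattering, electron–electron
collisions beyond the mean Coulomb force, excitation (non-ionizing) energy
loss, plasma screening beyond the explicit particles, and bond chemistry.
The first three mean cascade multiplicities are, if anything, slightly
overestimated.

## Pulses

SASE pulses are surrogates: a Gaussian envelope (FDHM 9 fs) times the
squared magnitude of complex Gaussian noise low-pass filtered to a 0.25 fs
coherence time, rescaled to 5·10¹¹ photons. This preserves the statistical
feature that matters for ionization dynamics — the spiky sub-femtosecond
intensity structure varying shot to shot — without wavefront propagation.
The ensemble default is 55 profiles used cyclically; alignment puts the
peak of the summed profile at t = 0. Fluence is photons × photon energy /
(FWHM_x·FWHM_y) and peak intensity fluence/FDHM; the defaults give
9.9·10⁵ J/cm² and 1.1·10²⁰ W/cm². The coherence time is a configurable
assumption, not a reproduction of any particular machine.

## Diffraction

The detector is a flat 81×81 array of 1200 μm pixels at 13 cm, beam center
on the central pixel; per-pixel Ewald scattering vectors, solid angles
Ω = A cos³θ/d², and Thomson factors r_e²(1 − sin²θ cos²φ) for horizontal
polarization. Full-period resolution is 7.1 Å at the edge center and 5.2 Å
at the corner. Pixel q is evaluated at the pixel center (no oversampling —
the geometry is deliberately coarse). Compton scattering is carried at the
Thomson cross section with no wavelength shift, consistent with the
time-integrated counting model.

Patterns integrate the bracketed model over Δt = 0.27 fs windows,
associating each window with the nearest recorded snapshot and weighting by
the window's incident fluence (window photons over the focus area), so
pixel values are expected photon counts on an absolute scale (the R metric
itself is scale invariant). Component flags (protein elastic, water elastic,
bound Compton, free electrons) choose what is summed; "subtracting the
water elastic term" is implemented as never summing it. The elastic term
is evaluated incrementally: neutral atoms never move in this model, so
F(t) = F(pristine) + corrections over the ionized/displaced subset only —
algebraically identical to the direct sum (verified to 10⁻¹⁰ relative) and
~50× faster at the 100-snapshot integration. Pipeline patterns use
single-precision phase evaluation (float32, ~10⁻⁶ relative error on R);
tests pin exactness in double precision.

## R-factor analysis

R(D) uses the cumulative region q ≤ 2π/D exactly as the metric is defined
(not per-shell), on a log grid of 28 points from 5 to 60 Å. The ideal
reference is the elastic-only pattern of the static neutral protein at the
same orientation and pulse; a flag can add the undamaged bound-Compton
term (whether the published comparisons included it is ambiguous — both
options are implemented, the default is elastic-only, and the combined
component set therefore retains a small inelastic-background floor even at
zero fluence). Orientation averaging is over the shared quaternion list
(Shoemake-uniform on SO(3)); the spread is the population standard
deviation (divisor N). The regime summary compares band-averaged mean R in
the high-resolution band (D ≤ 10 Å) and low-resolution band (D ≥ 20 Å) and
flags the thin-best-at-high-res / thick-best-at-low-res interchange.

## Experiment orchestration and seeds

The desk-scale experiment defaults to a 800-atom toy particle, thicknesses
{0, 2, 4, 6, 10, 20} Å, 20 trajectories per thickness with one pattern
each (orientation list length 20, shared across thicknesses), the
55-profile pulse ensemble taken cyclically, and facility-scale beam, detector
and fluence-per-atom. Full-scale values (PDB input, 1000 trajectories, 20
patterns each) are ordinary config values.

Seeds derive from the master seed per (role, index) via
`numpy.random.SeedSequence`: pulse realizations, base orientations and
damage streams are keyed by trajectory index only — *not* by thickness — so
thickness comparisons run under common random numbers. This pairing is the
desk-scale substitute for brute-force replication: thickness contrasts are
then differences of correlated estimates, with far smaller Monte-Carlo
variance than independent seeding would give. Water placement is the one
role keyed by thickness (each shell is a different object).

## What the synthetic data do and do not show

The generator reproduces: the element stoichiometry and density of a small
Fe/S protein, liquid-density water shells of controlled thickness, the
per-atom fluence, spectrum-integrated ionization rates and spiky pulse
statistics of a modern SPI beamline. It does not reproduce: real secondary
structure (no speckle detail of a specific protein), equilibrated water,
charge-state-resolved level shifts, or the ~5000-times larger replication
of a facility-scale campaign. Quantities that survive this reduction —
identities of the fidelity metric, beam bookkeeping, mechanism fractions,
and the direction of thickness trends — are asserted in the tests;
pointwise curve values are not claimed to transfer. One regime caveat: at
this sample size and fluence nearly all energetic electrons escape, so the
quasi-neutral-core/charged-shell structure only develops at elevated
fluence; the corresponding test exercises that regime explicitly (10×
photons on a smaller particle) because the property belongs to the strong
-ionization regime, not to these exact beam parameters.

## Numerical choices and limitations

* Timestep 0.027 fs (Δt/10); soft-core a = 0.5 Å; escape radius 3× bounding
  radius; collision cylinder r_c = 5 Å; capture radius 1 Å — all
  configurable on `PhysicsParams`.
* Neighbor search trees refresh every 20 steps (atom drift per refresh is
  ≪ r_c).
* The toy generator's hard-core placement is rejection sampling; it fails
  loudly (suggesting a larger radius) rather than degrading density.
* Desk problem sizes (800 atoms, 20 trajectories, 60-trajectory mechanism tallies pooled over 5 particle
  realizations) were chosen as the package's own balance of Monte-Carlo error
  against single-CPU turnaround; they are config values, not constants.
* Known limitations: no detector noise or response model (off-path Poisson
  sampling only), no phase retrieval/orientation recovery, no nanocrystal
  periodicity, no resonant (f′, f″) corrections.
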