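# Methods

`nanocg` implements a two-resolution model system for the interaction of
coated gold nanoparticles (NPs) with proteins: a 19-bead coarse-grained (CG)
NP and a single-sphere mesoscale (MS) NP, both coupled to a one-bead-per-
residue ("minimalist") protein with implicit solvent.  This note documents
the models, the parameter choices and their rationale, the numerical
decisions, and what the synthetic data used in the tests does and does not
demonstrate.

## Units

Lengths are Å, time ps, mass kDa, charge e, and energy kT at the force-field
reference temperature (300 K by default).  The Boltzmann constant in these
units (8.3145e-4 kDa Å² ps⁻² K⁻¹) converts reduced energies to mechanical
ones inside the integrators.

## Interaction model

The total energy is a sum over inter-body bead pairs of a hydrophobic/steric
term and a screened electrostatic term,

    U = Σ_{i>j} u_hs(r_ij; ε_ij, r0_ij) + Σ_{i>j} l_B q_i q_j exp(-r_ij/λ)/r_ij .

* `u_hs` is a 12-6 well, ε[(r0/r)¹² − 2(r0/r)⁶], parameterized by the
  minimum position r0 and depth ε.  The 12-6 form is the standard analytic
  choice for an (ε, r0) pair parameterization.
* Electrostatics is Debye–Hückel: the Bjerrum length l_B is computed from
  physical constants (7.10 Å at 300 K, εr = 78.5, never hard-coded), and the
  screening length λ from the ionic strength (17.6 Å at the working
  condition of 30 mM).
* Both terms are shifted to zero at the cutoff (default 30 Å — comfortably
  beyond λ at 30 mM) so forces are continuous there.
* Mixing: r0 = (σ_i+σ_j)/2 and ε = sqrt(ε_i ε_j) ("linear combination
  rule"); per-pair (r0, ε) overrides are supported and used by the σ
  calibration loop.

Residue beads use a per-letter species table: σ = 5 Å, hydrophobicity index
h from the Kyte–Doolittle scale rescaled to [0, 1] (the scale is
configurable; the index "can be defined in different ways"), well depth
ε = 0.1 + 0.9 h kT so hydrophobic residues attract at ~1 kT and polar ones
are mostly steric, formal charges K/R +1, D/E −1, H neutral (pH 7), and
mass 0.12 kDa (a 12 kDa protein divided by its 99 residues).

### MS nanoparticle

The MS NP is a single sphere of diameter 15 Å, mass 7.4 kDa, hydrophobicity
index 1 and charge −1 e placed at its centre.  Pairs involving the MS NP
take their well depth from the hydrophobicity indices, ε = k·h_i·h_NP, with
a single global coupling constant k.  The default is k = 4 kT: with k near
1 kT the NP–NP well barely exceeds thermal energy and no aggregation occurs,
whereas the ensemble phenomenology this model targets — a fast initial
potential-energy drop, stable NP-core aggregates with proteins attached, a
strong NP–NP contact peak at the NP diameter — requires a several-kT
hydrophobic attraction, as expected for a phenyl-coated particle.  k is a
config field, not a constant.

### CG nanoparticle

The CG NP is one AU core bead plus 18 ligand (CS) beads split into 12 inner
(CSi) and 6 outer (CSo) classes.  Bead σ/ε defaults are calibrated on the
synthetic reference fixture and marked as such in the serialized model:

* CS beads: σ = 7 Å (twice the 3.5 Å van-der-Waals radius of the coating
  group), ε = 1.2 kT and h = 0.81, both phenylalanine-like since the coating
  is chemically analogous to a phenylalanine side chain.
* AU bead: σ = 15 Å, ε = 1.0 kT, h = 0.  The AU bead stands for the whole
  gold core including its near field, so its contact distance is the NP
  diameter; two CG NPs then meet at the same separation as two MS NPs, which
  is where the ensemble NP–NP g(r) contact peak sits for both resolutions.
* Charges: AU +5, CSi −0.3125, CSo −0.375 (net −1 e exactly).  These are
  the per-bead sums of the fixture's RESP-like atomic charges; the values
  are chosen as exact binary fractions so charge bookkeeping is exact in
  floating point.

## Building the CG NP from reference data

The build pipeline consumes a labeled "atomistic-like" trajectory (core
atoms + ligand representative CS atoms, with per-atom charges and masses):

1. **Alignment** — every frame is superposed onto frame 0 by least-squares
   (Kabsch) rotation over the core atoms only; the core centroid is moved to
   the origin.  At least 3 non-collinear core atoms are required.
2. **Volume map & clustering** — all CS positions are accumulated on a 0.5 Å
   voxel grid; voxels above 5% of the maximal occupancy are clustered by
   count-weighted k-means (k-means++ seeding, fixed seed, 10 restarts) into
   18 sites.  The voxel/threshold/k-means triplet is one concrete choice of
   "volume map + centroids"; any density-based partition of the occupied
   volume would serve.
3. **Classification** — the 6 radially outermost sites are outer (CSo), the
   other 12 inner (CSi); ties break by stable input order.  On the ideal
   octahedral geometry the vertex/edge-midpoint radial ratio is √2.
4. **Charges** — bead charge = exact sum of constituent atomic charges
   (core atoms → AU, CS atoms → nearest site by trajectory-mean position).
5. **Masses** — lumping all core mass on the point-like AU bead
   underestimates the moment of inertia, so the shared CS mass is raised and
   the AU mass lowered until the *trace* of the CG inertia tensor matches
   the trajectory-averaged reference value, under exact total-mass
   conservation.  Matching the trace (one scalar) is the most the two free
   parameters (m_CS shared, m_AU) can support; CS masses are kept equal
   across both symmetry classes because a single trace constraint cannot
   distinguish them.  The COM shifts slightly with the masses, so the
   one-unknown problem is solved by a fixed-point iteration (converges to
   1e-12 in a few steps); an infeasible target (AU mass would go negative)
   raises a diagnostic error.

### σ calibration by RDF matching

`tune_sigma` matches the first-peak positions of the inter-body CS–CS,
CS–AU and AU–AU radial distribution functions from a two-NP simulation
against reference profiles, updating each pair minimum as
r0 ← r0 + η (r_peak_ref − r_peak_sim) with η = 0.5, tolerance 0.25 Å, at
most 20 iterations, returning the best-seen parameter set flagged
converged/unconverged.  The dimer protocol (two NPs started just outside
shell contact in a 70 Å periodic box, Langevin at 300 K, dt 0.1 ps,
friction 0.5 ps⁻¹, 0.25 Å RDF bins with parabolic sub-bin peak refinement)
is shared between reference generation and the loop so protocol bias
cancels.

Identifiability: the CS–CS peak responds nearly 1:1 to its r0; the CS–AU
and AU–AU peaks are partly set by ligand-shell packing, so their response is
weaker.  In practice the identifiable direction is the ligand σ (plus the
consistency of the cross terms); the recovery test therefore perturbs the
ligand σ and verifies recovery of all three pair minima to within 5%.

## Docking

Two-solute rigid docking uses a four-term grid energy: each solute carries
an electrostatic potential grid (Debye–Hückel of its beads; inside a bead
the potential is held at the bead-surface value, since a finite charged
sphere has no 1/r divergence), an electrostatic desolvation penalty
(0.36·exp(−d_surf/3 Å), positive, hugging the surface), a non-polar
desolvation shell (−0.0065 kT/Å² applied to the partner's bead SASA when it
sits 4–7 Å from the surface) and a soft-core repulsion ((σ/r)⁸ summed over
beads, capped at 10 kT).  The desolvation constants are exposed
configuration, not fitted truths.  Pose energy is the ½-symmetrized sum of
each solute's grids interpolated (trilinear) at the other's beads, which
makes solute exchange an exact symmetry.  Bead SASA comes from a
Shrake–Rupley implementation on beads (radius σ/2 + 1.4 Å probe, 240
deterministic golden-spiral points).

Docking runs relax random start poses (uniform orientation, start sphere
enclosing both solutes) by Metropolis rigid-body moves (1 Å / 5° steps) at
the force-field temperature, followed by a zero-temperature quench into the
local minimum; poses with total energy below 0 kT are retained, greedily
clustered by ligand RMSD (10 Å default, comparable to observed cluster
spreads), and reported with relative populations, spreads and residues
within 5.5 Å of the NP.

## Orientation maps

A protein surface point is labelled by its body-frame spherical direction
(θ polar from +z, φ azimuth from +x, right-handed; the convention is
serialized with every map).  For each grid cell (default φ 0–350°, θ 0–170°,
10° steps; 648 orientations) the protein is rotated about its COM so that
direction faces the NP, the energy is scanned over the COM–centre distance
(0.5 Å steps from hard contact until the interaction vanishes), and the
minimum U_min(θ,φ) recorded.  The Boltzmann-average binding energy

    E_b = Σ P_ij U_min / Σ P_ij ,  P_ij = exp(−U_min/kT)

is evaluated with the map minimum subtracted before exponentiation for
stability.  The printed formula carries no sin θ solid-angle factor; a
weighted variant is available behind a flag
(`boltzmann_binding_energy(..., solid_angle_weight=True)`).

## Dynamics

Rigid bodies carry COM position, unit quaternion, principal inertia and (for
Brownian runs) Stokes–Einstein diffusion coefficients (D_t = kT/6πηR,
D_r = kT/8πηR³ with R = max bead distance from COM + bead radius — a
sphere-equivalent substitute for bead-shell hydrodynamics).

* **Langevin** (MS ensemble runs): BAOAB splitting; the O step is an exact
  Ornstein–Uhlenbeck update on COM velocities and body-frame angular
  velocities, so friction γ and noise satisfy fluctuation–dissipation at the
  configured temperature.  Quaternions advance by the exponential map of
  ω dt; the gyroscopic term ω×(Iω) is kept in the velocity update.  Defaults
  follow the MS protocol: dt 0.15 ps, γ 0.001 ps⁻¹, 300 K, NP mass 7.4 kDa,
  residue mass 0.12 kDa.
* **Brownian** (multi-solute runs): overdamped Ermak–McCammon,
  Δx = (D_t/kT)F Δt + √(2 D_t Δt) ξ and the rotational analogue about the
  principal axes; free-draining (no hydrodynamic interactions between
  bodies), dt 0.4 ps default.

Forces come from a fused neighbour-list kernel (cell-free KD-tree pair list
with a 5 Å skin, rebuilt when any bead moves half the skin; minimum image in
periodic boxes).  The radial pair force is capped at 1e3 kT/Å so transient
hard overlaps (e.g. at dense aggregation fronts) remain integrable; the cap
only engages inside the steric core where the configuration is already
unphysical.  Quaternions are renormalized every step.

The periodic box follows from the stated mass concentrations
(V = total mass/concentration per species, inconsistencies reconciled by the
geometric-mean volume): 40 NPs at 24 g/L and 40 proteins at 46 g/L give a
~266 Å cube.  Initial placement is uniform random with rejection of any
inter-body bead pair closer than 0.9 r0.

## Analysis

g(r) uses protein COMs and NP centres (AU bead for the CG model) with
1 Å bins up to half the box, normalized by ideal-gas shell counts; the first
peak is the smallest-r local maximum with g > 1.1.  Aggregates are connected
components of the body contact graph (any inter-body bead pair < 6 Å,
slightly beyond the 5.5 Å contact-residue criterion); morphology comes from
the gyration tensor of member COMs — asphericity λ1 − (λ2+λ3)/2 and
relative shape anisotropy κ² (κ²→1 linear, κ²→0 globular).

## Synthetic reference data

All tests run on generated data; nothing is downloaded.

* The NP reference trajectory emulates a long atomistic run of a single
  coated NP: a 13-atom icosahedral-like core (radius 4.9 Å, about the size
  of a 1 nm gold core — large enough that core alignment is well
  conditioned against thermal jitter) plus 18 CS atoms at the octahedral
  truth sites (6 vertices at R_o = 8 Å, 12 edge midpoints at R_o/√2), with
  per-frame Gaussian jitter (0.8 Å default), rigid tumbling, and a random
  global orientation stored in the truth so recovery tests cannot exploit
  axis alignment.  Frame 0 keeps the reference orientation so the recovered
  core frame coincides with the truth frame.  500 frames by default.
* Toy proteins are Cα chains with exact 3.8 Å bonds, as a gentle helix
  ("rod") or a compact self-avoiding walk ("globule"), with species given by
  their sequence.

What passing on these fixtures shows: the pipeline recovers planted
geometry, conserved quantities and known statistical-mechanics limits, and
the ensemble phenomenology (aggregation, contact peaks) emerges at the
stated state point.  What it does not show: accuracy against real atomistic
data for a specific NP chemistry — the fixture has no ligand flexibility,
no solvent structure and idealized charges — nor binding modes of a real
protein, whose shape and charge anisotropy a toy chain does not reproduce.

## Problem sizes used in the shipped checks

The ensemble observable (NP–NP g(r) contact peak) is computed from a
40 NP + 40 protein Langevin run of 3 ns (20,000 steps at dt 0.15 ps),
analysing the second half — long enough at these concentrations for
aggregates to form and the contact peak at the NP diameter to be the
dominant feature.  The σ-calibration check uses 3 ns dimer runs per
iteration.  Longer runs sharpen but do not move these observables.

## Known limitations

* Rigid bodies throughout: no internal protein dynamics, no ligand
  flexibility on the NP.
* Free-draining Brownian dynamics; hydrodynamic coupling between bodies is
  neglected, and single-body coefficients are sphere approximations.
* The SDA-style desolvation kernels are plausible stand-ins with exposed
  constants; absolute docking energies are not calibrated against
  experiment.
* The AU–AU pair σ is only weakly identifiable from dimer RDFs because the
  ligand shell sets the packing distance; calibration is reliable for the
  ligand σ.
* Effective charges for docking are the bead charges themselves; no
  effective-charge refitting is performed.
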