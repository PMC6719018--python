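# nanocg

Low-resolution models for the interaction dynamics of coated gold
nanoparticles (NPs) with proteins.

Screening how NP size, coating chemistry and concentration shape
protein–nanoparticle association needs simulations of crowded ensembles far
beyond atomistic reach.  `nanocg` implements a two-resolution model system
for this problem, aimed at computational biophysicists studying bio–nano
interfaces (e.g. amyloidogenic proteins against functionalized AuNPs):

* **protein** — minimalist one-bead-per-residue (Cα) model, implicit
  solvent, rigid;
* **CG nanoparticle** — one gold-core bead (AU) plus 18 ligand beads (CS,
  split 12 inner CSi / 6 outer CSo on the octahedral symmetry of the core),
  net charge −1 e: coating chemistry and surface roughness kept explicit;
* **MS nanoparticle** — the whole NP as one 15 Å sphere with a central
  charge and a hydrophobicity index: cheapest possible description.

The interaction model is a hydrophobic/steric + screened-electrostatic
decomposition over inter-body bead pairs,

```
U = Σ_{i>j} ε_ij[(r0_ij/r_ij)¹² − 2(r0_ij/r_ij)⁶] + Σ_{i>j} l_B q_i q_j e^{−r_ij/λ}/r_ij   (kT)
```

with the Bjerrum length l_B computed from temperature and permittivity and
the Debye length λ from ionic strength.  Around it the package provides:

* `npbuilder` — bottom-up construction of the CG NP from a reference
  trajectory: core alignment, ligand-site recovery by volume-map clustering,
  CSi/CSo classification, exact charge lumping, inertia-matched mass
  assignment, and σ calibration by RDF first-peak matching;
* `docking` — two-solute rigid docking with a four-term grid energy
  (Coulombic, electrostatic desolvation, non-polar desolvation, soft-core
  repulsion), pose clustering with populations/spreads/contact residues;
* `orientmap` — binding-energy maps U_min(θ,φ) over protein orientations
  against the MS NP and the Boltzmann-averaged binding energy E_b;
* `dynamics` — rigid-body Langevin (BAOAB) and Brownian (Ermak–McCammon)
  ensemble simulation in periodic boxes sized from mass concentrations;
* `analysis` — g(r) (protein COM / NP centre based), first peaks, aggregate
  detection and linear-vs-globular morphology (gyration tensor, κ²);
* `fixtures` — synthetic reference data with known ground truth, toy
  proteins, and Cα-PDB/XYZ I/O, so everything is testable offline.

## Worked example

Build the 19-bead CG NP from a synthetic reference trajectory (500 frames of
a jittered, tumbling NP with 18 planted ligand sites), then map the binding
of a toy protein to the MS NP:

```python
import nanocg as ncg
from nanocg import npbuilder, orientmap

traj, truth = ncg.make_np_reference_trajectory(seed=11)
model = npbuilder.build_cg_np(traj, seed=11)
print(model.total_charge)                    # -1.0        (e, exact)
print(round(model.au_mass, 3))               # 2.014       (kDa)
print(round(model.cs_masses[0], 4))          # 0.2992      (kDa, shared)
print(model.cs_classes.count("CSi"),
      model.cs_classes.count("CSo"))         # 12 6

params = ncg.default_params()
protein = ncg.make_toy_protein(24, seed=7)
bmap = orientmap.build_map(protein, ncg.make_ms_np_body(), params)
print(bmap.umin.shape)                       # (18, 36)    648 orientations
print(round(float(bmap.umin.min()), 2))      # -22.38      (kT, best orientation)
print(round(orientmap.boltzmann_binding_energy(bmap), 2))   # -21.11 (kT)
```

The model's net charge is the exact sum of the reference atomic charges
(−1 e); the CS beads end up heavier than their ligand atoms (0.299 vs
0.138 kDa) because the mass assignment restores the moment of inertia that
lumping the gold core onto one bead would destroy.  The binding-energy map
shows a deep (≈ −22 kT) orientation-dependent well; E_b is its Boltzmann
average over all 648 orientations, dominated by the strongest-binding
patches.

A command-line interface mirrors the library:
`nanocg build-np`, `nanocg energy`, `nanocg dock`, `nanocg map`,
`nanocg simulate`, `nanocg analyze` (see `nanocg --help`).

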