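"""Pair potentials and total-energy evaluation for the CG and MS models.

The interaction between rigid bodies decomposes into a hydrophobic/steric
(``hs``) term and a screened electrostatic (``el``) term summed over all
inter-body bead pairs:

    U = sum_{i>j} u^hs(r_ij; eps_ij, r0_ij) + sum_{i>j} u^el(r_ij; q_i q_j, lambda)

``u^hs`` is a 12-6 well written as eps*[(r0/r)^12 - 2 (r0/r)^6] so that r0 is
the position of the minimum and eps its depth; ``u^el`` is a Debye-Hückel
potential l_B * q_i q_j * exp(-r/lambda)/r with the Bjerrum length l_B fixed by
temperature and relative permittivity.  Energies are in kT at the force-field
temperature, lengths in Å, charges in e.

Two mixing rules coexist.  Ordinary bead pairs use the linear combination rule
r0 = (sigma_i + sigma_j)/2 with geometric-mean well depths.  Pairs involving a
mesoscale (single-sphere) nanoparticle take their well depth from the
hydrophobicity indices instead, eps = k * h_i * h_NP, with a single global
coupling constant k; the MS NP's whole charge sits at the sphere centre (it is
the sphere's only bead).

All pair terms are shifted to zero at the cutoff so the potential (and the
dynamics driven by it) is continuous there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import constants as _c
from scipy.spatial import cKDTree

SCHEMA_VERSION = 1

#: Default relative permittivity of water and reference temperature.
EPS_R = 78.5
T_DEFAULT = 300.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------
@dataclass
class Species:
    """Per-bead-type parameters.

    sigma is the self-interaction minimum position r0 (Å), epsilon the well
    depth (kT), hindex a dimensionless hydrophobicity in [0, 1], charge in e
    and mass in kDa.  ``kind`` is ``"bead"`` for ordinary beads and ``"msnp"``
    for the single-sphere mesoscale nanoparticle.
    """

    name: str
    sigma: float
    epsilon: float
    hindex: float
    charge: float
    mass: float
    kind: str = "bead"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0 ({self.name})")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0 ({self.name})")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0 ({self.name})")


@dataclass
class FFParams:
    """Force-field parameter set: species table plus global constants."""

    species: dict
    debye_length: float
    temperature: float = T_DEFAULT
    cutoff: float = 30.0
    ms_coupling: float = 4.0  # kT; single free parameter of the MS interaction
    bjerrum: float = None
    #: optional per-pair (r0, eps) overrides: {"A-B" (labels sorted): {"r0":..,
    #: "eps":..}}; used e.g. by the sigma-tuning loop of the NP builder
    pair_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.debye_length <= 0:
            raise ValueError("debye length must be > 0")
        if self.bjerrum is None:
            self.bjerrum = bjerrum_length(self.temperature)
        if self.bjerrum <= 0:
            raise ValueError("bjerrum length must be > 0")
        max_sigma = max((s.sigma for s in self.species.values()), default=0.0)
        if self.cutoff < max_sigma:
            raise ValueError("cutoff must be at least the largest pair sigma")

    # -- serialization ------------------------------------------------------
    def to_json(self, path):
        payload = {
            "schema_version": SCHEMA_VERSION,
            "temperature": self.temperature,
            "debye_length": self.debye_length,
            "bjerrum_length": self.bjerrum,
            "cutoff": self.cutoff,
            "ms_coupling": self.ms_coupling,
            "pair_overrides": self.pair_overrides,
            "species": {k: asdict(v) for k, v in self.species.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        species = {k: Species(**v) for k, v in payload["species"].items()}
        return cls(
            species=species,
            debye_length=payload["debye_length"],
            temperature=payload.get("temperature", T_DEFAULT),
            cutoff=payload.get("cutoff", 30.0),
            ms_coupling=payload.get("ms_coupling", 4.0),
            bjerrum=payload.get("bjerrum_length"),
            pair_overrides=payload.get("pair_overrides", {}),
        )


@dataclass
class EnergyTerms:
    """Hydrophobic/steric and electrostatic energy decomposition, kT."""

    hs: float
    el: float

    @property
    def total(self) -> float:
        return self.hs + self.el


# ---------------------------------------------------------------------------
# elementary potentials
# ---------------------------------------------------------------------------
def bjerrum_length(temperature: float = T_DEFAULT, eps_r: float = EPS_R) -> float:
    """Bjerrum length e²/(4 pi eps0 eps_r kB T) in Å."""
    lb = _c.e ** 2 / (4 * np.pi * _c.epsilon_0 * eps_r * _c.Boltzmann * temperature)
    return lb * 1e10


def debye_length(ionic_strength: float, temperature: float = T_DEFAULT,
                 eps_r: float = EPS_R) -> float:
    """Debye screening length (Å) of a 1:1 electrolyte.

    ionic_strength in mol/L; lambda = sqrt(eps0 eps_r kB T / (2 NA e² I)).
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be > 0")
    i_si = ionic_strength * 1e3  # mol/m^3
    lam = np.sqrt(_c.epsilon_0 * eps_r * _c.Boltzmann * temperature /
                  (2 * _c.Avogadro * _c.e ** 2 * i_si))
    return lam * 1e10


def hs_potential(r, epsilon, r0, cutoff=None):
    """12-6 hydrophobic/steric well: eps[(r0/r)^12 - 2 (r0/r)^6], kT.

    Minimum value -epsilon at r = r0.  With *cutoff* given the potential is
    shifted to zero at the cutoff and vanishes beyond it.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    x6 = (r0 / r) ** 6
    u = epsilon * (x6 * x6 - 2.0 * x6)
    if cutoff is not None:
        xc6 = (r0 / cutoff) ** 6
        u = np.where(r < cutoff, u - epsilon * (xc6 * xc6 - 2.0 * xc6), 0.0)
    return u if u.ndim else float(u)


_USE_PARAMS = object()


def el_potential(r, qi, qj, params: FFParams, cutoff=_USE_PARAMS):
    """Debye-Hückel pair energy l_B q_i q_j exp(-r/lambda)/r, kT.

    Shifted to zero at the cutoff (``params.cutoff`` unless overridden; pass
    ``cutoff=None`` for the bare unshifted potential).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    pref = params.bjerrum * qi * qj
    u = pref * np.exp(-r / params.debye_length) / r
    rc = params.cutoff if cutoff is _USE_PARAMS else cutoff
    if rc is not None:
        shift = pref * np.exp(-rc / params.debye_length) / rc
        u = np.where(r < rc, u - shift, 0.0)
    return u if u.ndim else float(u)


def mix_pair(a: Species, b: Species):
    """Linear-combination mixing: r0 arithmetic mean, epsilon geometric mean."""
    return (a.sigma + b.sigma) / 2.0, float(np.sqrt(a.epsilon * b.epsilon))


def pair_well(a: Species, b: Species, ms_coupling: float):
    """(r0, epsilon) for a pair, dispatching on the MS hydrophobicity rule."""
    r0 = (a.sigma + b.sigma) / 2.0
    if a.kind == "msnp" or b.kind == "msnp":
        eps = ms_coupling * a.hindex * b.hindex
    else:
        eps = float(np.sqrt(a.epsilon * b.epsilon))
    return r0, eps


def ms_np_protein_potential(r, residue: Species, np_params: Species,
                            params: FFParams):
    """MS NP-residue pair energy: hydrophobicity-index well + Debye-Hückel.

    The short-range well depth is k * h_residue * h_NP with k the single free
    coupling constant of the mesoscale model; the NP charge acts from the
    sphere centre.
    """
    r0, eps = pair_well(residue, np_params, params.ms_coupling)
    u_hs = hs_potential(r, eps, r0, cutoff=params.cutoff)
    u_el = el_potential(r, residue.charge, np_params.charge, params)
    return u_hs + u_el


# ---------------------------------------------------------------------------
# tabulated pair interactions over a species set
# ---------------------------------------------------------------------------
class PairTable:
    """Precomputed per-species-pair constants for vectorized evaluation."""

    def __init__(self, params: FFParams, labels=None):
        self.params = params
        self.labels = list(params.species) if labels is None else list(labels)
        for lab in self.labels:
            if lab not in params.species:
                raise KeyError(f"unknown species label {lab!r}")
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        sp = [params.species[lab] for lab in self.labels]
        self.r0 = np.zeros((n, n))
        self.eps = np.zeros((n, n))
        self.qq = np.zeros((n, n))  # l_B * q_i * q_j
        for i in range(n):
            for j in range(n):
                r0, eps = pair_well(sp[i], sp[j], params.ms_coupling)
                key = "-".join(sorted((sp[i].name, sp[j].name)))
                override = params.pair_overrides.get(key)
                if override:
                    r0 = override.get("r0", r0)
                    eps = override.get("eps", eps)
                self.r0[i, j] = r0
                self.eps[i, j] = eps
                self.qq[i, j] = params.bjerrum * sp[i].charge * sp[j].charge
        rc = params.cutoff
        xc6 = (self.r0 / rc) ** 6
        self.hs_shift = self.eps * (xc6 * xc6 - 2 * xc6)
        self.el_shift_unit = np.exp(-rc / params.debye_length) / rc
        self.charges = np.array([s.charge for s in sp])
        self.sigmas = np.array([s.sigma for s in sp])

    def species_index(self, labels):
        return np.array([self.index[l] for l in labels], dtype=np.intp)

    def pair_energies(self, r, si, sj):
        """(hs, el) arrays for pair distances r between species si, sj."""
        r = np.asarray(r, dtype=float)
        r = np.maximum(r, 1e-6)
        r0 = self.r0[si, sj]
        eps = self.eps[si, sj]
        qq = self.qq[si, sj]
        lam = self.params.debye_length
        rc = self.params.cutoff
        x6 = (r0 / r) ** 6
        uhs = eps * (x6 * x6 - 2 * x6) - self.hs_shift[si, sj]
        uel = qq * (np.exp(-r / lam) / r - self.el_shift_unit)
        inside = r < rc
        return np.where(inside, uhs, 0.0), np.where(inside, uel, 0.0)

    def pair_energy_forces(self, dr, r, si, sj):
        """Energies and pair forces (on bead i, from j) for displacement dr."""
        r = np.maximum(r, 0.5)  # clamp hard overlaps; forces stay finite
        r0 = self.r0[si, sj]
        eps = self.eps[si, sj]
        qq = self.qq[si, sj]
        lam = self.params.debye_length
        rc = self.params.cutoff
        rinv = 1.0 / r
        x2 = (r0 * rinv) ** 2
        x6 = x2 * x2 * x2
        x12 = x6 * x6
        uhs = eps * (x12 - 2.0 * x6) - self.hs_shift[si, sj]
        expl = np.exp(-r / lam)
        uel = qq * (expl * rinv - self.el_shift_unit)
        # du/dr
        dhs = -12.0 * eps * rinv * (x12 - x6)
        del_ = -qq * expl * rinv * (1.0 / lam + rinv)
        inside = r < rc
        dudr = np.where(inside, dhs + del_, 0.0)
        # cap the radial force so transient hard overlaps stay integrable
        dudr = np.clip(dudr, -1e3, 1e3)
        # force on i = -dU/dr * (r_i - r_j)/r ; dr = r_i - r_j
        f = (-dudr * rinv)[:, None] * dr
        return np.where(inside, uhs, 0.0), np.where(inside, uel, 0.0), f


def _minimum_image(dr, box):
    if box is not None:
        dr -= box * np.round(dr / box)
    return dr


def find_pairs(positions, cutoff, box=None):
    """(i, j) index arrays of bead pairs closer than *cutoff* (minimum image)."""
    positions = np.asarray(positions, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        if np.any(box < 2 * cutoff):
            raise ValueError("box must be at least twice the cutoff")
        wrapped = np.mod(positions, box)
        # guard against coordinates landing exactly on the upper boundary
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs[:, 0], pairs[:, 1]


def system_energy(bodies, params: FFParams, box=None) -> EnergyTerms:
    """Total inter-body energy of a set of rigid bodies (kT).

    Intra-body pairs are excluded (rigid bodies); the minimum-image convention
    applies when *box* is given.
    """
    labels = sorted({s for b in bodies for s in b.species})
    table = PairTable(params, labels)
    pos = np.concatenate([b.world_coords() for b in bodies])
    sidx = np.concatenate([table.species_index(b.species) for b in bodies])
    bid = np.concatenate([np.full(b.n_beads, k) for k, b in enumerate(bodies)])
    if box is not None:
        box = np.asarray(box, dtype=float)
    i, j = find_pairs(pos, params.cutoff, box)
    keep = bid[i] != bid[j]
    i, j = i[keep], j[keep]
    if len(i) == 0:
        return EnergyTerms(0.0, 0.0)
    dr = _minimum_image(pos[i] - pos[j], box)
    r = np.linalg.norm(dr, axis=1)
    uhs, uel = table.pair_energies(r, sidx[i], sidx[j])
    return EnergyTerms(float(uhs.sum()), float(uel.sum()))


# ---------------------------------------------------------------------------
# default species tables
# ---------------------------------------------------------------------------
#: Kyte-Doolittle hydropathy, rescaled to [0, 1] below.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Formal residue charges at pH 7 (His neutral).
RESIDUE_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

RESIDUE_MASS = 0.12  # kDa: 12 kDa protein / 99 residues
RESIDUE_SIGMA = 5.0  # Å, Cα-bead contact distance
MSNP_SIGMA = 15.0    # Å, MS NP contact diameter
MSNP_MASS = 7.4      # kDa
MSNP_CHARGE = -1.0   # e


def kd_hindex(letter: str) -> float:
    """Kyte-Doolittle hydropathy rescaled to [0, 1]."""
    return (KYTE_DOOLITTLE[letter] + 4.5) / 9.0


def default_protein_species() -> dict:
    """One species per amino-acid letter for the minimalist protein model.

    Well depths grow linearly with the hydrophobicity index (0.1 + 0.9 h kT)
    so that the most hydrophobic residues attract at ~1 kT and polar ones are
    mostly steric.
    """
    table = {}
    for letter in KYTE_DOOLITTLE:
        h = kd_hindex(letter)
        table[letter] = Species(
            name=letter, sigma=RESIDUE_SIGMA, epsilon=0.1 + 0.9 * h, hindex=h,
            charge=RESIDUE_CHARGE.get(letter, 0.0), mass=RESIDUE_MASS,
        )
    return table


def default_ms_np_species() -> Species:
    """Mesoscale NP: one 15 Å sphere, hydrophobic, net charge -1 e."""
    return Species(name="NP", sigma=MSNP_SIGMA, epsilon=0.0, hindex=1.0,
                   charge=MSNP_CHARGE, mass=MSNP_MASS, kind="msnp")


def default_cg_np_species() -> dict:
    """AU / CSi / CSo bead types of the 19-bead CG NP.

    These defaults are calibrated on the synthetic reference fixture: sigma of
    the ligand beads is twice the 3.5 Å van-der-Waals radius of the coating
    groups; the well depth and hydrophobicity follow phenylalanine, to which
    the coating is chemically analogous; charges are the fixture's RESP-like
    per-bead sums (AU +5, CSi -0.3125, CSo -0.375; net exactly -1 e).

    The AU bead represents the whole gold core including its near-field, so
    its contact distance is the NP diameter (15 Å): two CG NPs then meet at
    the same separation as two MS NPs, which is where the ensemble NP-NP
    g(r) contact peak sits for both resolutions.
    """
    h_phe = kd_hindex("F")
    return {
        "AU": Species(name="AU", sigma=15.0, epsilon=1.0, hindex=0.0,
                      charge=5.0, mass=4.9232),
        "CSI": Species(name="CSI", sigma=7.0, epsilon=1.2, hindex=h_phe,
                       charge=-0.3125, mass=0.1376),
        "CSO": Species(name="CSO", sigma=7.0, epsilon=1.2, hindex=h_phe,
                       charge=-0.375, mass=0.1376),
    }


def default_params(ionic_strength: float = 0.030, temperature: float = T_DEFAULT,
                   cutoff: float = 30.0, ms_coupling: float = 4.0) -> FFParams:
    """Full default parameter set: amino acids + CG NP beads + MS NP."""
    species = default_protein_species()
    species.update(default_cg_np_species())
    species["NP"] = default_ms_np_species()
    return FFParams(
        species=species,
        debye_length=debye_length(ionic_strength, temperature),
        temperature=temperature, cutoff=cutoff, ms_coupling=ms_coupling,
    )
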