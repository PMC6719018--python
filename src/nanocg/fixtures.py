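"""Synthetic reference data and standard-format I/O.

Everything a test or example needs is generated here: a fake "atomistic-like"
reference trajectory of a coated gold nanoparticle with known ground truth
(18 ligand attachment sites on the octahedral symmetry of the core: 6 outer
sites at the octahedron vertices, 12 inner sites at the edge midpoints), toy
one-bead-per-residue proteins, and readers/writers for Cα PDB files and
multi-frame XYZ trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import forcefield as ff
from .bodies import RigidBody, body_from_beads, IDENTITY_QUAT

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

# fixture charge layout: exactly representable binary fractions so that the
# net NP charge sums to -1 e with no floating-point residue
CORE_CENTER_CHARGE = 0.5
CORE_VERTEX_CHARGE = 0.375   # x12 -> core total +5.0
CSI_CHARGE = -0.3125         # x12 -> -3.75
CSO_CHARGE = -0.375          # x6  -> -2.25; net -1.0

CS_ATOM_MASS = 0.1376        # kDa, S(CH2)2Ph ligand lumped on its first C
NP_TOTAL_MASS = 7.4          # kDa
CORE_ATOM_MASS = (NP_TOTAL_MASS - 18 * CS_ATOM_MASS) / 13


# ---------------------------------------------------------------------------
# reference trajectory fixture
# ---------------------------------------------------------------------------
@dataclass
class ReferenceTrajectory:
    """Labeled multi-frame coordinate set standing in for atomistic data.

    frames : (F, N, 3) Å; roles : per-atom "core" / "CS" / "other";
    charges : e; masses : kDa.  All frames share the atom roster.
    """

    frames: np.ndarray
    roles: list
    charges: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (F, N, 3)")
        if "core" not in self.roles or "CS" not in self.roles:
            raise ValueError("need at least one core and one CS atom")

    @property
    def n_frames(self):
        return len(self.frames)

    def atom_indices(self, role):
        return np.array([i for i, r in enumerate(self.roles) if r == role])


@dataclass
class NPFixtureTruth:
    """Ground truth of the synthetic NP fixture, for recovery tests."""

    sites: np.ndarray        # (18, 3) core-frame site positions, Å
    classes: list            # "CSi" | "CSo" per site
    rotation: np.ndarray     # global orientation applied to the ideal geometry
    jitter_std: float
    seed: int


def _octahedron_sites(r_outer: float):
    """6 vertices at r_outer and 12 edge midpoints at r_outer/sqrt(2)."""
    verts = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    ], dtype=float) * r_outer
    mids = []
    for a in range(6):
        for b in range(a + 1, 6):
            if np.dot(verts[a], verts[b]) == 0:  # adjacent vertices only
                mids.append((verts[a] + verts[b]) / 2.0)
    mids = np.array(mids)
    sites = np.concatenate([mids, verts])
    classes = ["CSi"] * 12 + ["CSo"] * 6
    return sites, classes


def _icosahedral_core(radius=4.9):
    """13-atom core: centre plus 12 icosahedron vertices."""
    phi = (1 + np.sqrt(5)) / 2
    raw = np.array([
        [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
        [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
        [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
    ], dtype=float)
    raw *= radius / np.linalg.norm(raw[0])
    return np.vstack([[0.0, 0.0, 0.0], raw])


def make_np_reference_trajectory(n_frames=500, r_outer=8.0, jitter_std=0.8,
                                 tumble=True, seed=0):
    """Synthetic "atomistic-like" NP trajectory with known ground truth.

    A 13-atom icosahedral-like gold core plus 18 ligand representative (CS)
    atoms at the true sites, thermally jittered per frame and, with *tumble*,
    rigidly rotated and translated per frame.  The whole geometry carries a
    random fixed orientation (stored in the truth) so recovery tests cannot
    rely on axis alignment.  Per-NP atomic charges sum to exactly -1 e.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    sites, classes = _octahedron_sites(r_outer)
    core = _icosahedral_core()
    orient = Rotation.random(random_state=rng)
    sites = orient.apply(sites)
    core = orient.apply(core)

    ref = np.concatenate([core, sites])
    roles = ["core"] * len(core) + ["CS"] * len(sites)
    charges = np.array(
        [CORE_CENTER_CHARGE] + [CORE_VERTEX_CHARGE] * 12
        + [CSI_CHARGE if c == "CSi" else CSO_CHARGE for c in classes]
    )
    masses = np.array([CORE_ATOM_MASS] * 13 + [CS_ATOM_MASS] * 18)

    frames = np.empty((n_frames, len(ref), 3))
    for f in range(n_frames):
        coords = ref + rng.normal(scale=jitter_std, size=ref.shape)
        if tumble and f > 0:
            # frame 0 stays in the reference orientation so the core frame
            # recovered by alignment coincides with the stored truth frame
            rot = Rotation.random(random_state=rng)
            shift = rng.uniform(-20.0, 20.0, size=3)
            coords = rot.apply(coords) + shift
        frames[f] = coords

    traj = ReferenceTrajectory(frames=frames, roles=roles, charges=charges,
                               masses=masses)
    truth = NPFixtureTruth(sites=sites, classes=classes,
                           rotation=orient.as_matrix(), jitter_std=jitter_std,
                           seed=seed)
    return traj, truth


# ---------------------------------------------------------------------------
# toy proteins and nanoparticle bodies
# ---------------------------------------------------------------------------
CA_SPACING = 3.8  # Å between consecutive Cα beads

_AUTO_CYCLE = "KFDLAVGSTIEYRNQHWPCM"  # mixes charge, hydrophobicity, polarity


def make_toy_protein(n_residues, sequence=None, shape="globule", seed=0):
    """Cα-like toy protein as a :class:`RigidBody`.

    Consecutive beads sit exactly 3.8 Å apart; a "rod" is a gentle helix, a
    "globule" a compact self-avoiding walk.  Species labels are one-letter
    amino-acid codes resolved by the force field's default table.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    if sequence is None:
        sequence = (_AUTO_CYCLE * (n_residues // len(_AUTO_CYCLE) + 1))[:n_residues]
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    for letter in sequence:
        if letter not in THREE_LETTER:
            raise ValueError(f"invalid residue letter {letter!r}")
    rng = np.random.default_rng(seed)
    if shape == "rod":
        coords = _helix_coords(n_residues)
    elif shape == "globule":
        coords = _saw_coords(n_residues, rng)
    else:
        raise ValueError("shape must be 'rod' or 'globule'")
    # random overall orientation so fixtures carry no axis bias
    coords = Rotation.random(random_state=rng).apply(coords)
    residue_ids = [f"{THREE_LETTER[s]}{i + 1}" for i, s in enumerate(sequence)]
    masses = np.full(n_residues, ff.RESIDUE_MASS)
    return body_from_beads(
        name=f"toyprot{n_residues}", kind="protein", coords=coords,
        species=list(sequence), masses=masses, residue_ids=residue_ids,
    )


def _helix_coords(n):
    radius = 2.0
    dtheta = np.deg2rad(40.0)
    chord = 2 * radius * np.sin(dtheta / 2)
    dz = np.sqrt(CA_SPACING ** 2 - chord ** 2)
    k = np.arange(n)
    return np.column_stack([radius * np.cos(k * dtheta),
                            radius * np.sin(k * dtheta), k * dz])


def _saw_coords(n, rng, min_sep=4.0, max_attempts=200):
    """Compact self-avoiding walk with exact 3.8 Å steps."""
    coords = [np.zeros(3)]
    while len(coords) < n:
        prev = coords[-1]
        center_pull = -prev
        for _ in range(max_attempts):
            step = rng.normal(size=3) + 0.15 * center_pull
            step *= CA_SPACING / np.linalg.norm(step)
            cand = prev + step
            if len(coords) < 2:
                break
            others = np.array(coords[:-1])
            if np.linalg.norm(others - cand, axis=1).min() >= min_sep:
                break
        else:
            # dead end: back up one bead and retry
            coords.pop()
            continue
        coords.append(cand)
    return np.array(coords)


def make_ms_np_body(species=None, name="NP"):
    """Mesoscale NP: a single sphere with the whole mass and central charge."""
    sp = species or ff.default_ms_np_species()
    return RigidBody(
        name=name, kind="np", body_coords=np.zeros((1, 3)), species=[sp.name],
        bead_masses=np.array([sp.mass]), com=np.zeros(3),
        quat=IDENTITY_QUAT.copy(), center_index=0,
    )


def make_cg_np_body(r_outer=8.0, species_table=None, name="NPCG",
                    cs_masses=None, au_mass=None):
    """Idealized 19-bead CG NP (AU at the centre + 18 CS sites)."""
    sites, classes = _octahedron_sites(r_outer)
    coords = np.vstack([[0.0, 0.0, 0.0], sites])
    species = ["AU"] + ["CSI" if c == "CSi" else "CSO" for c in classes]
    table = species_table or ff.default_cg_np_species()
    masses = np.array([au_mass if au_mass is not None else table["AU"].mass]
                      + list(cs_masses if cs_masses is not None
                             else [table[s].mass for s in species[1:]]))
    return body_from_beads(name=name, kind="np", coords=coords, species=species,
                           masses=masses, center_index=0,
                           orient_to_principal=False)


# ---------------------------------------------------------------------------
# PDB / XYZ I/O
# ---------------------------------------------------------------------------
def read_calpha_pdb(path):
    """One bead per residue at the Cα position from a PDB file.

    Alternate locations resolve to the highest occupancy; insertion codes are
    preserved in the residue identifiers; chain breaks (consecutive Cα farther
    than 4.5 Å) are reported as warnings.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("prot", path)
    coords, species, residue_ids = [], [], []
    model = next(structure.get_models())
    for chain in model:
        prev = None
        for residue in chain:
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                atom = max(atom.disordered_get_list(),
                           key=lambda a: a.get_occupancy() or 0.0)
            pos = atom.get_coord().astype(float)
            resname = residue.get_resname().strip()
            letter = ONE_LETTER.get(resname, "G")
            hetflag, resseq, icode = residue.get_id()
            rid = f"{resname}{resseq}{icode.strip()}"
            if prev is not None and np.linalg.norm(pos - prev) > 4.5:
                warnings.warn(f"chain break before {rid}", stacklevel=2)
            coords.append(pos)
            species.append(letter)
            residue_ids.append(rid)
            prev = pos
    if not coords:
        raise ValueError(f"no CA atoms found in {path}")
    masses = np.full(len(coords), ff.RESIDUE_MASS)
    return body_from_beads(name=str(path), kind="protein", coords=np.array(coords),
                           species=species, masses=masses, residue_ids=residue_ids)


def write_trajectory(frames, path, fmt="xyz", labels=None, box=None):
    """Write a multi-frame trajectory as extended-XYZ or MODEL/ENDMDL PDB.

    *frames* is an (F, N, 3) array or list of (N, 3) arrays; *labels* the
    per-atom names (defaults to ``X``).  The XYZ comment line carries the
    lattice when *box* is given.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("empty trajectory")
    n = len(frames[0])
    if labels is None:
        labels = ["X"] * n
    if fmt == "xyz":
        with open(path, "w") as fh:
            for k, coords in enumerate(frames):
                fh.write(f"{n}\n")
                comment = f"frame={k}"
                if box is not None:
                    b = np.asarray(box, dtype=float).reshape(-1)
                    comment += ' Lattice="%g 0 0 0 %g 0 0 0 %g"' % (b[0], b[1], b[2])
                fh.write(comment + "\n")
                for lab, (x, y, z) in zip(labels, coords):
                    fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
    elif fmt == "pdb":
        with open(path, "w") as fh:
            for k, coords in enumerate(frames):
                fh.write(f"MODEL     {k + 1:4d}\n")
                for i, (lab, (x, y, z)) in enumerate(zip(labels, coords), 1):
                    name = (lab[:3] or "X").upper()
                    fh.write(
                        f"ATOM  {i:5d}  CA  {name:>3s} A{i:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                    )
                fh.write("ENDMDL\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_xyz_trajectory(path):
    """Read a multi-frame (extended-)XYZ file -> (labels, frames, box)."""
    frames, labels, box = [], None, None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        if 'Lattice="' in comment and box is None:
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            vals = np.array([float(v) for v in lat]).reshape(3, 3)
            box = np.diag(vals)
        block = lines[i + 2:i + 2 + n]
        labs = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if labels is None:
            labels = labs
        frames.append(coords)
        i += 2 + n
    return labels, frames, box


def write_reference_trajectory_xyz(traj: ReferenceTrajectory, path):
    """Dump a reference trajectory with role labels as multi-frame XYZ."""
    write_trajectory(list(traj.frames), path, fmt="xyz",
                     labels=["AU" if r == "core" else "CS" for r in traj.roles])
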