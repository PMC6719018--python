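"""Two-solute rigid docking with a four-term grid interaction energy.

Each solute carries four precomputed lattices: its screened electrostatic
potential (phi_el, kT/e), an electrostatic desolvation kernel (phi_edesolv), a
non-polar desolvation kernel (phi_npdesolv, kT/Å² weighting buried surface
area), and a soft-core repulsion field (E_lj, kT).  The interaction free
energy of a pose is the symmetrized sum

    dG = 1/2 sum phi_el1 q_i2 + 1/2 sum phi_el2 q_j1
       +     sum phi_edesolv1 q_i2^2 + sum phi_edesolv2 q_j1^2
       +     sum phi_npdesolv1 SASA_m2 + sum phi_npdesolv2 SASA_m1
       + 1/2 sum E_lj1 + 1/2 sum E_lj2

evaluated by trilinear interpolation of each solute's grids at the other's
bead positions, which makes it symmetric under exchange of the two solutes by
construction.  Docking runs relax random starting poses by Metropolis
rigid-body moves followed by a zero-temperature quench; retained poses are
clustered by RMSD into representative complexes with relative populations,
spreads and contact residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from . import forcefield as ff
from .bodies import RigidBody, random_quaternion

# desolvation kernel constants; the functional details of the reference
# implementation live in its own literature, so these are exposed knobs
EDESOLV_SCALE = 0.36       # amplitude of the electrostatic desolvation penalty
EDESOLV_DECAY = 3.0        # Å, decay of the penalty away from the surface
NPDESOLV_BETA = -0.0065    # kT/Å², weight of buried SASA
NPDESOLV_SHELL = (4.0, 7.0)  # Å from the surface where burial counts
SOFTCORE_CAP = 10.0        # kT cap on the soft-core repulsion field
SOFTCORE_EXP = 8


@dataclass
class EnergyGrids:
    """Four scalar fields on a shared cubic lattice around one solute."""

    phi_el: np.ndarray
    phi_edesolv: np.ndarray
    phi_npdesolv: np.ndarray
    e_lj: np.ndarray
    origin: np.ndarray
    spacing: float

    def interpolate(self, which, points):
        """Trilinear interpolation at lab-frame points; 0 outside the lattice."""
        grid = getattr(self, which)
        idx = (np.asarray(points, dtype=float) - self.origin) / self.spacing
        return map_coordinates(grid, idx.T, order=1, mode="constant", cval=0.0)


@dataclass
class DockingSolute:
    """A rigid body with effective charges, per-bead SASA and energy grids."""

    body: RigidBody
    charges: np.ndarray
    sasa: np.ndarray
    grids: EnergyGrids = None
    radii: np.ndarray = None

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.sasa = np.asarray(self.sasa, dtype=float)
        if len(self.charges) != self.body.n_beads:
            raise ValueError("charge count must match bead count")
        if np.any(self.sasa < 0):
            raise ValueError("SASA must be non-negative")


@dataclass
class Pose:
    """Rigid placement of solute 2 relative to solute 1, with term energies."""

    quat: np.ndarray
    translation: np.ndarray
    el: float = np.nan
    edesolv: float = np.nan
    npdesolv: float = np.nan
    softcore: float = np.nan

    @property
    def total(self):
        return self.el + self.edesolv + self.npdesolv + self.softcore

    def apply(self, body_coords):
        return Rotation.from_quat(self.quat).apply(body_coords) + self.translation


@dataclass
class PoseCluster:
    representative: Pose
    members: list
    relpop: float          # % of retained poses
    spread: float          # Å RMSD of members to the representative
    contacts: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# solute preparation
# ---------------------------------------------------------------------------
def shrake_rupley_sasa(coords, radii, probe=1.4, n_points=240):
    """Solvent-accessible surface area per bead (Å²), Shrake-Rupley."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    # deterministic quasi-uniform sphere points (golden spiral)
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * k / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * k
    sphere = np.column_stack([np.cos(theta) * np.sin(phi),
                              np.sin(theta) * np.sin(phi), np.cos(phi)])
    sasa = np.zeros(len(coords))
    ext = radii + probe
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= ext[j]
        sasa[i] = 4 * np.pi * ext[i] ** 2 * accessible.mean()
    return sasa


def make_solute(body: RigidBody, params: ff.FFParams) -> DockingSolute:
    """Docking solute with bead charges used directly as effective charges."""
    charges = np.array([params.species[s].charge for s in body.species])
    radii = np.array([params.species[s].sigma / 2 for s in body.species])
    sasa = shrake_rupley_sasa(body.body_coords, radii)
    return DockingSolute(body=body, charges=charges, sasa=sasa, radii=radii)


def build_grids(solute: DockingSolute, params: ff.FFParams, spacing=1.0,
                margin=12.0) -> EnergyGrids:
    """Sample the four interaction fields of a solute on a cubic lattice.

    phi_el is the Debye-Hückel potential of the solute beads (kT/e per unit
    probe charge); phi_edesolv a positive exponential penalty hugging the
    solute surface; phi_npdesolv the burial weight beta inside a shell 4-7 Å
    from the surface; e_lj a capped soft-core repulsion (sigma/r)^8 summed
    over beads.  The lattice covers the solute plus *margin* on every side.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    coords = solute.body.body_coords  # grids live in the body frame
    radii = solute.radii if solute.radii is not None else np.full(
        solute.body.n_beads, 2.5)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    lam = params.debye_length
    lo_s, hi_s = NPDESOLV_SHELL
    phi_el = np.zeros(len(pts))
    e_lj = np.zeros(len(pts))
    surf_dist = np.full(len(pts), np.inf)
    for i in range(len(coords)):
        d = np.linalg.norm(pts - coords[i], axis=1)
        d = np.maximum(d, 0.5)
        # potential inside a finite charged bead stays at its surface value
        d_el = np.maximum(d, radii[i])
        phi_el += params.bjerrum * solute.charges[i] * np.exp(-d_el / lam) / d_el
        sigma_i = 2 * radii[i]
        e_lj += (sigma_i / d) ** SOFTCORE_EXP
        surf_dist = np.minimum(surf_dist, d - radii[i])
    e_lj = np.minimum(e_lj, SOFTCORE_CAP)
    outside = np.maximum(surf_dist, 0.0)
    phi_edesolv = EDESOLV_SCALE * np.exp(-outside / EDESOLV_DECAY)
    phi_npdesolv = np.where((surf_dist >= lo_s) & (surf_dist <= hi_s),
                            NPDESOLV_BETA, 0.0)
    return EnergyGrids(
        phi_el=phi_el.reshape(shape), phi_edesolv=phi_edesolv.reshape(shape),
        phi_npdesolv=phi_npdesolv.reshape(shape), e_lj=e_lj.reshape(shape),
        origin=lo, spacing=float(spacing),
    )


# ---------------------------------------------------------------------------
# energy evaluation
# ---------------------------------------------------------------------------
def sda_energy(solute1: DockingSolute, solute2: DockingSolute,
               pose: Pose) -> Pose:
    """Fill the four energy terms of a pose (solute 1 fixed in its frame)."""
    if solute1.grids is None or solute2.grids is None:
        raise ValueError("both solutes need grids (build_grids)")
    p2 = pose.apply(solute2.body.body_coords)        # beads of 2 in frame of 1
    inv = Rotation.from_quat(pose.quat).inv()
    p1 = inv.apply(solute1.body.body_coords - pose.translation)  # 1 in frame 2

    g1, g2 = solute1.grids, solute2.grids
    q1, q2 = solute1.charges, solute2.charges
    el = 0.5 * float(g1.interpolate("phi_el", p2) @ q2) + \
        0.5 * float(g2.interpolate("phi_el", p1) @ q1)
    edesolv = float(g1.interpolate("phi_edesolv", p2) @ (q2 ** 2)) + \
        float(g2.interpolate("phi_edesolv", p1) @ (q1 ** 2))
    npdesolv = float(g1.interpolate("phi_npdesolv", p2) @ solute2.sasa) + \
        float(g2.interpolate("phi_npdesolv", p1) @ solute1.sasa)
    softcore = 0.5 * float(g1.interpolate("e_lj", p2).sum()) + \
        0.5 * float(g2.interpolate("e_lj", p1).sum())
    return replace(pose, el=el, edesolv=edesolv, npdesolv=npdesolv,
                   softcore=softcore)


# ---------------------------------------------------------------------------
# docking and clustering
# ---------------------------------------------------------------------------
def run_docking(solute1: DockingSolute, solute2: DockingSolute, n_starts=100,
                seed=0, n_moves=500, quench_fraction=0.4, trans_step=1.0,
                rot_step_deg=5.0, retention_threshold=0.0):
    """Metropolis relaxation from random start poses; retained bound poses.

    Each start places solute 2 at a random orientation on a sphere enclosing
    both solutes, then performs rigid-body Metropolis moves at the force-field
    temperature followed by a zero-temperature quench into the local minimum.
    Poses with total energy below *retention_threshold* (kT) are retained.
    Deterministic for a given seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    r_start = solute1.body.radius() + solute2.body.radius() + 8.0
    rot_step = np.deg2rad(rot_step_deg)
    n_quench = int(n_moves * quench_fraction)
    retained = []
    for _ in range(n_starts):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pose = Pose(quat=random_quaternion(rng), translation=r_start * u)
        pose = sda_energy(solute1, solute2, pose)
        for move in range(n_moves):
            beta = 1.0 if move < n_moves - n_quench else np.inf
            cand = Pose(
                quat=_perturb_quat(pose.quat, rot_step, rng),
                translation=pose.translation + rng.normal(scale=trans_step,
                                                          size=3),
            )
            cand = sda_energy(solute1, solute2, cand)
            d_e = cand.total - pose.total
            if d_e <= 0 or (np.isfinite(beta) and
                            rng.random() < np.exp(-beta * d_e)):
                pose = cand
        if pose.total < retention_threshold:
            retained.append(pose)
    return retained


def _perturb_quat(quat, rot_step, rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(scale=rot_step)
    dq = Rotation.from_rotvec(axis * angle)
    q = (dq * Rotation.from_quat(quat)).as_quat()
    return q / np.linalg.norm(q)


def pose_rmsd(pose_a: Pose, pose_b: Pose, body_coords):
    """RMSD between the solute-2 bead positions under two poses."""
    return float(np.sqrt(np.mean(np.sum(
        (pose_a.apply(body_coords) - pose_b.apply(body_coords)) ** 2, axis=1))))


def cluster_poses(poses, body_coords, rmsd_cutoff=10.0):
    """Greedy RMSD clustering; clusters ordered by decreasing population.

    The lowest-energy unassigned pose seeds each cluster and becomes its
    representative; members are all poses within *rmsd_cutoff* of it.
    Relative populations sum to 100%.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    remaining = sorted(poses, key=lambda p: p.total)
    clusters = []
    while remaining:
        rep = remaining[0]
        members, rest = [], []
        for p in remaining:
            if pose_rmsd(rep, p, body_coords) <= rmsd_cutoff:
                members.append(p)
            else:
                rest.append(p)
        spread = 0.0 if len(members) == 1 else float(np.sqrt(np.mean(
            [pose_rmsd(rep, p, body_coords) ** 2 for p in members])))
        clusters.append(PoseCluster(
            representative=rep, members=members,
            relpop=100.0 * len(members) / len(poses), spread=spread))
        remaining = rest
    clusters.sort(key=lambda c: -c.relpop)
    return clusters


def contact_residues(pose: Pose, protein: RigidBody, np_body: RigidBody,
                     cutoff=5.5, np_radius=None):
    """Residues with a bead within *cutoff* Å of the NP (closed interval).

    The protein is the fixed solute; the NP is placed by the pose.  For a CG
    NP the distance is to the nearest NP bead; for an MS NP it is the distance
    to the sphere surface (centre distance minus radius).
    """
    prot = protein.rotation().apply(protein.body_coords)
    np_coords = pose.apply(np_body.body_coords)
    ids = protein.residue_ids or [f"RES{i + 1}" for i in range(protein.n_beads)]
    if np_body.n_beads == 1:
        radius = ff.MSNP_SIGMA / 2 if np_radius is None else np_radius
        d = np.linalg.norm(prot - np_coords[0], axis=1) - radius
    else:
        d = np.min(np.linalg.norm(
            prot[:, None, :] - np_coords[None, :, :], axis=2), axis=1)
    return [ids[i] for i in np.where(d <= cutoff)[0]]


def clusters_to_tsv(clusters, path, protein=None, np_body=None, cutoff=5.5):
    """Write one row per cluster: relpop, energy terms, spread, contacts."""
    with open(path, "w") as fh:
        fh.write("relpop_pct\tU_rep_kT\tE_LJ+U_ds_kT\tU_ep_kT\tspread_A"
                 "\tcontacts\n")
        for c in clusters:
            rep = c.representative
            contacts = c.contacts
            if not contacts and protein is not None and np_body is not None:
                contacts = contact_residues(rep, protein, np_body, cutoff)
            nonpolar = rep.npdesolv + rep.softcore
            electro = rep.el + rep.edesolv
            fh.write(f"{c.relpop:.1f}\t{rep.total:.2f}\t{nonpolar:.2f}\t"
                     f"{electro:.2f}\t{c.spread:.2f}\t"
                     f"{','.join(contacts)}\n")
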