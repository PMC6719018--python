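"""Rigid-body ensemble dynamics in a periodic box.

Two integrators are provided for the same rigid-body representation:

* a Langevin thermostat (BAOAB splitting) acting on centre-of-mass velocities
  and body-frame angular velocities, used for the mesoscale ensemble runs
  (default friction 0.001 ps⁻¹, dt 0.15 ps);
* an overdamped Brownian (Ermak-McCammon) propagator driven by translational
  and rotational diffusion coefficients, matching the multi-solute
  Brownian-dynamics protocol (default dt 0.4 ps).

Orientations are unit quaternions updated through the exponential map; the
torque-free precession term omega x (I omega) is kept in the velocity update.
Hydrodynamic interactions between bodies are neglected (free-draining).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .bodies import RigidBody, random_quaternion
from .forcefield import FFParams, PairTable, find_pairs
from .units import KB, KDA_TO_G, LITRE_TO_A3, CP_TO_INTERNAL


@dataclass
class SimulationConfig:
    """Integration settings; times in ps, lengths in Å, temperature in K."""

    timestep: float = 0.15
    n_steps: int = 1000
    temperature: float = 300.0
    friction: float = 0.001          # ps^-1 (Langevin)
    dump_interval: float = 500.0     # ps
    box: np.ndarray = None           # (3,) Å or None for open boundaries
    seed: int = 0
    integrator: str = "langevin"

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.dump_interval < self.timestep:
            raise ValueError("dump_interval must be >= timestep")
        if self.integrator not in ("langevin", "brownian"):
            raise ValueError("integrator must be 'langevin' or 'brownian'")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)


@dataclass
class SystemState:
    """Ensemble of rigid bodies plus (for Langevin) velocities."""

    bodies: list
    velocities: np.ndarray = None           # (n_bodies, 3) Å/ps
    angular_velocities: np.ndarray = None   # (n_bodies, 3) rad/ps, body frame
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(
            bodies=[b.copy() for b in self.bodies],
            velocities=None if self.velocities is None else self.velocities.copy(),
            angular_velocities=(None if self.angular_velocities is None
                                else self.angular_velocities.copy()),
            time=self.time,
        )


class Trajectory:
    """Dumped frames of a run: COMs, quaternions and per-term energies."""

    def __init__(self, bodies):
        self.bodies = [b.copy() for b in bodies]
        self.times = []
        self.coms = []
        self.quats = []
        self.e_hs = []
        self.e_el = []

    def append(self, time, coms, quats, ehs, eel):
        self.times.append(time)
        self.coms.append(coms.copy())
        self.quats.append(quats.copy())
        self.e_hs.append(ehs)
        self.e_el.append(eel)

    @property
    def n_frames(self):
        return len(self.times)

    def frame_bead_coords(self, t):
        """All bead lab coordinates at frame *t*, (n_beads, 3)."""
        mats = Rotation.from_quat(self.quats[t]).as_matrix()
        out = []
        for k, b in enumerate(self.bodies):
            out.append(b.body_coords @ mats[k].T + self.coms[t][k])
        return np.concatenate(out)

    def frame_points(self, t, kind):
        """Reference points of bodies of a given kind at frame *t*.

        Proteins use the COM; NPs use their centre bead (AU bead for the CG
        model, the sphere for the MS model).
        """
        pts = []
        for k, b in enumerate(self.bodies):
            if b.kind != kind:
                continue
            if b.center_index is not None:
                rot = Rotation.from_quat(self.quats[t][k])
                pts.append(rot.apply(b.body_coords[b.center_index]) +
                           self.coms[t][k])
            else:
                pts.append(self.coms[t][k])
        return np.array(pts)

    def energies_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("time_ps\ths_kT\tel_kT\ttotal_kT\n")
            for t, hs, el in zip(self.times, self.e_hs, self.e_el):
                fh.write(f"{t:.6g}\t{hs:.6f}\t{el:.6f}\t{hs + el:.6f}\n")

    def to_xyz(self, path, box=None):
        from .fixtures import write_trajectory
        labels = [s for b in self.bodies for s in b.species]
        frames = [self.frame_bead_coords(t) for t in range(self.n_frames)]
        write_trajectory(frames, path, fmt="xyz", labels=labels, box=box)


# ---------------------------------------------------------------------------
# setup helpers
# ---------------------------------------------------------------------------
def box_from_concentrations(molecules, concentrations):
    """Cubic box side lengths from species masses and mass concentrations.

    *molecules* maps species name -> (count, mass_kDa); *concentrations* maps
    species name -> g/L.  Each species implies a volume; inconsistent volumes
    are reconciled by their geometric mean.
    """
    vols = []
    for name, (count, mass) in molecules.items():
        conc = concentrations[name]
        if conc <= 0:
            raise ValueError("concentration must be > 0")
        if count <= 0:
            raise ValueError("need at least one molecule")
        grams = count * mass * KDA_TO_G
        vols.append(grams / conc * LITRE_TO_A3)
    if not vols:
        raise ValueError("no molecules given")
    volume = float(np.exp(np.mean(np.log(vols))))
    side = volume ** (1.0 / 3.0)
    return np.array([side, side, side])


def init_random_nonoverlapping(box, molecules, params: FFParams, seed=0,
                               max_attempts=2000):
    """Place copies of the given bodies at random poses without overlaps.

    No inter-body bead pair ends up closer than 0.9 of its pair contact
    distance r0.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    table = PairTable(params, sorted({s for b in molecules for s in b.species}))
    factor = 0.9
    placed, pos_list, sp_list = [], [], []
    rmax = factor * table.r0.max()
    for proto in molecules:
        body = proto.copy()
        sidx = table.species_index(body.species)
        for attempt in range(max_attempts):
            com = rng.uniform(0, 1, size=3) * box
            quat = random_quaternion(rng)
            coords = Rotation.from_quat(quat).apply(body.body_coords) + com
            if not pos_list:
                break
            existing = np.concatenate(pos_list)
            esp = np.concatenate(sp_list)
            d = coords[:, None, :] - existing[None, :, :]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d, axis=2)
            limit = factor * table.r0[sidx[:, None], esp[None, :]]
            if np.all(r >= limit):
                break
        else:
            raise RuntimeError(
                f"could not place body {len(placed)} after {max_attempts} attempts")
        body.com = com
        body.quat = quat
        placed.append(body)
        pos_list.append(coords)
        sp_list.append(sidx)
    return SystemState(bodies=placed)


def maxwell_boltzmann_velocities(state: SystemState, temperature, seed=0):
    """Draw COM and angular velocities from the equilibrium distribution."""
    rng = np.random.default_rng(seed)
    n = len(state.bodies)
    kt = KB * temperature
    m = np.array([b.mass for b in state.bodies])
    inertia = np.array([b.inertia for b in state.bodies])
    state.velocities = rng.normal(size=(n, 3)) * np.sqrt(kt / m)[:, None]
    state.angular_velocities = rng.normal(size=(n, 3)) * np.sqrt(kt / inertia)
    return state


def kinetic_temperature(state: SystemState):
    """Instantaneous kinetic temperature (K): translational, rotational."""
    m = np.array([b.mass for b in state.bodies])
    inertia = np.array([b.inertia for b in state.bodies])
    n = len(state.bodies)
    ke_t = 0.5 * np.sum(m[:, None] * state.velocities ** 2)
    ke_r = 0.5 * np.sum(inertia * state.angular_velocities ** 2)
    return 2 * ke_t / (3 * n * KB), 2 * ke_r / (3 * n * KB)


def stokes_einstein_coefficients(body: RigidBody, temperature=300.0,
                                 viscosity_cp=0.89, params: FFParams = None,
                                 bead_radius=None):
    """Stokes-Einstein diffusion coefficients of a rigid body.

    The hydrodynamic radius is the largest bead distance from the COM plus a
    bead radius (half the species sigma when *params* is given).  Returns
    (D_t, D_r) in Å²/ps and rad²/ps.
    """
    if bead_radius is None:
        if params is not None:
            bead_radius = max(params.species[s].sigma for s in body.species) / 2
        else:
            bead_radius = 2.5
    radius = body.radius() + bead_radius
    if radius <= 0:
        raise ValueError("hydrodynamic radius must be > 0")
    kt = KB * temperature
    eta = viscosity_cp * CP_TO_INTERNAL
    d_t = kt / (6 * np.pi * eta * radius)
    d_r = kt / (8 * np.pi * eta * radius ** 3)
    return d_t, d_r


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------
class SimulationEngine:
    """Caches flattened bead arrays, the pair table and the neighbour list."""

    def __init__(self, state: SystemState, config: SimulationConfig,
                 params: FFParams, skin=5.0):
        self.state = state
        self.config = config
        self.params = params
        self.skin = skin
        if config.box is not None and np.any(config.box < 2 * params.cutoff):
            raise ValueError("box must be at least twice the cutoff")
        bodies = state.bodies
        self.n_bodies = len(bodies)
        labels = sorted({s for b in bodies for s in b.species})
        self.table = PairTable(params, labels)
        self.body_pos = np.concatenate([b.body_coords for b in bodies])
        self.bead_body = np.concatenate(
            [np.full(b.n_beads, k, dtype=np.intp) for k, b in enumerate(bodies)])
        self.sidx = np.concatenate(
            [self.table.species_index(b.species) for b in bodies])
        self.mass = np.array([b.mass for b in bodies])
        self.inertia = np.array([b.inertia for b in bodies])
        self.frozen = np.array([b.frozen for b in bodies])
        self.com = np.array([b.com for b in bodies], dtype=float)
        self.quat = np.array([b.quat for b in bodies], dtype=float)
        self.d_t = np.array([b.d_t for b in bodies])
        self.d_r = np.array([b.d_r for b in bodies])
        self.rng = np.random.default_rng(config.seed)
        self.e_unit = KB * params.temperature       # kT_ff in kDa Å²/ps²
        self.kt_cfg = KB * config.temperature
        self.overlap_warnings = 0
        if config.integrator == "langevin":
            if state.velocities is None:
                maxwell_boltzmann_velocities(state, config.temperature,
                                             seed=config.seed + 1)
            self.vel = state.velocities
            self.omega = state.angular_velocities
        self._pairs = None
        self._ref_positions = None
        self.compute_forces()

    # -- geometry -----------------------------------------------------------
    def world_positions(self):
        mats = Rotation.from_quat(self.quat).as_matrix()
        return (np.einsum("nij,nj->ni", mats[self.bead_body], self.body_pos)
                + self.com[self.bead_body])

    def _rebuild_pairs(self, pos):
        rcut = self.params.cutoff + self.skin
        i, j = find_pairs(pos, rcut, self.config.box)
        keep = self.bead_body[i] != self.bead_body[j]
        self._pairs = (i[keep], j[keep])
        self._ref_positions = pos.copy()

    def compute_forces(self):
        from ._kernels import pair_forces
        box = self.config.box
        mats = Rotation.from_quat(self.quat).as_matrix()
        self._mats = mats
        pos = (np.einsum("nij,nj->ni", mats[self.bead_body], self.body_pos)
               + self.com[self.bead_body])
        if self._pairs is None or np.max(
                np.abs(pos - self._ref_positions)) > self.skin / 2:
            self._rebuild_pairs(pos)
        i, j = self._pairs
        fbead = np.zeros_like(pos)
        boxarr = box if box is not None else np.zeros(3)
        e_hs, e_el, n_over = pair_forces(
            pos, i, j, self.sidx, self.table.r0, self.table.eps,
            self.table.qq, self.table.hs_shift, self.params.debye_length,
            self.table.el_shift_unit, self.params.cutoff, boxarr,
            box is not None, fbead)
        self.e_hs = float(e_hs)
        self.e_el = float(e_el)
        self.overlap_warnings += int(n_over)
        lever = pos - self.com[self.bead_body]
        if box is not None:
            # bead may be in a different periodic image than its wrapped COM
            lever -= box * np.round(lever / box)
        tq_bead = np.cross(lever, fbead)
        force = np.empty((self.n_bodies, 3))
        tq = np.empty((self.n_bodies, 3))
        for d in range(3):
            force[:, d] = np.bincount(self.bead_body, weights=fbead[:, d],
                                      minlength=self.n_bodies)
            tq[:, d] = np.bincount(self.bead_body, weights=tq_bead[:, d],
                                   minlength=self.n_bodies)
        self.force = force
        self.torque_body = np.einsum("nji,nj->ni", mats, tq)

    # -- integrators --------------------------------------------------------
    def _kick(self, half_dt):
        mob = ~self.frozen
        acc = self.force * self.e_unit / self.mass[:, None]
        self.vel[mob] += half_dt * acc[mob]
        l_body = self.inertia * self.omega
        gyro = np.cross(self.omega, l_body)
        alpha = (self.torque_body * self.e_unit - gyro) / self.inertia
        self.omega[mob] += half_dt * alpha[mob]

    def _drift(self, half_dt):
        mob = ~self.frozen
        self.com[mob] += half_dt * self.vel[mob]
        rotvec = self.omega * half_dt
        dq = Rotation.from_rotvec(rotvec)
        rot = Rotation.from_quat(self.quat) * dq
        q = rot.as_quat()
        q /= np.linalg.norm(q, axis=1)[:, None]
        self.quat[mob] = q[mob]

    def langevin_step(self):
        dt = self.config.timestep
        gamma = self.config.friction
        self._kick(dt / 2)
        self._drift(dt / 2)
        # O: Ornstein-Uhlenbeck on velocities and angular velocities
        if gamma > 0:
            c1 = np.exp(-gamma * dt)
            c2 = np.sqrt(1.0 - c1 * c1)
            mob = ~self.frozen
            sig_v = np.sqrt(self.kt_cfg / self.mass)[:, None]
            sig_w = np.sqrt(self.kt_cfg / self.inertia)
            self.vel[mob] = (c1 * self.vel[mob] +
                             c2 * sig_v[mob] * self.rng.normal(size=(mob.sum(), 3)))
            self.omega[mob] = (c1 * self.omega[mob] +
                               c2 * sig_w[mob] * self.rng.normal(size=(mob.sum(), 3)))
        self._drift(dt / 2)
        self._wrap()
        self.compute_forces()
        self._kick(dt / 2)
        self.state.time += dt

    def brownian_step(self):
        dt = self.config.timestep
        mob = ~self.frozen
        beta_scale = self.params.temperature / self.config.temperature
        dx = (self.d_t[:, None] * self.force * dt * beta_scale +
              np.sqrt(2 * self.d_t * dt)[:, None] * self.rng.normal(
                  size=(self.n_bodies, 3)))
        self.com[mob] += dx[mob]
        phi = (self.d_r[:, None] * self.torque_body * dt * beta_scale +
               np.sqrt(2 * self.d_r * dt)[:, None] * self.rng.normal(
                   size=(self.n_bodies, 3)))
        dq = Rotation.from_rotvec(phi)
        rot = Rotation.from_quat(self.quat) * dq
        q = rot.as_quat()
        q /= np.linalg.norm(q, axis=1)[:, None]
        self.quat[mob] = q[mob]
        self._wrap()
        self.compute_forces()
        self.state.time += dt

    def step(self):
        if self.config.integrator == "langevin":
            self.langevin_step()
        else:
            self.brownian_step()

    def _wrap(self):
        if self.config.box is not None:
            self.com %= self.config.box

    def sync_state(self):
        """Write engine arrays back into the RigidBody objects."""
        for k, b in enumerate(self.state.bodies):
            b.com = self.com[k].copy()
            b.quat = self.quat[k].copy()
        if self.config.integrator == "langevin":
            self.state.velocities = self.vel
            self.state.angular_velocities = self.omega
        return self.state


def langevin_step(state, config, params):
    """Advance one BAOAB Langevin step; returns the updated state."""
    engine = SimulationEngine(state, config, params)
    engine.langevin_step()
    return engine.sync_state()


def brownian_step(state, config, params):
    """Advance one Ermak-McCammon Brownian step; returns the updated state."""
    engine = SimulationEngine(state, config, params)
    engine.brownian_step()
    return engine.sync_state()


def run_simulation(state, config, params, progress=False):
    """Run n_steps, dumping positions/orientations/energies periodically.

    Returns the :class:`Trajectory`; the state is advanced in place and
    bitwise reproducible for a given seed and configuration.
    """
    engine = SimulationEngine(state, config, params)
    every = max(1, int(round(config.dump_interval / config.timestep)))
    traj = Trajectory(state.bodies)
    traj.append(state.time, engine.com, engine.quat, engine.e_hs, engine.e_el)
    for step in range(1, config.n_steps + 1):
        engine.step()
        if step % every == 0:
            traj.append(state.time, engine.com, engine.quat,
                        engine.e_hs, engine.e_el)
    engine.sync_state()
    return traj
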