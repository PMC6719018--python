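"""Binding-energy map of a protein over orientations facing an MS nanoparticle.

A surface point of the protein is labelled by the spherical angles (theta,
phi) of its direction in the body frame (theta polar from body +z, phi
azimuth from +x, right-handed).  For each grid orientation the protein is
rotated about its COM so that this direction points along the COM-to-NP axis,
and the total interaction energy is scanned over the COM-centre distance
d_COM; the minimum defines U_min(theta, phi).  The Boltzmann average of U_min
over the grid gives the binding energy E_b:

    E_b = sum_ij P_ij U_min(phi_i, theta_j) / sum_ij P_ij,
    P_ij = exp(-U_min / kT).

The default grid samples phi from 0 to 350 deg and theta from 0 to 170 deg in
10 deg steps (648 orientations).  The average is over grid cells as written
above; an optional sin(theta) solid-angle weighting is available behind a
flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import forcefield as ff
from .bodies import RigidBody


@dataclass
class OrientationGrid:
    """Strictly increasing angle grids in degrees."""

    phi: np.ndarray = field(default_factory=lambda: np.arange(0.0, 360.0, 10.0))
    theta: np.ndarray = field(default_factory=lambda: np.arange(0.0, 180.0, 10.0))

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        for arr, hi, name in ((self.phi, 360.0, "phi"), (self.theta, 180.0, "theta")):
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} values must be strictly increasing")
            if arr[0] < 0 or arr[-1] >= hi:
                raise ValueError(f"{name} values must lie in [0, {hi})")

    @property
    def n_orientations(self):
        return len(self.phi) * len(self.theta)


@dataclass
class BindingEnergyMap:
    """U_min (kT) and argmin distance (Å) on the (theta, phi) grid."""

    umin: np.ndarray       # (n_theta, n_phi)
    dmin: np.ndarray       # (n_theta, n_phi)
    grid: OrientationGrid
    temperature: float

    def to_tsv(self, path, meta_path=None):
        header = "theta_deg\\phi_deg\t" + "\t".join(f"{p:g}" for p in self.grid.phi)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for t, row in zip(self.grid.theta, self.umin):
                fh.write(f"{t:g}\t" + "\t".join(f"{u:.4f}" for u in row) + "\n")
        if meta_path:
            with open(meta_path, "w") as fh:
                json.dump({
                    "phi_deg": self.grid.phi.tolist(),
                    "theta_deg": self.grid.theta.tolist(),
                    "temperature_K": self.temperature,
                    "convention": "theta polar from body +z, phi azimuth from "
                                  "+x, right-handed; surface point faces the NP",
                    "units": {"umin": "kT", "dmin": "A"},
                }, fh, indent=1)


def direction(theta_deg, phi_deg):
    """Unit vector of body-frame spherical direction (degrees)."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                     np.cos(th)])


def orient_protein(protein: RigidBody, phi, theta) -> RigidBody:
    """Rotate the protein about its COM so the body-frame direction
    (theta, phi) points along +z (the COM-to-NP axis).  COM unchanged."""
    if not (0 <= phi < 360) or not (0 <= theta < 180):
        raise ValueError("angles out of range: phi in [0,360), theta in [0,180)")
    n = direction(theta, phi)
    z = np.array([0.0, 0.0, 1.0])
    rot = _rotation_between(n, z)
    out = protein.copy()
    out.quat = (rot * protein.rotation()).as_quat()
    out.quat /= np.linalg.norm(out.quat)
    return out


def _rotation_between(a, b):
    """Minimal rotation taking unit vector a to unit vector b."""
    c = float(np.dot(a, b))
    if c > 1 - 1e-12:
        return Rotation.identity()
    if c < -1 + 1e-12:
        # antipodal: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * axis / np.linalg.norm(axis))
    axis = np.cross(a, b)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * np.arccos(c))


def _pair_constants(protein: RigidBody, np_body: RigidBody, params: ff.FFParams):
    table = ff.PairTable(params, sorted(set(protein.species) |
                                        set(np_body.species)))
    si = table.species_index(protein.species)
    sj = table.species_index(np_body.species)
    return table, si, sj


def distance_scan(protein_oriented: RigidBody, np_body: RigidBody, params,
                  d_min=None, d_max=None, step=0.5):
    """U(d_COM) profile along +z; returns (umin, dmin, (d, U) profile).

    The scan starts at hard contact (half the largest pair sigma involving the
    NP) and ends where the interaction is negligible.
    """
    table, si, sj = _pair_constants(protein_oriented, np_body, params)
    if d_min is None:
        d_min = 0.5 * float(table.r0[si][:, sj].max())
    if d_max is None:
        d_max = (protein_oriented.radius() + 0.5 * float(np_body.radius())
                 + 0.5 * float(table.r0.max()) + params.cutoff)
    dvals = np.arange(d_min, d_max + step, step)
    if len(dvals) == 0:
        raise ValueError("empty distance range")
    pcoords = protein_oriented.rotation().apply(protein_oriented.body_coords)
    npcoords = np_body.rotation().apply(np_body.body_coords)
    # displacement of every protein bead from every NP bead at each scanned d
    base = pcoords[:, None, :] - npcoords[None, :, :]
    u = np.empty(len(dvals))
    sii = np.repeat(si, len(sj))
    sjj = np.tile(sj, len(si))
    for k, d in enumerate(dvals):
        dr = base - np.array([0.0, 0.0, d])
        r = np.linalg.norm(dr.reshape(-1, 3), axis=1)
        uhs, uel = table.pair_energies(r, sii, sjj)
        u[k] = uhs.sum() + uel.sum()
    kmin = int(np.argmin(u))
    return float(u[kmin]), float(dvals[kmin]), (dvals, u)


def build_map(protein: RigidBody, np_body: RigidBody, params,
              grid: OrientationGrid = None, step=0.5) -> BindingEnergyMap:
    """U_min over every grid orientation; deterministic."""
    grid = grid or OrientationGrid()
    umin = np.empty((len(grid.theta), len(grid.phi)))
    dmin = np.empty_like(umin)
    for i, theta in enumerate(grid.theta):
        for j, phi in enumerate(grid.phi):
            oriented = orient_protein(protein, phi, theta)
            u, d, _ = distance_scan(oriented, np_body, params, step=step)
            umin[i, j] = u
            dmin[i, j] = d
    return BindingEnergyMap(umin=umin, dmin=dmin, grid=grid,
                            temperature=params.temperature)


def boltzmann_binding_energy(bmap: BindingEnergyMap, solid_angle_weight=False):
    """Boltzmann-averaged binding energy E_b (kT).

    Weights P = exp(-U_min/kT) with U_min in kT units already; stabilized by
    subtracting the map minimum before exponentiation.  With
    *solid_angle_weight* each cell is additionally weighted by sin(theta).
    """
    u = np.asarray(bmap.umin, dtype=float)
    if u.size == 0:
        raise ValueError("empty binding-energy map")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite entries in the map")
    w = np.exp(-(u - u.min()))
    if solid_angle_weight:
        w = w * np.sin(np.deg2rad(bmap.grid.theta))[:, None]
    return float((w * u).sum() / w.sum())
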