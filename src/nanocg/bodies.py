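"""Rigid-body container shared by all modules.

A :class:`RigidBody` stores bead coordinates in a body-fixed frame (origin at
the centre of mass, axes along the principal axes of inertia), together with a
centre-of-mass position and a unit quaternion giving its orientation in the
laboratory frame.  Proteins, CG nanoparticles and MS nanoparticles are all
instances of the same type; they differ only in bead count, species table and
the ``kind`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass
class RigidBody:
    """A rigid molecule as a set of beads.

    Parameters
    ----------
    name : str
        Human-readable identifier.
    kind : str
        One of ``"protein"``, ``"np"`` or ``"generic"``; used by analysis
        selections.
    body_coords : (n, 3) ndarray
        Bead coordinates in the body frame (COM at the origin).
    species : list of str
        Force-field species label per bead.
    bead_masses : (n,) ndarray
        Per-bead masses, kDa.
    com : (3,) ndarray
        Centre of mass in the lab frame, Å.
    quat : (4,) ndarray
        Orientation as a scalar-last ``(x, y, z, w)`` unit quaternion.
    residue_ids : list of str, optional
        Per-bead residue identifiers (``"LYS6"`` style) for proteins.
    center_index : int, optional
        Index of the bead taken as the geometric reference point (the AU bead
        of a CG NP, the single bead of an MS NP).  ``None`` means use the COM.
    d_t, d_r : float
        Translational (Å²/ps) and rotational (rad²/ps) diffusion coefficients
        for Brownian dynamics; 0 until assigned.
    frozen : bool
        Frozen bodies are excluded from integration.
    """

    name: str
    kind: str
    body_coords: np.ndarray
    species: list
    bead_masses: np.ndarray
    com: np.ndarray
    quat: np.ndarray
    residue_ids: list | None = None
    center_index: int | None = None
    d_t: float = 0.0
    d_r: float = 0.0
    frozen: bool = False
    inertia: np.ndarray = field(default=None)  # principal, kDa Å²

    def __post_init__(self):
        self.body_coords = np.asarray(self.body_coords, dtype=float)
        self.bead_masses = np.asarray(self.bead_masses, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.inertia is None:
            self.inertia = principal_inertia(
                self.body_coords, self.bead_masses, min_inertia=self._min_inertia()
            )
        if abs(np.linalg.norm(self.quat) - 1.0) > 1e-9:
            raise ValueError("quaternion must be normalized")
        if np.any(self.inertia <= 0):
            raise ValueError("principal inertia must be positive")

    def _min_inertia(self) -> float:
        # point-like or collinear bodies get a solid-sphere floor so the
        # rotational equations stay well conditioned
        r = 2.0
        return 0.4 * float(self.bead_masses.sum()) * r * r

    # -- derived quantities -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.body_coords)

    @property
    def mass(self) -> float:
        return float(self.bead_masses.sum())

    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def world_coords(self) -> np.ndarray:
        """Bead coordinates in the lab frame, (n, 3) Å."""
        return self.rotation().apply(self.body_coords) + self.com

    def radius(self) -> float:
        """Maximal bead distance from the COM (hydrodynamic core radius)."""
        return float(np.linalg.norm(self.body_coords, axis=1).max())

    def copy(self) -> "RigidBody":
        return replace(
            self,
            body_coords=self.body_coords.copy(),
            species=list(self.species),
            bead_masses=self.bead_masses.copy(),
            com=self.com.copy(),
            quat=self.quat.copy(),
            residue_ids=None if self.residue_ids is None else list(self.residue_ids),
            inertia=self.inertia.copy(),
        )


IDENTITY_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


def principal_inertia(coords, masses, min_inertia=0.0):
    """Principal moments of inertia of point masses about their COM.

    Returns the three eigenvalues, floored at *min_inertia*.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = masses @ coords / masses.sum()
    d = coords - com
    r2 = (d * d).sum(axis=1)
    tensor = (masses[:, None, None] * (r2[:, None, None] * np.eye(3) -
                                       d[:, :, None] * d[:, None, :])).sum(axis=0)
    eig = np.linalg.eigvalsh(tensor)
    return np.maximum(eig, min_inertia)


def inertia_tensor(coords, masses):
    """Full 3x3 inertia tensor of point masses about their COM (kDa Å²)."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = masses @ coords / masses.sum()
    d = coords - com
    r2 = (d * d).sum(axis=1)
    return (masses[:, None, None] * (r2[:, None, None] * np.eye(3) -
                                     d[:, :, None] * d[:, None, :])).sum(axis=0)


def body_from_beads(name, kind, coords, species, masses, *, residue_ids=None,
                    center_index=None, orient_to_principal=True):
    """Build a :class:`RigidBody` from lab-frame bead coordinates.

    Coordinates are re-centred on the COM.  When *orient_to_principal* is true
    the body frame is rotated into the principal-axis frame and the quaternion
    set so that the lab-frame coordinates are unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = masses @ coords / masses.sum()
    local = coords - com
    quat = IDENTITY_QUAT.copy()
    if orient_to_principal and len(coords) > 1:
        tensor = inertia_tensor(coords, masses)
        _, vecs = np.linalg.eigh(tensor)
        if np.linalg.det(vecs) < 0:  # keep a right-handed frame
            vecs[:, -1] *= -1
        local = local @ vecs  # coordinates expressed on principal axes
        quat = Rotation.from_matrix(vecs).as_quat()
        quat = quat / np.linalg.norm(quat)
    return RigidBody(
        name=name, kind=kind, body_coords=local, species=list(species),
        bead_masses=masses, com=com, quat=quat, residue_ids=residue_ids,
        center_index=center_index,
    )


def random_quaternion(rng) -> np.ndarray:
    """Uniform random unit quaternion (scalar-last)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)
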