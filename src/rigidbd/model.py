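"""Domain types for solutes, conformations, poses and simulation settings.

A solute is one or more rigid all-atom *conformations*; each conformation
carries its interaction-site lists, its bundle of precomputed interaction
grids, and its infinite-dilution diffusion coefficients.  The instantaneous
pose of a solute is a :class:`RigidBodyState`: a position (the geometric
centre of the atoms, in the lab frame), a unit-quaternion orientation and,
for flexible solutes, the index of the currently active conformation.

Units: angstrom, picosecond, kcal/mol, elementary charge, kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import geometry
from .constants import kappa_from_ionic_strength


@dataclass
class RigidBodyState:
    """Position + proper rotation (+ active conformation) of one solute."""

    position: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: geometry.quat_identity())
    conformation_index: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")
        ori = np.asarray(self.orientation, dtype=float)
        if ori.shape == (3, 3):
            geometry.assert_rotation_matrix(ori)
            ori = _matrix_to_quat(ori)
        elif ori.shape != (4,):
            raise ValueError("orientation must be a unit quaternion or 3x3 rotation")
        self.orientation = geometry.quat_normalize(ori)

    def rotation_matrix(self) -> np.ndarray:
        return geometry.quat_to_matrix(self.orientation)

    def copy(self) -> "RigidBodyState":
        return RigidBodyState(self.position.copy(), self.orientation.copy(), self.conformation_index)

    def inverse_apply(self, lab_points: np.ndarray) -> np.ndarray:
        """Map lab-frame points into this body's frame: R^T (p - x)."""
        m = self.rotation_matrix()
        pts = np.atleast_2d(np.asarray(lab_points, dtype=float))
        return (pts - self.position) @ m


def _matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """Shepperd-style rotation-matrix -> quaternion conversion."""
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        return geometry.quat_normalize(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    i = int(np.argmax(np.diag(m)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = np.sqrt(max(m[i, i] - m[j, j] - m[k, k] + 1.0, 0.0)) * 2
    q = np.empty(4)
    q[0] = (m[k, j] - m[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (m[j, i] + m[i, j]) / s
    q[1 + k] = (m[k, i] + m[i, k]) / s
    return geometry.quat_normalize(q)


@dataclass
class Conformation:
    """One rigid structure of a solute, with its sites, grids and diffusivities.

    ``atom_positions`` / ``site_positions`` are body-frame coordinates; the
    body frame has its origin at the geometric centre of the atoms.
    """

    atom_positions: np.ndarray  # (n_atoms, 3) A
    atom_charges: Optional[np.ndarray] = None  # (n_atoms,) e
    atom_radii: Optional[np.ndarray] = None  # (n_atoms,) A
    site_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # effective charges
    site_charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    grid_set: Optional["SetOfGrid"] = None  # noqa: F821 (grids module)
    d_trans: float = 0.01  # A^2/ps
    d_rot: float = 0.001  # rad^2/ps
    stokes_radius: float = 1.0  # A
    label: str = ""

    def __post_init__(self):
        self.atom_positions = np.atleast_2d(np.asarray(self.atom_positions, dtype=float))
        self.site_positions = np.atleast_2d(np.asarray(self.site_positions, dtype=float)) if np.size(self.site_positions) else np.zeros((0, 3))
        self.site_charges = np.asarray(self.site_charges, dtype=float).reshape(-1)
        if self.atom_charges is not None:
            self.atom_charges = np.asarray(self.atom_charges, dtype=float).reshape(-1)
        if self.atom_radii is not None:
            self.atom_radii = np.asarray(self.atom_radii, dtype=float).reshape(-1)
        if len(self.site_positions) != len(self.site_charges):
            raise ValueError("site_positions and site_charges must have equal length")
        for name, val in (("d_trans", self.d_trans), ("d_rot", self.d_rot), ("stokes_radius", self.stokes_radius)):
            if not (val > 0 and np.isfinite(val)):
                raise ValueError(f"{name} must be positive and finite")
        if not np.all(np.isfinite(self.atom_positions)) or not np.all(np.isfinite(self.site_positions)):
            raise ValueError("coordinates must be finite")

    @property
    def net_charge(self) -> float:
        """Net effective charge (e)."""
        return float(self.site_charges.sum())

    @classmethod
    def from_structure(cls, records, **kwargs) -> "Conformation":
        """Build from a list of :class:`rigidbd.structure_io.StructureRecord`.

        Coordinates are recentred on their geometric midpoint; PQR charges,
        when present, become effective-charge sites at the atom positions.
        """
        pos = np.array([r.position for r in records], dtype=float)
        center = pos.mean(axis=0)
        pos = pos - center
        charges = np.array([r.charge if r.charge is not None else 0.0 for r in records])
        radii = np.array([r.radius if r.radius is not None else 0.0 for r in records])
        has_q = any(r.charge is not None for r in records)
        return cls(
            atom_positions=pos,
            atom_charges=charges if has_q else None,
            atom_radii=radii if any(r.radius is not None for r in records) else None,
            site_positions=pos[charges != 0] if has_q else np.zeros((0, 3)),
            site_charges=charges[charges != 0] if has_q else np.zeros(0),
            **kwargs,
        )


@dataclass
class Solute:
    """An ordered set of conformations plus the instantaneous pose."""

    conformations: Sequence[Conformation]
    state: RigidBodyState = field(default_factory=lambda: RigidBodyState(np.zeros(3)))
    label: str = "solute"

    def __post_init__(self):
        self.conformations = list(self.conformations)
        if not self.conformations:
            raise ValueError("a solute needs at least one conformation")
        if not (0 <= self.state.conformation_index < len(self.conformations)):
            raise ValueError("conformation_index out of range")

    @property
    def conformation(self) -> Conformation:
        return self.conformations[self.state.conformation_index]

    @property
    def d_trans(self) -> float:
        return self.conformation.d_trans

    @property
    def d_rot(self) -> float:
        return self.conformation.d_rot

    @property
    def stokes_radius(self) -> float:
        return self.conformation.stokes_radius

    def sites_lab(self) -> np.ndarray:
        """Effective-charge site positions in the lab frame."""
        return geometry.apply_pose(self.conformation.site_positions, self.state)


@dataclass
class BoundarySpec:
    """Simulation volume: sphere, periodic box or reflective box.

    ``planar_surface_z`` optionally places an impenetrable planar surface
    (the xy-plane at that height) used in adsorption set-ups.
    """

    kind: str = "sphere"  # sphere | box_periodic | box_reflective
    dimensions: np.ndarray = field(default_factory=lambda: np.array([100.0]))
    planar_surface_z: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("sphere", "box_periodic", "box_reflective"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        self.dimensions = np.atleast_1d(np.asarray(self.dimensions, dtype=float))
        if self.kind == "sphere":
            if self.dimensions.size != 1:
                raise ValueError("sphere boundary takes a single radius")
        else:
            if self.dimensions.size == 1:
                self.dimensions = np.repeat(self.dimensions, 3)
            if self.dimensions.size != 3:
                raise ValueError("box boundary takes one or three edge lengths")
        if np.any(self.dimensions <= 0):
            raise ValueError("boundary dimensions must be positive")

    @property
    def box_lengths(self) -> np.ndarray:
        if self.kind == "sphere":
            raise ValueError("sphere boundary has no box lengths")
        return self.dimensions

    def volume(self) -> float:
        if self.kind == "sphere":
            return 4.0 / 3.0 * np.pi * self.dimensions[0] ** 3
        return float(np.prod(self.dimensions))


@dataclass
class SwitchSchedule:
    """Timing of conformational-switch trial moves."""

    mode: str = "fixed"  # fixed | normal
    mean_interval: float = 1000.0  # ps
    sd_interval: float = 0.0  # ps, normal mode only
    nearest: bool = False
    criterion: str = "metropolis"  # always | downhill | metropolis

    def __post_init__(self):
        if self.mode not in ("fixed", "normal"):
            raise ValueError(f"unknown switch mode {self.mode!r}")
        if self.mean_interval <= 0:
            raise ValueError("mean_interval must be positive")
        if self.sd_interval < 0:
            raise ValueError("sd_interval must be non-negative")
        if self.criterion not in ("always", "downhill", "metropolis"):
            raise ValueError(f"unknown acceptance criterion {self.criterion!r}")


@dataclass
class SimulationConfig:
    """Global simulation parameters (one flat control file maps onto this)."""

    dt: float = 1.0  # ps
    temperature: float = 298.15  # K
    ionic_strength: float = 0.0  # M
    solvent_dielectric: float = 78.0
    cutoff: float = 100.0  # A
    boundary: Optional[BoundarySpec] = None
    master_seed: int = 0
    n_trajectories: int = 0
    n_steps: int = 0
    switch_schedule: Optional[SwitchSchedule] = None
    # two-zone time step (extension, off unless dt_far is set)
    dt_far: Optional[float] = None
    near_radius: Optional[float] = None
    # exclusion-move retries and occupancy clamp
    n_retry: int = 100
    phi_max: float = 0.74
    kappa: Optional[float] = None  # 1/A override; else from ionic strength

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.dt_far is not None and self.dt_far < self.dt:
            raise ValueError("dt_far must be >= dt")

    @property
    def debye_kappa(self) -> float:
        if self.kappa is not None:
            return self.kappa
        return kappa_from_ionic_strength(self.ionic_strength)

    def timestep_at(self, distance: float | np.ndarray) -> float | np.ndarray:
        """Time step as a function of centre-centre distance (two-zone)."""
        if self.dt_far is None or self.near_radius is None:
            return self.dt if np.isscalar(distance) else np.full(np.shape(distance), self.dt)
        return np.where(np.asarray(distance) < self.near_radius, self.dt, self.dt_far)
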