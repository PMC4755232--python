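"""Stochastic propagation of rigid bodies.

The propagator is the overdamped (inertia-free) update for independent
Brownian particles: per step, a deterministic drift (dt/kT) * D * F plus an
isotropic Gaussian displacement with per-component variance 2 D dt (so the
mean squared step is 6 D dt).  Rotation uses the analogous update on a
rotation vector, realised through the exponential map, with the torque in
place of the force and the rotational diffusion coefficient in place of the
translational one.

Also here: boundary handling (periodic wrap, reflective walls), the local
volume-fraction estimate and mean-field hydrodynamic scaling of diffusion
coefficients, and overlap rejection against exclusion grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from . import geometry
from .constants import kt
from .grids import interpolate
from .model import BoundarySpec, RigidBodyState, SimulationConfig, Solute

logger = logging.getLogger(__name__)

__all__ = [
    "BDStep",
    "OccupancyResult",
    "translation_step",
    "rotation_step",
    "local_occupancy",
    "scaled_diffusion",
    "tokuyama_short_time",
    "apply_boundary",
    "attempt_move_with_exclusion",
    "minimum_image",
    "step_rng",
]


@dataclass
class BDStep:
    drift: np.ndarray
    random_displacement: np.ndarray
    new_state: RigidBodyState


@dataclass
class OccupancyResult:
    phi: float
    neighbor_count: int


def step_rng(master_seed: int, step: int, stream: int = 0) -> np.random.Generator:
    """Counter-based RNG stream keyed by (master_seed, step, stream).

    Philox streams make draws independent of how work is split across
    workers: the noise consumed at a given step is a pure function of the
    key, never of execution order.  The step goes into the 128-bit *key*
    (not the counter), so the blocks generated at different steps can never
    overlap; distinct ``stream`` values start in disjoint counter ranges.
    """
    return np.random.Generator(
        np.random.Philox(key=np.array([master_seed, step], dtype=np.uint64),
                         counter=np.array([0, stream, 0, 0], dtype=np.uint64))
    )


def translation_step(
    state: RigidBodyState,
    force: np.ndarray,
    d_trans: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    dt: Optional[float] = None,
) -> BDStep:
    """One translational BD step: drift (dt/kT) D F plus Gaussian noise."""
    if d_trans <= 0:
        raise ValueError("d_trans must be positive")
    force = np.asarray(force, dtype=float).reshape(3)
    if not np.all(np.isfinite(force)):
        raise ValueError("non-finite force")
    dt = config.dt if dt is None else dt
    drift = dt * d_trans / kt(config.temperature) * force
    noise = rng.normal(0.0, np.sqrt(2.0 * d_trans * dt), size=3)
    new = state.copy()
    new.position = state.position + drift + noise
    return BDStep(drift=drift, random_displacement=noise, new_state=new)


def rotation_step(
    state: RigidBodyState,
    torque: np.ndarray,
    d_rot: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    dt: Optional[float] = None,
) -> RigidBodyState:
    """One rotational BD step via the exponential map of the rotation vector."""
    if d_rot <= 0:
        raise ValueError("d_rot must be positive")
    torque = np.asarray(torque, dtype=float).reshape(3)
    if not np.all(np.isfinite(torque)):
        raise ValueError("non-finite torque")
    dt = config.dt if dt is None else dt
    w = dt * d_rot / kt(config.temperature) * torque
    w = w + rng.normal(0.0, np.sqrt(2.0 * d_rot * dt), size=3)
    new = state.copy()
    new.orientation = geometry.quat_normalize(
        geometry.quat_multiply(geometry.quat_from_rotvec(w), state.orientation)
    )
    return new


def local_occupancy(center_solute: Solute, neighbors: Sequence[Solute], r_local: float) -> OccupancyResult:
    """Fractional occupancy of the sphere of radius r_local around a solute.

    Neighbours whose centres fall inside the sphere contribute their full
    Stokes volume (4/3) pi a^3; the solute itself is not counted.
    """
    if r_local <= 0:
        raise ValueError("r_local must be positive")
    center = center_solute.state.position
    phi = 0.0
    count = 0
    for nb in neighbors:
        if nb is center_solute:
            continue
        if np.linalg.norm(nb.state.position - center) <= r_local:
            phi += (nb.stokes_radius / r_local) ** 3
            count += 1
    return OccupancyResult(phi=phi, neighbor_count=count)


def tokuyama_short_time(phi: np.ndarray | float):
    """Short-time self-diffusion scaling D/D0 = 1/(1+H(phi)) of Tokuyama-Oppenheim.

    H(phi) = 2 b^2/(1-b) - c/(1+2c) - b c (2+c) / [(1+c)(1-b+c)]
    with b = sqrt(9 phi / 8), c = 11 phi / 16.
    """
    phi = np.asarray(phi, dtype=float)
    b = np.sqrt(9.0 * phi / 8.0)
    c = 11.0 * phi / 16.0
    h = 2.0 * b**2 / (1.0 - b) - c / (1.0 + 2.0 * c) - b * c * (2.0 + c) / ((1.0 + c) * (1.0 - b + c))
    s = 1.0 / (1.0 + h)
    return float(s) if s.ndim == 0 else s


_POLICIES: dict[str, Callable] = {"tokuyama": tokuyama_short_time}


def scaled_diffusion(d0: float, phi: float, policy: str = "tokuyama", phi_max: float = 0.74) -> float:
    """Mean-field hydrodynamic scaling of a diffusion coefficient.

    D = D0 * s(phi), with s(0)=1 and s strictly decreasing.  Occupancies at
    or above 1 (overlapping-sphere artefacts) are clamped to ``phi_max``.
    """
    if phi < 0:
        raise ValueError("phi must be non-negative")
    if phi >= 1.0:
        logger.warning("local occupancy %.3f >= 1 clamped to %.2f", phi, phi_max)
        phi = phi_max
    phi = min(phi, phi_max)
    return d0 * _POLICIES[policy](phi)


def minimum_image(d: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors in a periodic box."""
    return d - box_lengths * np.round(d / box_lengths)


def _reflect_axis(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mirror coordinates into [lo, hi] (handles multiple reflections)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def apply_boundary(state: RigidBodyState, boundary: BoundarySpec) -> RigidBodyState:
    """Wrap (periodic box) or mirror (reflective box/sphere) a position."""
    pos = np.asarray(state.position, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite position")
    new = state.copy()
    if boundary.kind == "box_periodic":
        L = boundary.box_lengths
        w = np.mod(pos, L)
        # np.mod of a tiny negative can round to exactly L; fold it back
        new.position = np.where(w >= L, w - L, w)
    elif boundary.kind == "box_reflective":
        L = boundary.box_lengths
        new.position = np.array([_reflect_axis(pos[i], 0.0, L[i]) for i in range(3)])
    else:  # sphere, reflective at the wall
        radius = boundary.dimensions[0]
        r = np.linalg.norm(pos)
        if r > radius:
            r_new = 2.0 * radius - r
            if r_new < 0:
                r_new = np.mod(r_new, radius)  # pathological excursions
            new.position = pos * (r_new / r)
    if boundary.planar_surface_z is not None and new.position[2] < boundary.planar_surface_z:
        new.position = new.position.copy()
        new.position[2] = 2.0 * boundary.planar_surface_z - new.position[2]
    return new


def _overlaps(solute: Solute, state: RigidBodyState, partners: Sequence[Solute]) -> bool:
    conf = solute.conformation
    probes = conf.atom_positions if len(conf.atom_positions) else conf.site_positions
    if len(probes) == 0:
        probes = np.zeros((1, 3))
    trial = state.copy()
    lab = geometry.apply_pose(probes, trial)
    for p in partners:
        mask = None if p.conformation.grid_set is None else p.conformation.grid_set.exclusion_mask
        if mask is None:
            continue
        body = p.state.inverse_apply(lab)
        if np.any(interpolate(mask, body) >= 0.5):
            return True
    return False


def attempt_move_with_exclusion(
    solute: Solute,
    proposed_state: RigidBodyState,
    partners: Sequence[Solute],
    redraw: Optional[Callable[[], RigidBodyState]] = None,
    n_retry: int = 100,
) -> RigidBodyState:
    """Accept a proposed move unless it lands inside a partner's exclusion grid.

    On overlap the stochastic part of the move is redrawn (``redraw`` returns
    a fresh proposal) up to ``n_retry`` times; if all retries overlap, the
    solute stays put.  Overlap means any atom (or charge site) of the moved
    solute interpolates to >= 0.5 on a partner's exclusion mask.
    """
    if not _overlaps(solute, proposed_state, partners):
        return proposed_state
    if redraw is not None:
        for _ in range(n_retry):
            trial = redraw()
            if not _overlaps(solute, trial, partners):
                return trial
    logger.debug("exclusion retries exhausted for %s; move rejected", solute.label)
    return solute.state.copy()
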