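"""Potential of mean force for adsorption to a planar surface.

The free energy of adsorption is a function of six rigid-body degrees of
freedom: the height z above the surface (the reaction coordinate, a line
perpendicular to the surface), two lateral offsets within a periodic
surface cell, and three orientation angles.  At every height the five
orthogonal degrees of freedom are sampled on a regular product grid with
equal subintervals, and the PMF is the Boltzmann-weighted free energy

    PMF(z) = -kT ln < exp(-E / kT) >_{orientations, offsets},

anchored to zero at the largest height.  The orientational average uses
sin(beta)-weighted quadrature for the polar Euler angle, so a uniform
orientation distribution is represented without bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import geometry
from .constants import kt
from .grids import SetOfGrid, interpolate
from .interactions import TERM_NAMES, _term_sites
from .model import RigidBodyState, Solute

__all__ = ["PMFSpec", "PMFProfile", "sample_surface_energies", "pmf_profile"]


@dataclass
class PMFSpec:
    """Sampling plan for the 6D adsorption free-energy calculation."""

    z_values: np.ndarray  # A, ascending
    n_rotations: int = 4  # subintervals per Euler angle
    lateral_extent: float = 0.0  # A, periodic surface cell edge (0 = single point)
    lateral_step: float = 1.0  # A
    temperature: float = 298.15  # K

    def __post_init__(self):
        self.z_values = np.asarray(self.z_values, dtype=float).reshape(-1)
        if np.any(np.diff(self.z_values) <= 0):
            raise ValueError("z_values must be sorted ascending")
        if self.n_rotations < 1 or self.lateral_step <= 0:
            raise ValueError("counts and steps must be positive")

    def euler_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(quaternions (m,4), weights (m,)) on the midpoint Euler product grid."""
        n = self.n_rotations
        alphas = (np.arange(n) + 0.5) * 2 * np.pi / n
        betas = (np.arange(n) + 0.5) * np.pi / n
        gammas = (np.arange(n) + 0.5) * 2 * np.pi / n
        quats, weights = [], []
        for a in alphas:
            qa = geometry.quat_from_rotvec(np.array([0.0, 0.0, a]))
            for b in betas:
                qb = geometry.quat_from_rotvec(np.array([0.0, b, 0.0]))
                for g in gammas:
                    qg = geometry.quat_from_rotvec(np.array([0.0, 0.0, g]))
                    quats.append(geometry.quat_multiply(qa, geometry.quat_multiply(qb, qg)))
                    weights.append(np.sin(b))
        w = np.asarray(weights)
        return np.asarray(quats), w / w.sum()

    def lateral_grid(self) -> np.ndarray:
        if self.lateral_extent <= 0:
            return np.zeros((1, 2))
        xs = np.arange(0.0, self.lateral_extent, self.lateral_step)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel()], axis=-1)


@dataclass
class PMFProfile:
    z: np.ndarray
    pmf: np.ndarray  # kcal/mol, anchored to 0 at the largest z
    n_samples: np.ndarray
    e_min: np.ndarray = field(default_factory=lambda: np.zeros(0))


def sample_surface_energies(
    solute: Solute,
    surface_grids: SetOfGrid,
    spec: PMFSpec,
    enabled_terms: Iterable[str] = ("electrostatic",),
) -> tuple[np.ndarray, np.ndarray]:
    """Interaction-energy samples of the solute over the surface.

    The surface grids live in the lab frame with the surface in the
    xy-plane.  For every height z the solute is placed at each lateral
    offset and orientation of the regular product grid and its enabled
    energy terms are summed over sites; samples that fall entirely outside
    the grids contribute zero energy.

    Returns (energies (n_z, n_samples), orientation weights (n_samples,)).
    """
    quats, wq = spec.euler_grid()
    lat = spec.lateral_grid()
    n_or, n_lat = len(quats), len(lat)
    weights = np.repeat(wq, n_lat) / n_lat
    rots = geometry.quat_to_matrix(quats)
    term_grids = []
    for term in enabled_terms:
        if term not in TERM_NAMES:
            raise ValueError(f"unknown term {term!r} for surface sampling")
        from .interactions import _TERM_GRID

        grid = surface_grids.get(_TERM_GRID[term])
        if grid is None:
            raise ValueError(f"surface grid for term {term!r} is missing")
        sites, w = _term_sites(solute, term)
        term_grids.append((grid, np.atleast_2d(sites), np.asarray(w, dtype=float)))
    energies = np.zeros((len(spec.z_values), n_or * n_lat))
    for iz, z in enumerate(spec.z_values):
        offsets = np.concatenate([lat, np.full((n_lat, 1), z)], axis=1)  # (n_lat, 3)
        for grid, sites, w in term_grids:
            if len(sites) == 0:
                continue
            rotated = np.einsum("oij,mj->omi", rots, sites)  # (n_or, m, 3)
            pts = rotated[:, None, :, :] + offsets[None, :, None, :]  # (n_or, n_lat, m, 3)
            vals = interpolate(grid, pts.reshape(-1, 3)).reshape(n_or, n_lat, len(sites))
            energies[iz] += (vals * w[None, None, :]).sum(axis=-1).reshape(-1)
    return energies, weights


def pmf_profile(
    samples: np.ndarray,
    temperature: float,
    z_values: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> PMFProfile:
    """Boltzmann-averaged PMF from per-height energy samples.

    PMF(z) = -kT ln sum_i w_i exp(-E_i/kT), computed with the per-height
    minimum subtracted before exponentiation (overflow-safe), then shifted
    so the profile vanishes at the largest height.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    nz, ns = samples.shape
    if ns < 1:
        raise ValueError("need at least one sample per height")
    w = np.full(ns, 1.0 / ns) if weights is None else np.asarray(weights, dtype=float) / np.sum(weights)
    beta = 1.0 / kt(temperature)
    e_min = samples.min(axis=1)
    ln_avg = np.log(np.sum(w[None, :] * np.exp(-beta * (samples - e_min[:, None])), axis=1))
    pmf = e_min - ln_avg / beta
    pmf = pmf - pmf[-1]
    z = np.arange(nz, dtype=float) if z_values is None else np.asarray(z_values, dtype=float)
    return PMFProfile(z=z, pmf=pmf, n_samples=np.full(nz, ns), e_min=e_min)
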