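"""Pairwise solute-solute energies, forces and torques.

Interactions follow the grid/site decomposition of rigid-body BD codes: a
precomputed scalar grid travels with one solute and the partner contributes
discrete interaction sites that sample the grid.  When both solutes carry a
grid for a term, the two one-sided evaluations are averaged; this restores
Newton's third law, which a single-sided grid evaluation breaks.

Term conventions (all energies kcal/mol):

* ``electrostatic``           sites = effective charges, weight q  (grid in kcal/(mol e))
* ``electro_desolvation``     sites = effective charges, weight q^2
* ``hydrophobic_desolvation`` sites = atoms, unit weight
* ``softcore``                sites = atoms, unit weight

Centre pairs whose site evaluations all fall outside the partner grids pick
up the analytic Debye-Hueckel correction between net charges, so the
electrostatic interaction does not simply vanish at the grid edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import grids as G
from .constants import COULOMB_CONSTANT
from .model import Solute

__all__ = [
    "InteractionTerms",
    "ForceTorque",
    "TERM_NAMES",
    "pair_energy",
    "pair_force_torque",
    "dh_correction",
]

#: energy terms in evaluation order; "dh_correction" is handled separately.
TERM_NAMES = ("electrostatic", "electro_desolvation", "hydrophobic_desolvation", "softcore")

_TERM_GRID = {
    "electrostatic": "electrostatic_potential",
    "electro_desolvation": "electro_desolvation",
    "hydrophobic_desolvation": "hydrophobic_desolvation",
    "softcore": "softcore_repulsion",
}


@dataclass
class InteractionTerms:
    electrostatic: float = 0.0
    electro_desolvation: float = 0.0
    hydrophobic_desolvation: float = 0.0
    softcore: float = 0.0
    dh_correction: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.electrostatic
            + self.electro_desolvation
            + self.hydrophobic_desolvation
            + self.softcore
            + self.dh_correction
        )

    def as_dict(self) -> dict:
        return {
            "electrostatic": self.electrostatic,
            "electro_desolvation": self.electro_desolvation,
            "hydrophobic_desolvation": self.hydrophobic_desolvation,
            "softcore": self.softcore,
            "dh_correction": self.dh_correction,
            "total": self.total,
        }


@dataclass
class ForceTorque:
    """Force (kcal/(mol A)) and torque about the solute centre (kcal/(mol rad))."""

    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torque: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float).reshape(3)
        self.torque = np.asarray(self.torque, dtype=float).reshape(3)


class MissingGridError(ValueError):
    """A requested energy term needs a grid that neither solute provides."""


def _term_sites(solute: Solute, term: str):
    """(body-frame positions, weights) of the sites sampling a partner grid."""
    conf = solute.conformation
    if term == "electrostatic":
        return conf.site_positions, conf.site_charges
    if term == "electro_desolvation":
        return conf.site_positions, conf.site_charges**2
    # hydrophobic desolvation and soft-core sample at the atom positions
    return conf.atom_positions, np.ones(len(conf.atom_positions))


def _grid_of(solute: Solute, term: str):
    gs = solute.conformation.grid_set
    return None if gs is None else gs.get(_TERM_GRID[term])


def _one_sided(grid_owner: Solute, site_owner: Solute, term: str):
    """Energy, per-site forces (lab frame) and site lab positions for one side.

    Returns (energy, f_lab (n,3), sites_lab (n,3), any_inside).
    """
    grid = _grid_of(grid_owner, term)
    pos_body, w = _term_sites(site_owner, term)
    if grid is None or len(pos_body) == 0:
        return 0.0, None, None, False
    m_site = site_owner.state.rotation_matrix()
    sites_lab = pos_body @ m_site.T + site_owner.state.position
    pts = grid_owner.state.inverse_apply(sites_lab)
    vals, inside = G.interpolate(grid, pts, return_inside=True)
    energy = float(np.sum(w * vals))
    grad_body = G.gradient(grid, pts)
    m_grid = grid_owner.state.rotation_matrix()
    f_lab = -(w[:, None] * grad_body) @ m_grid.T
    return energy, f_lab, sites_lab, bool(np.any(inside))


def pair_energy(
    solute_a: Solute,
    solute_b: Solute,
    enabled_terms: Iterable[str] = ("electrostatic",),
    config=None,
) -> InteractionTerms:
    """Interaction energy of a solute pair, term by term.

    For each enabled term the symmetric average of "sites of B on the grid
    of A" and "sites of A on the grid of B" is used when both grids exist;
    single-sided evaluation otherwise; a configuration error if neither
    solute carries the grid.
    """
    terms = InteractionTerms()
    enabled = list(enabled_terms)
    any_inside = False
    for term in enabled:
        if term == "dh_correction":
            continue
        if term not in TERM_NAMES:
            raise ValueError(f"unknown interaction term {term!r}")
        ga, gb = _grid_of(solute_a, term), _grid_of(solute_b, term)
        if ga is None and gb is None:
            raise MissingGridError(
                f"term {term!r} enabled but neither {solute_a.label!r} nor {solute_b.label!r} has the grid"
            )
        e_on_a, _, _, in_a = _one_sided(solute_a, solute_b, term) if ga is not None else (0.0, None, None, False)
        e_on_b, _, _, in_b = _one_sided(solute_b, solute_a, term) if gb is not None else (0.0, None, None, False)
        if ga is not None and gb is not None:
            e = 0.5 * (e_on_a + e_on_b)
        else:
            e = e_on_a + e_on_b
        if term == "electrostatic":
            any_inside = any_inside or in_a or in_b
        setattr(terms, term, e)
    if "dh_correction" in enabled and not any_inside:
        cfg = config
        r = float(np.linalg.norm(solute_b.state.position - solute_a.state.position))
        if r > 0:
            kappa = cfg.debye_kappa if cfg is not None else 0.0
            eps = cfg.solvent_dielectric if cfg is not None else 78.0
            a_sum = solute_a.stokes_radius + solute_b.stokes_radius
            e_dh, _ = dh_correction(
                solute_a.conformation.net_charge, solute_b.conformation.net_charge, r, kappa, eps, a_sum
            )
            terms.dh_correction = e_dh
    return terms


def pair_force_torque(
    solute_a: Solute,
    solute_b: Solute,
    enabled_terms: Iterable[str] = ("electrostatic",),
    config=None,
) -> tuple[ForceTorque, ForceTorque]:
    """Forces and torques on both solutes; action-reaction by construction.

    Per one-sided evaluation the force on each site of the sampling solute is
    -w * grad U at the site; the grid owner receives the opposite force,
    applied at the same site position, which fixes its torque about its own
    centre.
    """
    f_a, t_a = np.zeros(3), np.zeros(3)
    f_b, t_b = np.zeros(3), np.zeros(3)
    enabled = list(enabled_terms)
    any_inside = False
    for term in enabled:
        if term == "dh_correction":
            continue
        if term not in TERM_NAMES:
            raise ValueError(f"unknown interaction term {term!r}")
        ga, gb = _grid_of(solute_a, term), _grid_of(solute_b, term)
        if ga is None and gb is None:
            raise MissingGridError(
                f"term {term!r} enabled but neither {solute_a.label!r} nor {solute_b.label!r} has the grid"
            )
        both = ga is not None and gb is not None
        scale = 0.5 if both else 1.0
        if ga is not None:
            _, f_sites, sites_lab, inside = _one_sided(solute_a, solute_b, term)
            if f_sites is not None:
                if term == "electrostatic":
                    any_inside = any_inside or inside
                f = scale * f_sites
                f_b += f.sum(axis=0)
                t_b += np.cross(sites_lab - solute_b.state.position, f).sum(axis=0)
                f_a -= f.sum(axis=0)
                t_a += np.cross(sites_lab - solute_a.state.position, -f).sum(axis=0)
        if gb is not None:
            _, f_sites, sites_lab, inside = _one_sided(solute_b, solute_a, term)
            if f_sites is not None:
                if term == "electrostatic":
                    any_inside = any_inside or inside
                f = scale * f_sites
                f_a += f.sum(axis=0)
                t_a += np.cross(sites_lab - solute_a.state.position, f).sum(axis=0)
                f_b -= f.sum(axis=0)
                t_b += np.cross(sites_lab - solute_b.state.position, -f).sum(axis=0)
    if "dh_correction" in enabled and not any_inside:
        rvec = solute_b.state.position - solute_a.state.position
        r = float(np.linalg.norm(rvec))
        if r > 0:
            kappa = config.debye_kappa if config is not None else 0.0
            eps = config.solvent_dielectric if config is not None else 78.0
            a_sum = solute_a.stokes_radius + solute_b.stokes_radius
            _, f_rad = dh_correction(
                solute_a.conformation.net_charge, solute_b.conformation.net_charge, r, kappa, eps, a_sum
            )
            # f_rad > 0 pushes the solutes apart along the centre line
            u = rvec / r
            f_b += f_rad * u
            f_a -= f_rad * u
    return ForceTorque(f_a, t_a), ForceTorque(f_b, t_b)


def dh_correction(
    q_net_a: float,
    q_net_b: float,
    r: float | np.ndarray,
    kappa: float,
    dielectric: float,
    a_sum: float = 0.0,
) -> tuple:
    """Debye-Hueckel interaction of two net charges with finite-size factor.

    U(r) = 332.064 q_a q_b exp(kappa a_sum)/(1+kappa a_sum)
           * exp(-kappa r) / (dielectric r)   [kcal/mol]

    Returns (energy, radial force -dU/dr); positive force is repulsive.
    Broadcasts over ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("centre-centre distance must be positive")
    pref = COULOMB_CONSTANT * q_net_a * q_net_b * np.exp(kappa * a_sum) / (1.0 + kappa * a_sum)
    energy = pref * np.exp(-kappa * r) / (dielectric * r)
    force = energy * (kappa + 1.0 / r)  # -dU/dr
    if r.ndim == 0:
        return float(energy), float(force)
    return energy, force
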