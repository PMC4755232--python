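"""Uniform 3D scalar interaction grids.

A :class:`Grid3D` is a node-centred lattice with isotropic spacing.  Grid
values are potentials in kcal/(mol e) (electrostatic), energies in kcal/mol
(desolvation, soft-core) or {0,1} masks (exclusion).  Interpolation is
trilinear — continuous, cheap, and exact on affine fields — and queries
outside the grid volume return zero: the long-range part of the
electrostatic interaction is carried by the analytic Debye-Hueckel
correction, not by the grid.

The module also provides analytic grid builders (screened-Coulomb test
grids, exclusion masks, soft-core repulsion) and the effective-charge fit
that represents a solute's electrostatic potential by a small set of point
charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import COULOMB_CONSTANT

__all__ = [
    "Grid3D",
    "SetOfGrid",
    "interpolate",
    "gradient",
    "build_dh_test_grid",
    "build_exclusion_softcore",
    "fit_effective_charges",
]


@dataclass
class Grid3D:
    """A uniform, isotropic 3D scalar lattice."""

    origin: np.ndarray  # (3,) A, position of node (0,0,0)
    spacing: float  # A
    values: np.ndarray  # (nx, ny, nz)
    kind: str = "potential"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid needs at least 2 nodes per dimension")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        """Position of the last node along each axis."""
        return self.origin + self.spacing * (np.array(self.dims) - 1)

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [self.origin[d] + self.spacing * np.arange(self.dims[d]) for d in range(3)]
        return np.meshgrid(*axes, indexing="ij")

    def extent_radius(self) -> float:
        """Radius of the largest sphere centred at the grid centre inside the box."""
        half = 0.5 * self.spacing * (np.array(self.dims) - 1)
        return float(half.min())

    def center(self) -> np.ndarray:
        return self.origin + 0.5 * self.spacing * (np.array(self.dims) - 1)


@dataclass
class SetOfGrid:
    """The grid bundle describing one conformation's interaction fields.

    Any member may be ``None``, which switches the corresponding energy term
    off for this solute.  All grids share the conformation's body frame.
    """

    electrostatic_potential: Optional[Grid3D] = None
    electro_desolvation: Optional[Grid3D] = None
    hydrophobic_desolvation: Optional[Grid3D] = None
    softcore_repulsion: Optional[Grid3D] = None
    exclusion_mask: Optional[Grid3D] = None
    reaction_sites: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    reaction_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.reaction_sites = (
            np.atleast_2d(np.asarray(self.reaction_sites, dtype=float))
            if np.size(self.reaction_sites)
            else np.zeros((0, 3))
        )

    def get(self, term: str) -> Optional[Grid3D]:
        return getattr(self, term)


def _locate(grid: Grid3D, points: np.ndarray):
    """Cell indices, fractional offsets and an inside mask for query points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    t = (pts - grid.origin) / grid.spacing
    n = np.array(grid.dims)
    inside = np.all((t >= 0.0) & (t <= n - 1), axis=-1)
    idx = np.clip(np.floor(t).astype(int), 0, n - 2)
    frac = np.clip(t - idx, 0.0, 1.0)
    return pts, idx, frac, inside


def _corner_values(grid: Grid3D, idx: np.ndarray):
    i, j, k = idx[..., 0], idx[..., 1], idx[..., 2]
    v = grid.values
    return (
        v[i, j, k], v[i + 1, j, k], v[i, j + 1, k], v[i + 1, j + 1, k],
        v[i, j, k + 1], v[i + 1, j, k + 1], v[i, j + 1, k + 1], v[i + 1, j + 1, k + 1],
    )


def interpolate(grid: Grid3D, points: np.ndarray, return_inside: bool = False):
    """Trilinear interpolation of the grid at lab/body points (A).

    Points outside the grid volume evaluate to 0.  Scalar in, scalar out;
    arrays broadcast over the leading axis.
    """
    scalar_in = np.asarray(points).ndim == 1
    pts, idx, f, inside = _locate(grid, points)
    c000, c100, c010, c110, c001, c101, c011, c111 = _corner_values(grid, idx)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    out = (c0 * (1 - fz) + c1 * fz) * inside
    if scalar_in:
        out = float(out[0])
        inside = bool(inside[0])
    if return_inside:
        return out, inside
    return out


def gradient(grid: Grid3D, points: np.ndarray) -> np.ndarray:
    """Analytic spatial gradient of the trilinear interpolant (value/A).

    Zero outside the grid volume.  Within one cell of the boundary the
    interpolant is only C0 across cell faces, so finite differences that
    straddle a face may disagree there.
    """
    scalar_in = np.asarray(points).ndim == 1
    pts, idx, f, inside = _locate(grid, points)
    c000, c100, c010, c110, c001, c101, c011, c111 = _corner_values(grid, idx)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    h = grid.spacing
    # d/dx
    gx = (
        (c100 - c000) * (1 - fy) * (1 - fz)
        + (c110 - c010) * fy * (1 - fz)
        + (c101 - c001) * (1 - fy) * fz
        + (c111 - c011) * fy * fz
    ) / h
    gy = (
        (c010 - c000) * (1 - fx) * (1 - fz)
        + (c110 - c100) * fx * (1 - fz)
        + (c011 - c001) * (1 - fx) * fz
        + (c111 - c101) * fx * fz
    ) / h
    gz = (
        (c001 - c000) * (1 - fx) * (1 - fy)
        + (c101 - c100) * fx * (1 - fy)
        + (c011 - c010) * (1 - fx) * fy
        + (c111 - c110) * fx * fy
    ) / h
    g = np.stack([gx, gy, gz], axis=-1) * inside[..., None]
    return g[0] if scalar_in else g


def _screened_coulomb(r: np.ndarray, charge: float, kappa: float, dielectric: float) -> np.ndarray:
    return COULOMB_CONSTANT * charge * np.exp(-kappa * r) / (dielectric * r)


def build_dh_test_grid(
    point_charges,
    kappa: float,
    dielectric: float,
    origin,
    spacing: float,
    dims,
) -> Grid3D:
    """Analytic screened-Coulomb (Debye-Hueckel) potential grid.

    Node value = sum_k 332.064 q_k exp(-kappa r_k) / (dielectric r_k),
    kcal/(mol e).  Nodes closer than half a grid spacing to a source charge
    are clamped to the value at that distance, so the grid stays finite.
    """
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    origin = np.asarray(origin, dtype=float).reshape(3)
    dims = tuple(int(d) for d in dims)
    xs, ys, zs = np.meshgrid(*[origin[d] + spacing * np.arange(dims[d]) for d in range(3)], indexing="ij")
    nodes = np.stack([xs, ys, zs], axis=-1)
    values = np.zeros(dims)
    r_min = 0.5 * spacing
    for pos, q in point_charges:
        r = np.linalg.norm(nodes - np.asarray(pos, dtype=float), axis=-1)
        r = np.maximum(r, r_min)
        values += _screened_coulomb(r, q, kappa, dielectric)
    return Grid3D(origin=origin, spacing=spacing, values=values, kind="electrostatic_potential")


def build_exclusion_softcore(
    atoms,
    spacing: float,
    padding: float = 2.0,
    probe: float = 1.4,
    softcore_params: tuple[float, float, float] | None = (1.0, None, 6),
) -> tuple[Grid3D, Grid3D]:
    """Exclusion mask and soft-core repulsion grids for a set of atoms.

    ``atoms`` is a sequence of (position, radius A).  The exclusion node is 1
    iff it lies inside any atom sphere inflated by ``probe``; the soft-core
    value is sum_atoms A / (1 + (r/sigma)^n), with sigma defaulting to each
    atom's own radius.  Pass ``softcore_params=(0, ...)`` for an all-zero
    soft-core grid.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("build_exclusion_softcore needs at least one atom")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pos = np.array([a[0] for a in atoms], dtype=float)
    rad = np.array([a[1] for a in atoms], dtype=float)
    amp, sigma, n_exp = softcore_params if softcore_params is not None else (0.0, None, 6)
    lo = pos.min(axis=0) - rad.max() - probe - padding
    hi = pos.max(axis=0) + rad.max() + probe + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    xs, ys, zs = np.meshgrid(*[lo[d] + spacing * np.arange(dims[d]) for d in range(3)], indexing="ij")
    nodes = np.stack([xs, ys, zs], axis=-1)
    excl = np.zeros(tuple(dims))
    soft = np.zeros(tuple(dims))
    for p, a in zip(pos, rad):
        r = np.linalg.norm(nodes - p, axis=-1)
        excl = np.maximum(excl, (r <= a + probe).astype(float))
        if amp != 0.0:
            s = a if sigma is None else sigma
            soft += amp / (1.0 + (r / s) ** n_exp)
    return (
        Grid3D(origin=lo, spacing=spacing, values=excl, kind="exclusion_mask"),
        Grid3D(origin=lo, spacing=spacing, values=soft, kind="softcore_repulsion"),
    )


def fit_effective_charges(
    target_potential: Grid3D,
    site_positions,
    shell_inner: float,
    shell_outer: float,
    kappa: float,
    dielectric: float,
) -> np.ndarray:
    """Least-squares effective charges reproducing a target potential grid.

    Minimises, over grid nodes whose distance from the centroid of the sites
    lies in [shell_inner, shell_outer], the squared mismatch between the
    target potential and the screened-Coulomb potential of point charges at
    ``site_positions``.  Returns the fitted charges (e).
    """
    sites = np.atleast_2d(np.asarray(site_positions, dtype=float))
    if len(sites) == 0:
        raise ValueError("at least one site is required")
    if not (shell_outer > shell_inner > 0):
        raise ValueError("require shell_outer > shell_inner > 0")
    # degenerate (coincident) sites make the design matrix rank deficient
    if len(sites) > 1:
        d = np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=-1)
        iu = np.triu_indices(len(sites), k=1)
        bad = np.argwhere(d[iu] < 1e-6)
        if len(bad):
            pairs = [(int(iu[0][b]), int(iu[1][b])) for b in bad.ravel()]
            raise ValueError(f"coincident effective-charge sites: {pairs}")
    centroid = sites.mean(axis=0)
    xs, ys, zs = target_potential.node_coordinates()
    nodes = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=-1)
    dist = np.linalg.norm(nodes - centroid, axis=-1)
    mask = (dist >= shell_inner) & (dist <= shell_outer)
    if mask.sum() < len(sites):
        raise ValueError("shell contains fewer grid nodes than sites")
    nodes = nodes[mask]
    target = target_potential.values.ravel()[mask]
    r = np.linalg.norm(nodes[:, None, :] - sites[None, :, :], axis=-1)
    r = np.maximum(r, 1e-12)
    design = COULOMB_CONSTANT * np.exp(-kappa * r) / (dielectric * r)
    q, *_ = np.linalg.lstsq(design, target, rcond=None)
    return q
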