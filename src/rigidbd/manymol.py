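"""Many-molecule BD simulations (crowded-solution mode).

A single long trajectory of N solutes in a periodic or reflective volume:
per step, pair interactions within a cutoff (minimum image under
periodicity), optional mean-field hydrodynamic scaling of the diffusion
coefficients by the local volume fraction, the BD move, exclusion-overlap
redraws and boundary handling.  Includes the box builder (`genbox`) that
realises a target mass concentration, on-the-fly radial distribution
functions, and post-hoc self-diffusion analysis (translational MSD and
rotational autocorrelation).

Determinism contract: the per-step noise comes from a counter-based stream
keyed by (master_seed, step), and pair forces are accumulated in fixed
solute-index order, so results are bit-identical for any worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import geometry
from .constants import AVOGADRO, kt
from .engine import minimum_image, scaled_diffusion, step_rng
from .interactions import dh_correction, pair_energy, pair_force_torque
from .model import BoundarySpec, Conformation, RigidBodyState, SimulationConfig, Solute

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesSpec",
    "BoxConfiguration",
    "Trajectory",
    "RDFTable",
    "genbox",
    "box_edge_length",
    "ManyMoleculeSimulation",
    "run_many_molecule",
    "rdf",
    "translational_diffusion_msd",
    "rotational_diffusion",
]


@dataclass
class SpeciesSpec:
    """One solute species: template conformations plus its molar mass."""

    conformations: Sequence[Conformation]
    molar_mass: float  # g/mol
    label: str = "species"

    @property
    def radius(self) -> float:
        return self.conformations[0].stokes_radius


@dataclass
class BoxConfiguration:
    solutes: list[Solute]
    boundary: BoundarySpec
    concentration: float  # mg/ml
    molar_masses: dict[str, float] = field(default_factory=dict)


def box_edge_length(counts_and_masses: Sequence[tuple[int, float]], concentration: float) -> float:
    """Cubic box edge (A) for given (count, molar mass g/mol) at c mg/ml.

    V = sum(n M) / (N_A c); 1 mg/ml = 1 g/l and 1 l = 1e27 A^3.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    total_mass = sum(n * m for n, m in counts_and_masses)  # g/mol
    volume_l = total_mass / (AVOGADRO * concentration)
    return float((volume_l * 1e27) ** (1.0 / 3.0))


def genbox(
    n_per_species: Sequence[int],
    species: Sequence[SpeciesSpec],
    concentration: float,
    boundary_kind: str = "box_periodic",
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 10_000,
) -> BoxConfiguration:
    """Random non-overlapping start configuration at a target concentration.

    Solutes are placed by rejection sampling: a candidate position (uniform
    in the box) and orientation (uniform on SO(3)) is rejected if the
    Stokes spheres of the new and any placed solute overlap (minimum-image
    distances under periodicity).
    """
    rng = np.random.default_rng() if rng is None else rng
    if len(n_per_species) != len(species):
        raise ValueError("n_per_species and species must align")
    L = box_edge_length([(n, s.molar_mass) for n, s in zip(n_per_species, species)], concentration)
    boundary = BoundarySpec(kind=boundary_kind, dimensions=np.array([L, L, L]))
    periodic = boundary_kind == "box_periodic"
    placed_pos: list[np.ndarray] = []
    placed_rad: list[float] = []
    solutes: list[Solute] = []
    box = np.array([L, L, L])
    for n, spec in zip(n_per_species, species):
        for i in range(n):
            ok = False
            for _ in range(max_retries):
                pos = rng.random(3) * box
                if placed_pos:
                    d = np.asarray(placed_pos) - pos
                    if periodic:
                        d = minimum_image(d, box)
                    dist = np.linalg.norm(d, axis=1)
                    if np.any(dist < np.asarray(placed_rad) + spec.radius):
                        continue
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place solute {len(solutes) + 1} "
                    f"({len(solutes)} placed); packing too dense"
                )
            placed_pos.append(pos)
            placed_rad.append(spec.radius)
            solutes.append(
                Solute(
                    conformations=list(spec.conformations),
                    state=RigidBodyState(pos, geometry.random_quaternion(rng)),
                    label=f"{spec.label}_{i}",
                )
            )
    return BoxConfiguration(
        solutes=solutes,
        boundary=boundary,
        concentration=concentration,
        molar_masses={s.label: s.molar_mass for s in species},
    )


# ---------------------------------------------------------------- trajectory


@dataclass
class Trajectory:
    """Stored frames of a many-molecule run.

    Positions are wrapped into the box; ``wrap_counts`` holds per-axis image
    counters so unwrapped displacements (for MSD) are exact.
    """

    times: np.ndarray  # (F,) ps
    positions: np.ndarray  # (F, N, 3) wrapped
    wrap_counts: np.ndarray  # (F, N, 3) int
    orientations: np.ndarray  # (F, N, 4)
    conformation_indices: np.ndarray  # (F, N)
    energies: np.ndarray  # (F,) total pair energy at the frame
    boundary: BoundarySpec

    def unwrapped(self) -> np.ndarray:
        if self.boundary.kind == "box_periodic":
            return self.positions + self.wrap_counts * self.boundary.box_lengths
        return self.positions

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class RDFTable:
    bin_centers: np.ndarray
    g: np.ndarray
    g_se: np.ndarray
    bin_width: float
    r_max: float
    frame_count: int


class ManyMoleculeSimulation:
    """BD of N solutes in a box, with optional crowding physics.

    ``hydrodynamics=True`` switches on the mean-field scaling of each
    solute's diffusion coefficients by the fractional occupancy of its local
    volume (radius ``r_local``, default 4x the largest Stokes radius).
    ``excluded_volume=True`` rejects moves that overlap Stokes spheres,
    redrawing the stochastic displacement up to ``config.n_retry`` times.
    """

    def __init__(
        self,
        box: BoxConfiguration,
        config: SimulationConfig,
        enabled_terms: Iterable[str] = (),
        hydrodynamics: bool = False,
        r_local: Optional[float] = None,
        excluded_volume: bool = False,
    ):
        self.box = box
        self.config = config
        self.enabled_terms = tuple(enabled_terms)
        self.hydrodynamics = hydrodynamics
        self.excluded_volume = excluded_volume
        max_rad = max(s.stokes_radius for s in box.solutes)
        self.r_local = 4.0 * max_rad if r_local is None else r_local
        if self.r_local <= max_rad:
            raise ValueError("r_local must exceed the largest Stokes radius")

    # total pair energy, from scratch (used for logging and checkpoints)
    def total_energy(self) -> float:
        solutes = self.box.solutes
        periodic = self.box.boundary.kind == "box_periodic"
        box = self.box.boundary.box_lengths if periodic else None
        if not self.enabled_terms:
            return 0.0
        if set(self.enabled_terms) == {"dh_correction"}:
            pos = np.array([s.state.position for s in solutes])
            total = 0.0
            for i in range(len(solutes)):
                d = pos[i + 1 :] - pos[i]
                if periodic:
                    d = minimum_image(d, box)
                r = np.linalg.norm(d, axis=1)
                sel = r <= self.config.cutoff
                if not np.any(sel):
                    continue
                qi = solutes[i].conformation.net_charge
                for j, rr in zip(np.where(sel)[0] + i + 1, r[sel]):
                    e, _ = dh_correction(
                        qi, solutes[j].conformation.net_charge, rr,
                        self.config.debye_kappa, self.config.solvent_dielectric,
                        solutes[i].stokes_radius + solutes[j].stokes_radius,
                    )
                    total += e
            return total
        total = 0.0
        for i in range(len(solutes)):
            for j in range(i + 1, len(solutes)):
                d, r = self._pair_vector(solutes[i], solutes[j], periodic, box)
                if r > self.config.cutoff:
                    continue
                total += self._pair_energy_min_image(solutes[i], solutes[j], d).total
        return total

    def _pair_vector(self, si, sj, periodic, box):
        d = sj.state.position - si.state.position
        if periodic:
            d = minimum_image(d, box)
        return d, float(np.linalg.norm(d))

    def _pair_energy_min_image(self, si, sj, d):
        # evaluate with sj shifted to its minimum image relative to si
        orig = sj.state.position.copy()
        sj.state.position = si.state.position + d
        try:
            return pair_energy(si, sj, self.enabled_terms, self.config)
        finally:
            sj.state.position = orig

    def _forces(self, n_workers: int = 1):
        """Forces/torques on all solutes; fixed accumulation order."""
        solutes = self.box.solutes
        n = len(solutes)
        periodic = self.box.boundary.kind == "box_periodic"
        box = self.box.boundary.box_lengths if periodic else None
        forces = np.zeros((n, 3))
        torques = np.zeros((n, 3))
        if not self.enabled_terms:
            return forces, torques
        dh_only = set(self.enabled_terms) == {"dh_correction"}
        pos = np.array([s.state.position for s in solutes])
        # chunking mimics a parallel first loop; reduction order is fixed
        chunks = np.array_split(np.arange(n), max(1, n_workers))
        for chunk in chunks:
            for i in chunk:
                d = pos - pos[i]
                if periodic:
                    d = minimum_image(d, box)
                r = np.linalg.norm(d, axis=1)
                r[i] = np.inf
                sel = np.where(r <= self.config.cutoff)[0]
                for j in sel:
                    if dh_only:
                        e, f_rad = dh_correction(
                            solutes[i].conformation.net_charge,
                            solutes[j].conformation.net_charge,
                            r[j], self.config.debye_kappa, self.config.solvent_dielectric,
                            solutes[i].stokes_radius + solutes[j].stokes_radius,
                        )
                        # force on i points away from j for like charges
                        forces[i] -= 0.5 * f_rad * d[j] / r[j]
                        forces[j] += 0.5 * f_rad * d[j] / r[j]
                    else:
                        if j < i:
                            continue  # grid pairs evaluated once
                        orig = solutes[j].state.position.copy()
                        solutes[j].state.position = pos[i] + d[j]
                        try:
                            ft_i, ft_j = pair_force_torque(
                                solutes[i], solutes[j], self.enabled_terms, self.config
                            )
                        finally:
                            solutes[j].state.position = orig
                        forces[i] += ft_i.force
                        torques[i] += ft_i.torque
                        forces[j] += ft_j.force
                        torques[j] += ft_j.torque
        return forces, torques

    def run(
        self,
        n_steps: int,
        master_seed: Optional[int] = None,
        n_workers: int = 1,
        save_interval: int = 1,
        energy_interval: int = 0,
    ) -> Trajectory:
        cfg = self.config
        seed = cfg.master_seed if master_seed is None else master_seed
        solutes = self.box.solutes
        n = len(solutes)
        boundary = self.box.boundary
        periodic = boundary.kind == "box_periodic"
        box = boundary.box_lengths if periodic else None
        kt_val = kt(cfg.temperature)
        dt = cfg.dt

        pos = np.array([s.state.position for s in solutes])
        quat = np.array([s.state.orientation for s in solutes])
        wraps = np.zeros((n, 3), dtype=np.int64)
        radii = np.array([s.stokes_radius for s in solutes])
        d_t = np.array([s.d_trans for s in solutes])
        d_r = np.array([s.d_rot for s in solutes])

        frames_t, frames_p, frames_w, frames_q, frames_c, frames_e = [], [], [], [], [], []

        def sync_states():
            for s, p, q in zip(solutes, pos, quat):
                s.state.position = p
                s.state.orientation = q

        def snapshot(step):
            frames_t.append(step * dt)
            frames_p.append(pos.copy())
            frames_w.append(wraps.copy())
            frames_q.append(quat.copy())
            frames_c.append(np.array([s.state.conformation_index for s in solutes]))
            if energy_interval and step % energy_interval == 0:
                e = self.total_energy()
                if not np.isfinite(e):
                    raise FloatingPointError(f"non-finite energy at step {step}")
                frames_e.append(e)
            else:
                frames_e.append(np.nan)

        sync_states()
        snapshot(0)
        for step in range(1, n_steps + 1):
            forces, torques = self._forces(n_workers=n_workers)

            d_t_eff, d_r_eff = d_t, d_r
            if self.hydrodynamics:
                dmat = pos[:, None, :] - pos[None, :, :]
                if periodic:
                    dmat = minimum_image(dmat, box)
                dist = np.linalg.norm(dmat, axis=-1)
                np.fill_diagonal(dist, np.inf)
                inside = dist <= self.r_local
                phi = (inside * (radii[None, :] / self.r_local) ** 3).sum(axis=1)
                scale = np.array(
                    [scaled_diffusion(1.0, p, phi_max=cfg.phi_max) for p in phi]
                )
                d_t_eff = d_t * scale
                d_r_eff = d_r * scale

            rng = step_rng(seed, step)
            noise = rng.normal(size=(n, 6))
            new_pos = (
                pos
                + (dt / kt_val) * d_t_eff[:, None] * forces
                + np.sqrt(2.0 * d_t_eff * dt)[:, None] * noise[:, :3]
            )
            w_rot = (dt / kt_val) * d_r_eff[:, None] * torques + np.sqrt(2.0 * d_r_eff * dt)[:, None] * noise[:, 3:]
            quat = geometry.quat_multiply(geometry.quat_from_rotvec(w_rot), quat)

            # exclusion redraw: resample the stochastic part for overlapping spheres
            if self.excluded_volume:
                for attempt in range(cfg.n_retry):
                    d = new_pos[:, None, :] - new_pos[None, :, :]
                    if periodic:
                        d = minimum_image(d, box)
                    dist = np.linalg.norm(d, axis=-1)
                    np.fill_diagonal(dist, np.inf)
                    bad = (dist < radii[None, :] + radii[:, None]).any(axis=1)
                    if not bad.any():
                        break
                    redraw = rng.normal(size=(int(bad.sum()), 3))
                    new_pos[bad] = (
                        pos[bad]
                        + (dt / kt_val) * d_t_eff[bad, None] * forces[bad]
                        + np.sqrt(2.0 * d_t_eff[bad] * dt)[:, None] * redraw
                    )
                else:
                    # leave overlapping movers at their previous positions
                    new_pos[bad] = pos[bad]

            if periodic:
                w_step = np.floor(new_pos / box).astype(np.int64)
                pos = new_pos - w_step * box
                # rounding can land exactly on the upper face; fold consistently
                over = pos >= box
                pos = np.where(over, pos - box, pos)
                w_step = w_step + over.astype(np.int64)
                wraps += w_step
            else:
                from .engine import apply_boundary

                for i in range(n):
                    st = RigidBodyState(new_pos[i], quat[i])
                    pos[i] = apply_boundary(st, boundary).position
            sync_states()
            if step % save_interval == 0:
                snapshot(step)

        return Trajectory(
            times=np.array(frames_t),
            positions=np.array(frames_p),
            wrap_counts=np.array(frames_w),
            orientations=np.array(frames_q),
            conformation_indices=np.array(frames_c),
            energies=np.array(frames_e),
            boundary=boundary,
        )


def run_many_molecule(box: BoxConfiguration, config: SimulationConfig, n_steps: int, **kwargs) -> Trajectory:
    """Convenience wrapper: build the simulation and run it."""
    sim = ManyMoleculeSimulation(box, config, kwargs.pop("enabled_terms", ()),
                                 hydrodynamics=kwargs.pop("hydrodynamics", False),
                                 r_local=kwargs.pop("r_local", None),
                                 excluded_volume=kwargs.pop("excluded_volume", False))
    return sim.run(n_steps, **kwargs)


# ------------------------------------------------------------------ analysis


def rdf(trajectory: Trajectory, bin_width: float = 1.0, r_max: Optional[float] = None) -> RDFTable:
    """Radial distribution function, minimum-image, ideal-gas normalised.

    The per-bin standard error is estimated from the frame-to-frame scatter
    of g(r), which treats frames as independent samples.
    """
    boundary = trajectory.boundary
    if boundary.kind != "box_periodic":
        raise ValueError("rdf requires a periodic box")
    box = boundary.box_lengths
    if r_max is None:
        r_max = float(box.min()) / 2.0
    if r_max > box.min() / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the box edge")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-9]
    centers = 0.5 * (edges[:-1] + edges[1:])
    nbins = len(centers)
    F, N = trajectory.positions.shape[:2]
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # expected pair count per shell for an ideal gas: C(N,2) * V_shell / V
    ideal_per_frame = N * (N - 1) / 2.0 * shell_vol / boundary.volume()
    g_frames = np.empty((F, nbins))
    iu = np.triu_indices(N, k=1)
    for f in range(F):
        d = trajectory.positions[f][iu[0]] - trajectory.positions[f][iu[1]]
        d = minimum_image(d, box)
        r = np.linalg.norm(d, axis=1)
        counts, _ = np.histogram(r, bins=edges)
        g_frames[f] = counts / ideal_per_frame
    g = g_frames.mean(axis=0)
    g_se = g_frames.std(axis=0, ddof=1) / np.sqrt(F) if F > 1 else np.zeros(nbins)
    return RDFTable(bin_centers=centers, g=g, g_se=g_se, bin_width=bin_width, r_max=r_max, frame_count=F)


def translational_diffusion_msd(trajectory: Trajectory, fit_window: Optional[int] = None) -> tuple[float, float]:
    """Translational self-diffusion from the MSD slope: D = slope/6.

    Averages the MSD over solutes and time origins (unwrapped coordinates),
    then fits a zero-intercept least-squares line over ``fit_window`` lags.
    Returns (D, standard error of the fit).
    """
    pos = trajectory.unwrapped()
    F = pos.shape[0]
    if fit_window is None:
        fit_window = max(2, F // 4)
    if fit_window >= F:
        raise ValueError("fit window longer than trajectory")
    lags = np.arange(1, fit_window + 1)
    msd = np.empty(fit_window)
    msd_se = np.empty(fit_window)
    for k, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]
        sq = np.sum(disp**2, axis=-1).ravel()
        msd[k] = sq.mean()
        msd_se[k] = sq.std(ddof=1) / np.sqrt(sq.size) if sq.size > 1 else 0.0
    t = lags * (trajectory.times[1] - trajectory.times[0])
    slope = float(np.sum(t * msd) / np.sum(t * t))
    resid = msd - slope * t
    dof = max(len(t) - 1, 1)
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(t * t)))
    return slope / 6.0, slope_se / 6.0


def rotational_diffusion(
    trajectory: Trajectory, fit_window: Optional[int] = None, axis: np.ndarray = (0.0, 0.0, 1.0)
) -> tuple[float, float]:
    """Rotational self-diffusion from <u(0).u(t)> = exp(-2 D_R t).

    Tracks a body-fixed unit vector, averages the orientational
    autocorrelation over solutes and time origins, and fits log C(t) over
    ``fit_window`` lags.  Returns (D_R, standard error).
    """
    F, N = trajectory.orientations.shape[:2]
    if fit_window is None:
        fit_window = max(2, F // 4)
    if fit_window >= F:
        raise ValueError("fit window longer than trajectory")
    u = np.asarray(axis, dtype=float)
    u /= np.linalg.norm(u)
    vecs = np.einsum(
        "fnij,j->fni", geometry.quat_to_matrix(trajectory.orientations.reshape(-1, 4)).reshape(F, N, 3, 3), u
    )
    lags = np.arange(1, fit_window + 1)
    corr = np.array([np.mean(np.sum(vecs[lag:] * vecs[:-lag], axis=-1)) for lag in lags])
    good = corr > 1e-3
    if good.sum() < 2:
        return 0.0, 0.0
    t = lags[good] * (trajectory.times[1] - trajectory.times[0])
    y = np.log(corr[good])
    slope = float(np.sum(t * y) / np.sum(t * t))
    resid = y - slope * t
    dof = max(len(t) - 1, 1)
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(t * t)))
    d_r = max(-slope / 2.0, 0.0)
    return d_r, slope_se / 2.0
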