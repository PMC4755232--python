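"""Bimolecular simulations: association rates, encounter-complex docking.

One solute is held at the origin (it still rotates); the other diffuses with
the combined translational diffusion coefficient D_rel = D_T(fixed) +
D_T(mobile), which accounts for the diffusion of the fixed partner.
Trajectories start with the mobile solute uniformly distributed on the
*b*-surface (a sphere of radius b where direct forces are negligible) and
end either when the reaction criteria are satisfied or when the
centre-centre separation reaches the truncation *c*-surface.  The fraction
beta of reactive trajectories is converted into a diffusional association
rate constant with the Northrup-Allison-McCammon (NAM) formula

    k_on = k(b) * beta / (1 - (1 - beta) * b/c),      k(b) = 4 pi D_rel b.

Trajectories are propagated in lockstep as a batch (vectorised over
trajectories); the single-trajectory API is a batch of one.  Encounter
complexes can be recorded along the way into a bounded lowest-energy
archive with RMSD deduplication, then grouped by average-linkage
hierarchical clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import geometry
from .constants import RATE_TO_PER_MOLAR_PER_SECOND, kt
from .grids import Grid3D, gradient, interpolate
from .interactions import TERM_NAMES, _term_sites
from .model import RigidBodyState, SimulationConfig, Solute

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionCriteria",
    "NAMInputs",
    "TrajectoryResult",
    "ComplexRecord",
    "ComplexArchive",
    "RateResult",
    "sample_b_surface",
    "check_contacts",
    "independent_contact_count",
    "BimolecularSimulation",
    "run_bimolecular_trajectory",
    "estimate_beta",
    "nam_rate",
    "record_complex",
    "rmsd_mobile",
    "cluster_complexes",
]


# --------------------------------------------------------------- criteria


@dataclass
class ReactionCriteria:
    """Native-contact reaction criteria for encounter-complex definition.

    ``contact_pairs`` indexes into the body-frame site lists
    ``sites_fixed`` / ``sites_mobile``.  A pair is *made* when its
    inter-site distance is at or below the threshold; the number of
    *independent* made pairs counts a greedy maximal subset in which, on
    each solute separately, the selected sites are mutually farther apart
    than ``independence_min_separation``.
    """

    sites_fixed: np.ndarray  # (nf, 3) body frame of fixed solute
    sites_mobile: np.ndarray  # (nm, 3) body frame of mobile solute
    contact_pairs: Sequence[tuple[int, int]]
    contact_distance: float = 6.0
    independence_min_separation: float = 5.0
    required_independent_contacts: int = 2
    window_distances: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.sites_fixed = np.atleast_2d(np.asarray(self.sites_fixed, dtype=float))
        self.sites_mobile = np.atleast_2d(np.asarray(self.sites_mobile, dtype=float))
        self.contact_pairs = [(int(i), int(j)) for i, j in self.contact_pairs]
        if not self.contact_pairs:
            raise ValueError("reaction criteria need at least one contact pair")
        if self.contact_distance <= 0 or self.independence_min_separation <= 0:
            raise ValueError("criteria distances must be positive")
        if self.required_independent_contacts < 1:
            raise ValueError("required_independent_contacts must be >= 1")

    @property
    def windows(self) -> np.ndarray:
        """Sorted window thresholds (A); the first entry is the tightest."""
        w = list(self.window_distances) if self.window_distances else [self.contact_distance]
        if self.contact_distance not in w:
            w.append(self.contact_distance)
        return np.array(sorted(w))


def independent_contact_count(
    distances: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    sites_fixed_lab: np.ndarray,
    sites_mobile_lab: np.ndarray,
    threshold: float,
    min_separation: float,
) -> int:
    """Greedy count of independent made contacts (ascending distance order)."""
    order = np.argsort(distances, kind="stable")
    chosen_f: list[int] = []
    chosen_m: list[int] = []
    count = 0
    for idx in order:
        if distances[idx] > threshold:
            break
        fi, mi = pairs[idx]
        ok = all(
            np.linalg.norm(sites_fixed_lab[fi] - sites_fixed_lab[fj]) > min_separation for fj in chosen_f
        ) and all(
            np.linalg.norm(sites_mobile_lab[mi] - sites_mobile_lab[mj]) > min_separation for mj in chosen_m
        )
        if ok:
            chosen_f.append(fi)
            chosen_m.append(mi)
            count += 1
    return count


def check_contacts(
    fixed_pose: RigidBodyState,
    mobile_pose: RigidBodyState,
    criteria: ReactionCriteria,
) -> tuple[int, dict[float, bool]]:
    """Independent contact count and per-window satisfaction for one pose pair."""
    sf = geometry.apply_pose(criteria.sites_fixed, fixed_pose)
    sm = geometry.apply_pose(criteria.sites_mobile, mobile_pose)
    d = np.array([np.linalg.norm(sf[i] - sm[j]) for i, j in criteria.contact_pairs])
    satisfied = {}
    n_at_default = 0
    for w in criteria.windows:
        n = independent_contact_count(
            d, criteria.contact_pairs, sf, sm, w, criteria.independence_min_separation
        )
        satisfied[float(w)] = n >= criteria.required_independent_contacts
        if w == criteria.contact_distance:
            n_at_default = n
    return n_at_default, satisfied


def sample_b_surface(b: float, rng: np.random.Generator) -> RigidBodyState:
    """Random start pose: uniform on the b-sphere, uniform orientation."""
    if b <= 0:
        raise ValueError("b must be positive")
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return RigidBodyState(position=b * v, orientation=geometry.random_quaternion(rng))


# ------------------------------------------------------------------ results


@dataclass
class TrajectoryResult:
    reacted: dict[float, bool]
    escaped: bool
    steps: int
    min_center_distance: float


@dataclass
class NAMInputs:
    b: float
    c: float
    d_rel: float
    beta: float
    beta_se: float = 0.0

    def __post_init__(self):
        if not (self.c > self.b > 0):
            raise ValueError("require c > b > 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")


def estimate_beta(reacted_flags: Sequence[bool] | np.ndarray, window: float | None = None) -> tuple[float, float]:
    """Reaction probability and its binomial standard error.

    ``reacted_flags`` is either a boolean sequence or a list of
    :class:`TrajectoryResult` (then ``window`` selects the threshold).
    """
    if window is not None and len(reacted_flags) and isinstance(reacted_flags[0], TrajectoryResult):
        flags = np.array([tr.reacted[window] for tr in reacted_flags], dtype=bool)
    else:
        flags = np.asarray(reacted_flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("no trajectories")
    beta = float(flags.mean())
    se = float(np.sqrt(beta * (1.0 - beta) / n))
    return beta, se


def nam_rate(nam: NAMInputs, b_rate: Optional[float] = None) -> float:
    """NAM association rate constant in A^3/ps.

    ``b_rate`` optionally overrides the no-interaction start-surface rate
    k(b) = 4 pi D_rel b (hook for centrosymmetric-potential corrections).
    """
    kb = 4.0 * np.pi * nam.d_rel * nam.b if b_rate is None else b_rate
    denom = 1.0 - (1.0 - nam.beta) * (nam.b / nam.c)
    return float(kb * nam.beta / denom)


def rate_to_molar(k_cubic_angstrom_per_ps: float) -> float:
    """Convert a rate constant from A^3/ps to M^-1 s^-1."""
    return k_cubic_angstrom_per_ps * RATE_TO_PER_MOLAR_PER_SECOND


@dataclass
class RateResult:
    """Outcome of a batch of bimolecular trajectories."""

    windows: np.ndarray
    reacted: np.ndarray  # (n_traj, n_windows) bool
    escaped: np.ndarray  # (n_traj,) bool
    steps: np.ndarray
    b: float
    c: float
    d_rel: float
    archive: Optional["ComplexArchive"] = None

    def beta(self, window: float | None = None) -> tuple[float, float]:
        j = 0 if window is None else int(np.argmin(np.abs(self.windows - window)))
        return estimate_beta(self.reacted[:, j])

    def k_on(self, window: float | None = None) -> tuple[float, float]:
        """(k_on, standard error) in A^3/ps at the given window."""
        beta, se = self.beta(window)
        k = nam_rate(NAMInputs(self.b, self.c, self.d_rel, beta, se))
        if beta in (0.0, 1.0):
            return k, 0.0
        dk = abs(nam_rate(NAMInputs(self.b, self.c, self.d_rel, min(beta + se, 1.0))) - k)
        return k, dk


# --------------------------------------------------------------- simulation


class BimolecularSimulation:
    """Two-solute BD with b-surface starts and c-surface truncation.

    Parameters
    ----------
    fixed, mobile : Solute
        The fixed (rotating) and diffusing solutes.
    criteria : ReactionCriteria
        Encounter definition; drives termination and window bookkeeping.
    config : SimulationConfig
        Time step (optionally two-zone via ``dt_far``/``near_radius``),
        temperature, ionic strength.
    b, c : float
        Start and truncation sphere radii (A), c > b.
    enabled_terms : iterable of str
        Interaction terms acting during the dynamics (empty = free diffusion).
    """

    def __init__(
        self,
        fixed: Solute,
        mobile: Solute,
        criteria: ReactionCriteria,
        config: SimulationConfig,
        b: float,
        c: float,
        enabled_terms: Iterable[str] = (),
    ):
        if not (c > b > 0):
            raise ValueError("require c > b > 0")
        self.fixed = fixed
        self.mobile = mobile
        self.criteria = criteria
        self.config = config
        self.b = float(b)
        self.c = float(c)
        self.enabled_terms = tuple(enabled_terms)
        self.d_rel = fixed.d_trans + mobile.d_trans
        bad = [t for t in self.enabled_terms if t not in TERM_NAMES + ("dh_correction",)]
        if bad:
            raise ValueError(f"unknown interaction terms {bad}")

    # -- batched force evaluation -----------------------------------------

    def _grid_terms(self):
        out = []
        for term in self.enabled_terms:
            if term == "dh_correction":
                continue
            gf = self.fixed.conformation.grid_set
            gm = self.mobile.conformation.grid_set
            from .interactions import _TERM_GRID

            grid_f = None if gf is None else gf.get(_TERM_GRID[term])
            grid_m = None if gm is None else gm.get(_TERM_GRID[term])
            if grid_f is None and grid_m is None:
                raise ValueError(f"term {term!r} enabled but no grid on either solute")
            out.append((term, grid_f, grid_m))
        return out

    def _forces(self, pos, quat_m, quat_f, grid_terms):
        """Batched force on mobile, torques on both (n,3) arrays."""
        n = len(pos)
        f_m = np.zeros((n, 3))
        t_m = np.zeros((n, 3))
        t_f = np.zeros((n, 3))
        any_inside = np.zeros(n, dtype=bool)
        rm = geometry.quat_to_matrix(quat_m)
        rf = geometry.quat_to_matrix(quat_f)
        for term, grid_f, grid_m in grid_terms:
            both = grid_f is not None and grid_m is not None
            scale = 0.5 if both else 1.0
            if grid_f is not None:
                sites, w = _term_sites(self.mobile, term)
                if len(sites):
                    ins = self._one_sided_batch(
                        grid_f, rf, np.zeros((n, 3)), rm, pos, sites, w, scale, f_m, t_m, t_f, sign=+1
                    )
                    if term == "electrostatic":
                        any_inside |= ins
            if grid_m is not None:
                sites, w = _term_sites(self.fixed, term)
                if len(sites):
                    ins = self._one_sided_batch(
                        grid_m, rm, pos, rf, np.zeros((n, 3)), sites, w, scale, f_m, t_m, t_f, sign=-1
                    )
                    if term == "electrostatic":
                        any_inside |= ins
        if "dh_correction" in self.enabled_terms:
            from .interactions import dh_correction

            r = np.linalg.norm(pos, axis=1)
            qa = self.fixed.conformation.net_charge
            qb = self.mobile.conformation.net_charge
            _, f_rad = dh_correction(
                qa, qb, np.maximum(r, 1e-9), self.config.debye_kappa, self.config.solvent_dielectric,
                self.fixed.stokes_radius + self.mobile.stokes_radius,
            )
            f_rad = np.where(any_inside, 0.0, f_rad)
            f_m += (f_rad / np.maximum(r, 1e-9))[:, None] * pos
        return f_m, t_m, t_f

    def _one_sided_batch(self, grid, r_grid, x_grid, r_site, x_site, sites, w, scale, f_m, t_m, t_f, sign):
        """Sites of one solute sampling the partner grid, for the whole batch.

        ``sign=+1``: sites belong to the mobile solute (grid on fixed);
        ``sign=-1``: sites belong to the fixed solute (grid on mobile).
        Accumulates force on the mobile solute and torques on both.
        """
        sites_lab = np.einsum("nij,mj->nmi", r_site, sites) + x_site[:, None, :]
        pts = np.einsum("nji,nmj->nmi", r_grid, sites_lab - x_grid[:, None, :])
        flat = pts.reshape(-1, 3)
        vals, inside = interpolate(grid, flat, return_inside=True)
        grad = gradient(grid, flat).reshape(sites_lab.shape)
        inside = inside.reshape(sites_lab.shape[:2])
        f_site = -scale * w[None, :, None] * np.einsum("nij,nmj->nmi", r_grid, grad)
        f_tot = f_site.sum(axis=1)
        if sign > 0:  # force acts on the mobile solute's sites
            f_m += f_tot
            t_m += np.cross(sites_lab - x_site[:, None, :], f_site).sum(axis=1)
            t_f += np.cross(sites_lab - x_grid[:, None, :], -f_site).sum(axis=1)
        else:  # sites on fixed; reaction force on the mobile grid owner
            f_m -= f_tot
            t_f += np.cross(sites_lab - x_site[:, None, :], f_site).sum(axis=1)
            t_m += np.cross(sites_lab - x_grid[:, None, :], -f_site).sum(axis=1)
        return inside.any(axis=1)

    # -- propagation -------------------------------------------------------

    def run(
        self,
        n_trajectories: int,
        master_seed: Optional[int] = None,
        max_steps: int = 1_000_000,
        archive: Optional["ComplexArchive"] = None,
        record_interval: int = 50,
    ) -> RateResult:
        """Propagate ``n_trajectories`` in lockstep and collect statistics."""
        cfg = self.config
        seed = cfg.master_seed if master_seed is None else master_seed
        rng0 = np.random.Generator(np.random.Philox(key=np.array([seed, 2**32], dtype=np.uint64)))
        n = int(n_trajectories)
        windows = self.criteria.windows
        nw = len(windows)

        # initial poses on the b-surface
        v = rng0.normal(size=(n, 3))
        pos = self.b * v / np.linalg.norm(v, axis=1, keepdims=True)
        quat_m = geometry.random_quaternion(rng0, n)
        quat_f = geometry.random_quaternion(rng0, n)

        grid_terms = self._grid_terms() if self.enabled_terms else []
        sf_body = self.criteria.sites_fixed
        sm_body = self.criteria.sites_mobile
        pairs = np.array(self.criteria.contact_pairs)
        centres_only = not np.any(sf_body) and not np.any(sm_body)
        need_rot = bool(grid_terms) or not centres_only
        simple = (
            self.criteria.required_independent_contacts == 1
            or len(self.criteria.contact_pairs) == 1
        )

        reacted = np.zeros((n, nw), dtype=bool)
        escaped = np.zeros(n, dtype=bool)
        steps = np.zeros(n, dtype=np.int64)
        active = np.arange(n)
        kt_val = kt(cfg.temperature)
        d_m_rot, d_f_rot = self.mobile.d_rot, self.fixed.d_rot

        step = 0
        while len(active) and step < max_steps:
            step += 1
            p = pos[active]
            r = np.linalg.norm(p, axis=1)
            dt = cfg.timestep_at(r)
            if np.isscalar(dt):
                dt = np.full(len(active), float(dt))
            rng = np.random.Generator(
                np.random.Philox(key=np.array([seed, step], dtype=np.uint64))
            )
            if grid_terms or "dh_correction" in self.enabled_terms:
                f_m, t_m, t_f = self._forces(p, quat_m[active], quat_f[active], grid_terms)
            else:
                f_m = t_m = t_f = None

            noise = rng.normal(size=(len(active), 9 if need_rot else 3))
            disp = np.sqrt(2.0 * self.d_rel * dt)[:, None] * noise[:, :3]
            if f_m is not None:
                disp = disp + (dt / kt_val)[:, None] * self.d_rel * f_m
            pos[active] = p + disp

            if need_rot:
                w_m = np.sqrt(2.0 * d_m_rot * dt)[:, None] * noise[:, 3:6]
                w_f = np.sqrt(2.0 * d_f_rot * dt)[:, None] * noise[:, 6:9]
                if t_m is not None:
                    w_m = w_m + (dt / kt_val)[:, None] * d_m_rot * t_m
                    w_f = w_f + (dt / kt_val)[:, None] * d_f_rot * t_f
                quat_m[active] = geometry.quat_multiply(geometry.quat_from_rotvec(w_m), quat_m[active])
                quat_f[active] = geometry.quat_multiply(geometry.quat_from_rotvec(w_f), quat_f[active])

            # reaction / escape bookkeeping
            p_new = pos[active]
            r_new = np.linalg.norm(p_new, axis=1)
            if centres_only:
                dists = r_new[:, None]  # single pair at the centres
                hit = dists[:, 0][:, None] <= windows[None, :]
            else:
                sf = np.einsum("nij,mj->nmi", geometry.quat_to_matrix(quat_f[active]), sf_body)
                sm = (
                    np.einsum("nij,mj->nmi", geometry.quat_to_matrix(quat_m[active]), sm_body)
                    + p_new[:, None, :]
                )
                dvec = sf[:, pairs[:, 0], :] - sm[:, pairs[:, 1], :]
                dists = np.linalg.norm(dvec, axis=-1)
                if simple:
                    hit = dists.min(axis=1)[:, None] <= windows[None, :]
                else:
                    hit = np.zeros((len(active), nw), dtype=bool)
                    cand = np.where(dists.min(axis=1) <= windows[-1])[0]
                    for row in cand:
                        for jw, wdist in enumerate(windows):
                            nin = independent_contact_count(
                                dists[row], self.criteria.contact_pairs, sf[row], sm[row],
                                wdist, self.criteria.independence_min_separation,
                            )
                            hit[row, jw] = nin >= self.criteria.required_independent_contacts
            reacted[active] |= hit

            if archive is not None and step % record_interval == 0:
                self._record_batch(archive, active, pos, quat_m, quat_f, grid_terms)

            done = reacted[active, 0] | (r_new >= self.c)
            escaped[active] |= (r_new >= self.c) & ~reacted[active, 0]
            steps[active] += 1
            active = active[~done]

        if len(active):
            logger.warning("%d trajectories exceeded the step budget; marked escaped", len(active))
            escaped[active] = True

        return RateResult(
            windows=windows, reacted=reacted, escaped=escaped, steps=steps,
            b=self.b, c=self.c, d_rel=self.d_rel, archive=archive,
        )

    def _record_batch(self, archive, active, pos, quat_m, quat_f, grid_terms):
        from .interactions import pair_energy

        for idx in active:
            self.mobile.state = RigidBodyState(pos[idx], quat_m[idx])
            self.fixed.state = RigidBodyState(np.zeros(3), quat_f[idx])
            try:
                terms = pair_energy(self.fixed, self.mobile, self.enabled_terms, self.config)
            except ValueError:
                continue
            if terms.total >= archive.energy_ceiling:
                continue
            archive.add(
                ComplexRecord(
                    position=pos[idx].copy(),
                    orientation=quat_m[idx].copy(),
                    energy=terms.total,
                    energy_terms=terms.as_dict(),
                    conformation_fixed=self.fixed.state.conformation_index,
                    conformation_mobile=self.mobile.state.conformation_index,
                )
            )


def run_bimolecular_trajectory(
    fixed: Solute,
    mobile: Solute,
    criteria: ReactionCriteria,
    config: SimulationConfig,
    rng_or_seed,
    b: float,
    c: float,
    enabled_terms: Iterable[str] = (),
    max_steps: int = 1_000_000,
) -> TrajectoryResult:
    """Run a single trajectory (a batch of one)."""
    seed = int(rng_or_seed.integers(2**31)) if hasattr(rng_or_seed, "integers") else int(rng_or_seed)
    sim = BimolecularSimulation(fixed, mobile, criteria, config, b, c, enabled_terms)
    res = sim.run(1, master_seed=seed, max_steps=max_steps)
    return TrajectoryResult(
        reacted={float(w): bool(res.reacted[0, j]) for j, w in enumerate(res.windows)},
        escaped=bool(res.escaped[0]),
        steps=int(res.steps[0]),
        min_center_distance=float("nan"),
    )


# ------------------------------------------------------- complex recording


@dataclass
class ComplexRecord:
    """A docked mobile-solute pose with its energy breakdown."""

    position: np.ndarray
    orientation: np.ndarray  # quaternion of the mobile solute
    energy: float
    energy_terms: dict = field(default_factory=dict)
    multiplicity: int = 1
    conformation_fixed: int = 0
    conformation_mobile: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = geometry.quat_normalize(np.asarray(self.orientation, dtype=float))


def rmsd_mobile(record_a: ComplexRecord, record_b: ComplexRecord, atom_subset: np.ndarray) -> float:
    """RMSD (A) of the mobile solute's atoms between two poses.

    Both records share the fixed-solute frame, so no re-superposition is
    performed: the fixed frame *is* the alignment.
    """
    atoms = np.atleast_2d(np.asarray(atom_subset, dtype=float))
    if atoms.size == 0:
        raise ValueError("atom subset must not be empty")
    ra = geometry.quat_to_matrix(record_a.orientation)
    rb = geometry.quat_to_matrix(record_b.orientation)
    pa = atoms @ ra.T + record_a.position
    pb = atoms @ rb.T + record_b.position
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


class ComplexArchive:
    """Bounded archive of the lowest-energy encounter complexes.

    A candidate within ``dedup_rmsd`` of an already archived, lower-energy
    record is not stored; instead that record's multiplicity is incremented,
    so cluster populations reflect the full sampling.  The archive keeps at
    most ``capacity`` records (lowest energies win); multiplicity of evicted
    records is retained in ``evicted_multiplicity``.
    """

    def __init__(self, capacity: int, atom_subset: np.ndarray, dedup_rmsd: float = 1.0,
                 energy_ceiling: float = np.inf):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self.atom_subset = np.atleast_2d(np.asarray(atom_subset, dtype=float))
        self.dedup_rmsd = float(dedup_rmsd)
        self.energy_ceiling = float(energy_ceiling)
        self.records: list[ComplexRecord] = []
        self.evicted_multiplicity = 0

    @property
    def total_multiplicity(self) -> int:
        return sum(r.multiplicity for r in self.records) + self.evicted_multiplicity

    def add(self, candidate: ComplexRecord) -> None:
        for rec in self.records:
            if rec.energy <= candidate.energy and rmsd_mobile(rec, candidate, self.atom_subset) <= self.dedup_rmsd:
                rec.multiplicity += candidate.multiplicity
                return
        self.records.append(candidate)
        self.records.sort(key=lambda r: r.energy)
        while len(self.records) > self.capacity:
            evicted = self.records.pop()
            self.evicted_multiplicity += evicted.multiplicity


def record_complex(archive: ComplexArchive, candidate: ComplexRecord) -> ComplexArchive:
    """Functional wrapper around :meth:`ComplexArchive.add`."""
    archive.add(candidate)
    return archive


# ------------------------------------------------------------- clustering


@dataclass
class Cluster:
    members: list[int]
    representative: int
    population: float  # percent of total multiplicity
    mean_energy: float


def cluster_complexes(
    records: Sequence[ComplexRecord],
    n_clusters: int,
    atom_subset: np.ndarray,
) -> list[Cluster]:
    """Average-linkage hierarchical clustering of docked poses by RMSD.

    Populations are percentages of the total multiplicity; the
    representative is the cluster medoid (minimal mean intra-cluster RMSD).
    Clusters are returned sorted by population, largest first.
    """
    records = list(records)
    if len(records) < n_clusters:
        raise ValueError("fewer records than requested clusters")
    n = len(records)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = rmsd_mobile(records[i], records[j], atom_subset)
    labels = fcluster(linkage(squareform(dmat, checks=False), method="average"), n_clusters, criterion="maxclust")
    total = sum(r.multiplicity for r in records)
    clusters = []
    for lab in np.unique(labels):
        members = [int(i) for i in np.where(labels == lab)[0]]
        sub = dmat[np.ix_(members, members)]
        representative = members[int(np.argmin(sub.mean(axis=1)))]
        pop = 100.0 * sum(records[i].multiplicity for i in members) / total
        mean_e = float(np.mean([records[i].energy for i in members]))
        clusters.append(Cluster(members=members, representative=representative, population=pop, mean_energy=mean_e))
    clusters.sort(key=lambda c: -c.population)
    return clusters
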