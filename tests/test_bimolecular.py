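import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from rigidbd.bimolecular import (
    BimolecularSimulation,
    ComplexArchive,
    ComplexRecord,
    NAMInputs,
    ReactionCriteria,
    check_contacts,
    cluster_complexes,
    estimate_beta,
    nam_rate,
    rmsd_mobile,
    run_bimolecular_trajectory,
    sample_b_surface,
)
from rigidbd.model import RigidBodyState, SimulationConfig

from conftest import make_point_solute


def centre_criteria(threshold):
    return ReactionCriteria(
        sites_fixed=np.zeros((1, 3)), sites_mobile=np.zeros((1, 3)),
        contact_pairs=[(0, 0)], contact_distance=threshold,
        required_independent_contacts=1,
    )


class TestBSurface:
    def test_radius_exact(self, rng):
        st = sample_b_surface(150.0, rng)
        assert np.linalg.norm(st.position) == pytest.approx(150.0, abs=1e-9)

    def test_mean_position_zero(self, rng):
        n = 20_000
        pos = np.array([sample_b_surface(1.0, rng).position for _ in range(n)])
        se = 1.0 / np.sqrt(3 * n)
        assert np.all(np.abs(pos.mean(axis=0)) < 3 * se)

    def test_z_uniform_hat_box(self, rng):
        # Archimedes: z of a uniform point on a sphere is uniform on [-b, b]
        z = np.array([sample_b_surface(1.0, rng).position[2] for _ in range(20_000)])
        assert kstest(z, "uniform", args=(-1.0, 2.0)).pvalue > 0.01


class TestCheckContacts:
    def make_criteria(self, fixed_sites, mobile_sites, pairs, **kw):
        return ReactionCriteria(sites_fixed=fixed_sites, sites_mobile=mobile_sites,
                                contact_pairs=pairs, **kw)

    def test_no_contacts_when_far(self):
        crit = centre_criteria(6.0)
        n, sat = check_contacts(RigidBodyState(np.zeros(3)), RigidBodyState(np.array([50.0, 0, 0])), crit)
        assert n == 0 and not sat[6.0]

    def test_close_fixed_sites_collapse_to_one(self):
        # two made pairs whose fixed-solute sites are 4 A apart (< 5): one independent
        crit = self.make_criteria(
            np.array([[0.0, 0, 0], [4.0, 0, 0]]),
            np.array([[0.0, 0, 1.0], [4.0, 0, 1.0]]),
            [(0, 0), (1, 1)],
        )
        n, sat = check_contacts(RigidBodyState(np.zeros(3)), RigidBodyState(np.zeros(3)), crit)
        assert n == 1
        assert not sat[6.0]

    def test_well_separated_sites_count_two(self):
        crit = self.make_criteria(
            np.array([[0.0, 0, 0], [8.0, 0, 0]]),
            np.array([[0.0, 0, 1.0], [8.0, 0, 1.0]]),
            [(0, 0), (1, 1)],
        )
        n, sat = check_contacts(RigidBodyState(np.zeros(3)), RigidBodyState(np.zeros(3)), crit)
        assert n == 2
        assert sat[6.0]

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            ReactionCriteria(sites_fixed=np.zeros((1, 3)), sites_mobile=np.zeros((1, 3)), contact_pairs=[])


class TestBetaAndRate:
    def test_beta_none_reacted(self):
        beta, se = estimate_beta(np.zeros(100, dtype=bool))
        assert beta == 0.0 and se == 0.0

    def test_beta_quarter(self):
        flags = np.zeros(100, dtype=bool)
        flags[:25] = True
        beta, se = estimate_beta(flags)
        assert beta == 0.25
        assert se == pytest.approx(0.0433, abs=1e-4)

    def test_beta_all_reacted(self):
        beta, se = estimate_beta(np.ones(100, dtype=bool))
        assert beta == 1.0 and se == 0.0

    def test_rate_zero_beta(self):
        assert nam_rate(NAMInputs(50.0, 100.0, 0.02, 0.0)) == 0.0

    def test_rate_beta_one_reduces_to_kb(self):
        assert nam_rate(NAMInputs(50.0, 100.0, 0.02, 1.0)) == pytest.approx(4 * np.pi * 0.02 * 50.0, rel=1e-12)

    def test_nam_inverts_first_passage_to_smoluchowski(self):
        # analytic beta for an absorbing sphere pushed through NAM gives 4 pi D R
        R, b, c, d = 10.0, 50.0, 100.0, 0.02
        beta = (1 / b - 1 / c) / (1 / R - 1 / c)
        assert nam_rate(NAMInputs(b, c, d, beta)) == pytest.approx(4 * np.pi * d * R, rel=1e-12)

    def test_rejects_c_not_beyond_b(self):
        with pytest.raises(ValueError):
            NAMInputs(100.0, 50.0, 0.02, 0.5)


class TestTrajectories:
    def test_unreachable_criteria_escape(self):
        fixed, mobile = make_point_solute(), make_point_solute()
        cfg = SimulationConfig(dt=5.0)
        res = run_bimolecular_trajectory(fixed, mobile, centre_criteria(1e-6), cfg, 7, b=20.0, c=25.0)
        assert res.escaped and not res.reacted[1e-6]

    def test_start_near_c_escapes_quickly(self):
        fixed, mobile = make_point_solute(), make_point_solute()
        cfg = SimulationConfig(dt=5.0)
        sim = BimolecularSimulation(fixed, mobile, centre_criteria(1.0), cfg, b=99.0, c=100.0)
        res = sim.run(200, master_seed=11, max_steps=100_000)
        assert res.escaped.mean() > 0.95
        assert res.steps.mean() < 1000

    def test_absorbing_sphere_first_passage_probability(self):
        # pure diffusion: P(react) = (1/b - 1/c) / (1/R - 1/c)
        R, b, c = 10.0, 20.0, 40.0
        fixed = make_point_solute(d_trans=0.01, d_rot=1e-4)
        mobile = make_point_solute(d_trans=0.01, d_rot=1e-4)
        cfg = SimulationConfig(dt=0.2, dt_far=5.0, near_radius=R + 4.0)
        sim = BimolecularSimulation(fixed, mobile, centre_criteria(R), cfg, b=b, c=c)
        res = sim.run(3000, master_seed=5, max_steps=400_000)
        beta, se = res.beta()
        analytic = (1 / b - 1 / c) / (1 / R - 1 / c)
        assert abs(beta - analytic) < 3 * max(se, 1e-6)

    def test_same_seed_reproducible(self):
        fixed, mobile = make_point_solute(), make_point_solute()
        cfg = SimulationConfig(dt=1.0, dt_far=10.0, near_radius=15.0)
        runs = [
            BimolecularSimulation(fixed, mobile, centre_criteria(10.0), cfg, b=20.0, c=40.0)
            .run(100, master_seed=42, max_steps=200_000)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].reacted, runs[1].reacted)
        np.testing.assert_array_equal(runs[0].steps, runs[1].steps)


def record_at(x, y, z, energy, quat=(1.0, 0, 0, 0), multiplicity=1):
    return ComplexRecord(position=np.array([x, y, z], dtype=float), orientation=np.array(quat),
                         energy=energy, multiplicity=multiplicity)


ATOMS = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1.0, 1.0, 0]])


class TestRMSD:
    def test_identical_poses_zero(self):
        a = record_at(1, 2, 3, -1.0)
        assert rmsd_mobile(a, a, ATOMS) == 0.0

    def test_pure_translation_closed_form(self):
        a = record_at(0, 0, 0, -1.0)
        b = record_at(3, 4, 0, -2.0)
        assert rmsd_mobile(a, b, ATOMS) == pytest.approx(5.0, rel=1e-12)

    def test_symmetric(self, rng):
        a = record_at(*rng.normal(size=3), -1.0)
        b = record_at(*rng.normal(size=3), -2.0)
        assert rmsd_mobile(a, b, ATOMS) == rmsd_mobile(b, a, ATOMS)

    def test_empty_subset_rejected(self):
        a = record_at(0, 0, 0, -1.0)
        with pytest.raises(ValueError):
            rmsd_mobile(a, a, np.zeros((0, 3)))


class TestArchive:
    def test_insert_into_empty(self):
        arc = ComplexArchive(capacity=10, atom_subset=ATOMS)
        arc.add(record_at(0, 0, 0, -1.0))
        assert len(arc.records) == 1 and arc.records[0].multiplicity == 1

    def test_duplicate_increments_multiplicity(self):
        arc = ComplexArchive(capacity=10, atom_subset=ATOMS, dedup_rmsd=1.0)
        arc.add(record_at(0, 0, 0, -2.0))
        arc.add(record_at(0.1, 0, 0, -1.0))  # within 1 A of a lower-energy record
        assert len(arc.records) == 1
        assert arc.records[0].multiplicity == 2

    def test_top_k_matches_full_sort(self, rng):
        arc = ComplexArchive(capacity=10, atom_subset=ATOMS, dedup_rmsd=1e-6)
        energies = rng.normal(size=100)
        positions = rng.uniform(0, 1000, size=(100, 3))  # far apart: no dedup
        for e, p in zip(energies, positions):
            arc.add(record_at(*p, e))
        kept = sorted(r.energy for r in arc.records)
        np.testing.assert_allclose(kept, np.sort(energies)[:10])

    def test_eviction_preserves_multiplicity_total(self, rng):
        arc = ComplexArchive(capacity=3, atom_subset=ATOMS, dedup_rmsd=1e-6)
        for i in range(10):
            arc.add(record_at(100.0 * i, 0, 0, float(i)))
        assert arc.total_multiplicity == 10
        assert [r.energy for r in arc.records] == [0.0, 1.0, 2.0]


def brute_force_average_linkage(dmat, n_clusters):
    """Exhaustive agglomerative average linkage (multiplicity-unweighted)."""
    clusters = [[i] for i in range(len(dmat))]
    while len(clusters) > n_clusters:
        best = None
        for (ia, a), (ib, b) in itertools.combinations(enumerate(clusters), 2):
            d = np.mean([dmat[i, j] for i in a for j in b])
            if best is None or d < best[0]:
                best = (d, ia, ib)
        _, ia, ib = best
        clusters[ia] = clusters[ia] + clusters[ib]
        del clusters[ib]
    return {frozenset(c) for c in clusters}


class TestClustering:
    def make_blobs(self, rng, centers, per_blob=5, spread=0.05):
        records = []
        for cx in centers:
            for _ in range(per_blob):
                records.append(record_at(cx + rng.normal() * spread, rng.normal() * spread, 0, rng.normal()))
        return records

    def test_identical_records_single_cluster(self):
        records = [record_at(0, 0, 0, -1.0) for _ in range(6)]
        clusters = cluster_complexes(records, 1, ATOMS)
        assert clusters[0].population == pytest.approx(100.0)

    def test_two_blobs_match_brute_force(self, rng):
        records = self.make_blobs(rng, [0.0, 20.0], per_blob=6)
        clusters = cluster_complexes(records, 2, ATOMS)
        n = len(records)
        dmat = np.array([[rmsd_mobile(a, b, ATOMS) for b in records] for a in records])
        expected = brute_force_average_linkage(dmat, 2)
        got = {frozenset(c.members) for c in clusters}
        assert got == expected

    def test_populations_sum_to_100(self, rng):
        records = self.make_blobs(rng, [0.0, 10.0, 30.0], per_blob=4)
        for r in records[:3]:
            r.multiplicity = 5
        clusters = cluster_complexes(records, 3, ATOMS)
        assert sum(c.population for c in clusters) == pytest.approx(100.0, abs=1e-9)

    def test_order_invariance(self, rng):
        records = self.make_blobs(rng, [0.0, 25.0], per_blob=5)
        c1 = cluster_complexes(records, 2, ATOMS)
        perm = rng.permutation(len(records))
        c2 = cluster_complexes([records[i] for i in perm], 2, ATOMS)
        sets1 = {frozenset(records[i].energy for i in c.members) for c in c1}
        sets2 = {frozenset(records[perm[i]].energy for i in c.members) for c in c2}
        assert sets1 == sets2

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            cluster_complexes([record_at(0, 0, 0, -1.0)], 2, ATOMS)
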