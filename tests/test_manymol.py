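import numpy as np
import pytest

from rigidbd.manymol import (
    BoxConfiguration,
    ManyMoleculeSimulation,
    SpeciesSpec,
    Trajectory,
    box_edge_length,
    genbox,
    rdf,
    rotational_diffusion,
    translational_diffusion_msd,
)
from rigidbd.engine import minimum_image
from rigidbd.model import BoundarySpec, Conformation, SimulationConfig


def sphere_species(radius=16.0, molar_mass=14_300.0, d_trans=0.01, d_rot=1e-3, charge=None):
    kwargs = dict(atom_positions=np.zeros((1, 3)), d_trans=d_trans, d_rot=d_rot, stokes_radius=radius)
    if charge is not None:
        kwargs.update(site_positions=np.zeros((1, 3)), site_charges=[charge])
    return SpeciesSpec(conformations=[Conformation(**kwargs)], molar_mass=molar_mass)


class TestGenbox:
    def test_edge_length_from_mass_balance(self):
        # 256 solutes of 14300 g/mol at 150 mg/ml
        L = box_edge_length([(256, 14_300.0)], 150.0)
        assert L == pytest.approx((256 * 14_300.0 / (6.0221e23 * 150.0) * 1e27) ** (1 / 3), rel=1e-12)
        assert L == pytest.approx(343.5, abs=0.2)

    def test_single_solute_placed(self, rng):
        box = genbox([1], [sphere_species()], 150.0, rng=rng)
        assert len(box.solutes) == 1

    def test_no_overlaps_brute_force(self, rng):
        box = genbox([40], [sphere_species(radius=16.0)], 150.0, rng=rng)
        pos = np.array([s.state.position for s in box.solutes])
        L = box.boundary.box_lengths
        assert np.all(pos >= 0) and np.all(pos <= L)
        for i in range(len(pos)):
            d = minimum_image(pos[i + 1 :] - pos[i], L)
            assert np.all(np.linalg.norm(d, axis=1) >= 32.0)

    def test_impossible_packing_reports_progress(self, rng):
        with pytest.raises(RuntimeError, match="placed"):
            genbox([200], [sphere_species(radius=200.0)], 150.0, rng=rng, max_retries=50)


def ideal_box(rng, n=64, L=200.0, d_trans=0.01, d_rot=1e-3):
    from rigidbd import geometry
    from rigidbd.model import RigidBodyState, Solute

    conf = lambda: Conformation(atom_positions=np.zeros((1, 3)), d_trans=d_trans, d_rot=d_rot, stokes_radius=2.0)
    solutes = [
        Solute(conformations=[conf()], state=RigidBodyState(rng.random(3) * L, geometry.random_quaternion(rng)))
        for _ in range(n)
    ]
    return BoxConfiguration(solutes=solutes, boundary=BoundarySpec("box_periodic", np.array([L] * 3)),
                            concentration=0.0)


class TestDynamics:
    def test_free_diffusion_msd_recovery(self, rng):
        d_t = 0.01
        box = ideal_box(rng, n=64, d_trans=d_t)
        sim = ManyMoleculeSimulation(box, SimulationConfig(dt=1.0))
        traj = sim.run(3000, master_seed=9)
        est, se = translational_diffusion_msd(traj, fit_window=300)
        assert est == pytest.approx(d_t, rel=0.05)

    def test_static_trajectory_zero_diffusion(self):
        pos = np.tile(np.array([[10.0, 10.0, 10.0]]), (50, 4, 1))
        traj = Trajectory(
            times=np.arange(50.0), positions=pos, wrap_counts=np.zeros_like(pos, dtype=int),
            orientations=np.tile([1.0, 0, 0, 0], (50, 4, 1)), conformation_indices=np.zeros((50, 4), dtype=int),
            energies=np.full(50, np.nan), boundary=BoundarySpec("box_periodic", np.array([100.0] * 3)),
        )
        d, _ = translational_diffusion_msd(traj, fit_window=10)
        assert d == 0.0
        d_r, _ = rotational_diffusion(traj, fit_window=10)
        assert d_r == 0.0

    def test_msd_invariant_to_wrapping(self, rng):
        box = ideal_box(rng, n=32, L=20.0)  # small box: lots of wrapping
        sim = ManyMoleculeSimulation(box, SimulationConfig(dt=1.0))
        traj = sim.run(1000, master_seed=4)
        assert np.all(traj.positions >= 0) and np.all(traj.positions <= 20.0)
        assert traj.wrap_counts.any()  # wrapping actually happened
        est, _ = translational_diffusion_msd(traj, fit_window=100)
        assert est == pytest.approx(0.01, rel=0.1)

    def test_rotational_diffusion_recovery(self, rng):
        d_r = 2e-3
        box = ideal_box(rng, n=256, d_rot=d_r)
        sim = ManyMoleculeSimulation(box, SimulationConfig(dt=2.0))
        traj = sim.run(1500, master_seed=12)
        est, se = rotational_diffusion(traj, fit_window=100)
        assert est == pytest.approx(d_r, rel=0.05)

    def test_rotational_estimate_axis_independent(self, rng):
        # isotropic rotation: the tracked body axis must not matter
        box = ideal_box(rng, n=256, d_rot=5e-3)
        sim = ManyMoleculeSimulation(box, SimulationConfig(dt=2.0))
        traj = sim.run(1200, master_seed=13)
        d1, _ = rotational_diffusion(traj, fit_window=60, axis=(0, 0, 1.0))
        d2, _ = rotational_diffusion(traj, fit_window=60, axis=(1.0, 0, 0))
        assert d2 == pytest.approx(d1, rel=0.05)

    def test_worker_count_does_not_change_results(self, rng):
        finals = []
        for workers in (1, 4):
            r = np.random.default_rng(77)
            box = genbox([8], [sphere_species(radius=5.0, charge=2.0)], 20.0, rng=r)
            sim = ManyMoleculeSimulation(box, SimulationConfig(dt=0.5, ionic_strength=0.005, cutoff=60.0),
                                         enabled_terms=("dh_correction",))
            traj = sim.run(50, master_seed=5, n_workers=workers)
            finals.append(traj.positions[-1].copy())
        np.testing.assert_array_equal(finals[0], finals[1])

    def test_centroid_free_of_systematic_drift(self, rng):
        box = ideal_box(rng, n=64)
        sim = ManyMoleculeSimulation(box, SimulationConfig(dt=1.0))
        traj = sim.run(2000, master_seed=21)
        disp = traj.unwrapped()[-1] - traj.unwrapped()[0]
        centroid = disp.mean(axis=0)
        # centroid of n independent walkers diffuses with D/n
        sigma = np.sqrt(2 * 0.01 * traj.times[-1] / 64)
        assert np.all(np.abs(centroid) < 4 * sigma)

    def test_energy_log_matches_recomputation(self, rng):
        r = np.random.default_rng(3)
        box = genbox([6], [sphere_species(radius=5.0, charge=3.0)], 30.0, rng=r)
        cfg = SimulationConfig(dt=0.5, ionic_strength=0.005, cutoff=80.0)
        sim = ManyMoleculeSimulation(box, cfg, enabled_terms=("dh_correction",))
        traj = sim.run(20, master_seed=8, energy_interval=10)
        # recompute the final logged energy from the stored frame
        for s, p, q in zip(box.solutes, traj.positions[-1], traj.orientations[-1]):
            s.state.position = p.copy()
            s.state.orientation = q.copy()
        assert traj.energies[-1] == pytest.approx(sim.total_energy(), abs=1e-8)

    def test_mean_field_slows_diffusion_at_higher_concentration(self):
        estimates = []
        for conc in (20.0, 200.0):
            r = np.random.default_rng(10)
            box = genbox([27], [sphere_species(radius=16.0, d_trans=0.01)], conc, rng=r)
            sim = ManyMoleculeSimulation(box, SimulationConfig(dt=1.0), hydrodynamics=True)
            traj = sim.run(600, master_seed=6)
            est, _ = translational_diffusion_msd(traj, fit_window=60)
            estimates.append(est)
        assert estimates[1] < estimates[0]
        assert estimates[0] == pytest.approx(0.01, rel=0.15)


class TestRDF:
    def poisson_trajectory(self, rng, n=64, L=100.0, frames=150):
        pos = rng.random((frames, n, 3)) * L
        return Trajectory(
            times=np.arange(float(frames)), positions=pos,
            wrap_counts=np.zeros((frames, n, 3), dtype=int),
            orientations=np.tile([1.0, 0, 0, 0], (frames, n, 1)),
            conformation_indices=np.zeros((frames, n), dtype=int),
            energies=np.full(frames, np.nan),
            boundary=BoundarySpec("box_periodic", np.array([L] * 3)),
        )

    def test_ideal_gas_is_flat(self, rng):
        traj = self.poisson_trajectory(rng)
        table = rdf(traj, bin_width=2.0)
        sel = table.bin_centers > 4.0  # tiny-count bins near r=0 are noisy
        assert np.all(np.abs(table.g[sel] - 1.0) < 3 * table.g_se[sel] + 1e-12)

    def test_hard_spheres_vacate_contact_shell(self, rng):
        r = np.random.default_rng(2)
        box = genbox([32], [sphere_species(radius=8.0)], 80.0, rng=r)
        sim = ManyMoleculeSimulation(box, SimulationConfig(dt=1.0), excluded_volume=True)
        traj = sim.run(200, master_seed=14, save_interval=10)
        table = rdf(traj, bin_width=2.0)
        inside = table.bin_centers < 16.0 - table.bin_width
        assert np.all(table.g[inside] == 0.0)

    def test_neighbor_count_normalisation(self, rng):
        traj = self.poisson_trajectory(rng, n=64, L=100.0)
        table = rdf(traj, bin_width=1.0, r_max=40.0)
        rho = 64 / 100.0**3
        shell = 4 * np.pi * table.bin_centers**2 * rho * table.bin_width
        expected = np.sum(shell)  # mean neighbours within 40 A of a solute
        got = np.sum(table.g * shell)
        assert got == pytest.approx(expected, rel=0.05)

    def test_r_max_bounded_by_half_box(self, rng):
        traj = self.poisson_trajectory(rng, L=50.0)
        with pytest.raises(ValueError):
            rdf(traj, bin_width=1.0, r_max=30.0)
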