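import numpy as np
import pytest

from rigidbd import geometry
from rigidbd.constants import kt
from rigidbd.engine import (
    apply_boundary,
    attempt_move_with_exclusion,
    local_occupancy,
    rotation_step,
    scaled_diffusion,
    tokuyama_short_time,
    translation_step,
)
from rigidbd.grids import SetOfGrid, build_exclusion_softcore
from rigidbd.model import BoundarySpec, Conformation, RigidBodyState, SimulationConfig, Solute

from conftest import make_point_solute


class TestTranslationStep:
    def test_zero_force_zero_noise_is_identity(self, zero_rng, default_config):
        st = RigidBodyState(np.array([1.0, 2.0, 3.0]))
        step = translation_step(st, np.zeros(3), 0.01, default_config, zero_rng)
        np.testing.assert_array_equal(step.new_state.position, st.position)

    def test_random_displacement_variance(self, rng, default_config):
        # <|R|^2> = 6 D dt
        n = 20_000
        d_t, dt = 0.01, 1.0
        sq = np.empty(n)
        st = RigidBodyState(np.zeros(3))
        for i in range(n):
            sq[i] = np.sum(translation_step(st, np.zeros(3), d_t, default_config, rng).random_displacement ** 2)
        target = 6 * d_t * dt
        se = sq.std(ddof=1) / np.sqrt(n)
        assert abs(sq.mean() - target) < 3 * se

    def test_drift_under_constant_force(self, rng, default_config):
        n = 20_000
        d_t = 0.01
        force = np.array([1.0, 0.0, 0.0])
        st = RigidBodyState(np.zeros(3))
        dx = np.empty(n)
        for i in range(n):
            step = translation_step(st, force, d_t, default_config, rng)
            dx[i] = step.new_state.position[0]
        expected = default_config.dt * d_t / kt(default_config.temperature)
        assert expected == pytest.approx(0.01 / 0.59248, rel=1e-4)
        se = dx.std(ddof=1) / np.sqrt(n)
        assert abs(dx.mean() - expected) < 3 * se

    def test_nonfinite_force_rejected(self, rng, default_config):
        with pytest.raises(ValueError):
            translation_step(RigidBodyState(np.zeros(3)), np.array([np.nan, 0, 0]), 0.01, default_config, rng)


class TestRotationStep:
    def test_zero_torque_zero_noise_is_identity(self, zero_rng, default_config):
        st = RigidBodyState(np.zeros(3), geometry.quat_from_rotvec(np.array([0.3, 0.1, -0.2])))
        new = rotation_step(st, np.zeros(3), 1e-3, default_config, zero_rng)
        np.testing.assert_allclose(new.orientation, st.orientation, atol=1e-12)

    def test_orientation_autocorrelation_decay(self, rng):
        # body-fixed unit vector decorrelates as exp(-2 D_R t)
        d_r, dt, n_steps, n_rep = 1e-3, 5.0, 100, 2000
        cfg = SimulationConfig(dt=dt)
        q = geometry.quat_identity((n_rep,))
        u0 = np.array([0.0, 0.0, 1.0])
        corr = []
        times = []
        for s in range(1, n_steps + 1):
            w = rng.normal(0.0, np.sqrt(2 * d_r * dt), size=(n_rep, 3))
            q = geometry.quat_normalize(geometry.quat_multiply(geometry.quat_from_rotvec(w), q))
            if s % 10 == 0:
                u = geometry.quat_to_matrix(q) @ u0
                corr.append(u[:, 2].mean())
                times.append(s * dt)
        times, corr = np.array(times), np.array(corr)
        fit = -np.sum(times * np.log(corr)) / np.sum(times**2) / 2.0
        assert fit == pytest.approx(d_r, rel=0.05)

    def test_orthonormal_after_many_steps(self, rng):
        cfg = SimulationConfig(dt=1.0)
        st = RigidBodyState(np.zeros(3))
        for _ in range(20_000):
            st = rotation_step(st, np.zeros(3), 1e-2, cfg, rng)
        m = st.rotation_matrix()
        assert np.abs(m @ m.T - np.eye(3)).max() < 1e-6


class TestOccupancy:
    def test_no_neighbors_phi_zero(self):
        c = make_point_solute()
        res = local_occupancy(c, [], 20.0)
        assert res.phi == 0.0 and res.neighbor_count == 0

    def test_half_radius_neighbor(self):
        c = make_point_solute()
        nb = make_point_solute(stokes_radius=10.0, position=(5.0, 0, 0))
        res = local_occupancy(c, [nb], 20.0)
        assert res.phi == pytest.approx(0.125)

    def test_phi_nondecreasing_with_neighbors(self, rng):
        c = make_point_solute()
        neighbors = [make_point_solute(stokes_radius=2.0, position=rng.normal(size=3) * 5) for _ in range(10)]
        phis = [local_occupancy(c, neighbors[:k], 15.0).phi for k in range(11)]
        assert all(b >= a for a, b in zip(phis, phis[1:]))

    def test_self_not_counted(self):
        c = make_point_solute()
        assert local_occupancy(c, [c], 20.0).phi == 0.0


class TestScaledDiffusion:
    def test_zero_phi_identity(self):
        assert scaled_diffusion(0.013, 0.0) == 0.013

    def test_strictly_decreasing(self):
        s = [scaled_diffusion(1.0, p) for p in (0.0, 0.1, 0.3)]
        assert s[2] < s[1] < s[0] == 1.0
        assert s[2] > 0

    def test_matches_independent_formula_copy(self):
        # independently coded Tokuyama-Oppenheim short-time expression
        def oracle(phi):
            b = np.sqrt(9.0 * phi / 8.0)
            c = 11.0 * phi / 16.0
            h = (2 * b * b) / (1 - b) - c / (1 + 2 * c) - (b * c * (2 + c)) / ((1 + c) * (1 - b + c))
            return 1.0 / (1.0 + h)

        for phi in np.linspace(0.0, 0.5, 20):
            assert tokuyama_short_time(phi) == pytest.approx(oracle(phi), rel=1e-12)

    def test_clamps_unphysical_phi(self):
        assert scaled_diffusion(1.0, 1.2) == scaled_diffusion(1.0, 0.74)


class TestBoundary:
    def test_periodic_wrap(self):
        b = BoundarySpec(kind="box_periodic", dimensions=np.array([100.0, 100.0, 100.0]))
        st = RigidBodyState(np.array([103.0, 50.0, -1.0]))
        out = apply_boundary(st, b)
        np.testing.assert_allclose(out.position, [3.0, 50.0, 99.0])

    def test_reflective_sphere_mirror(self):
        b = BoundarySpec(kind="sphere", dimensions=np.array([50.0]))
        direction = np.array([1.0, 2.0, 2.0]) / 3.0
        st = RigidBodyState(52.0 * direction)
        out = apply_boundary(st, b)
        assert np.linalg.norm(out.position) == pytest.approx(48.0)
        np.testing.assert_allclose(out.position / 48.0, direction, atol=1e-12)

    def test_interior_point_unchanged(self):
        b = BoundarySpec(kind="box_reflective", dimensions=np.array([30.0, 30.0, 30.0]))
        st = RigidBodyState(np.array([10.0, 20.0, 5.0]))
        np.testing.assert_array_equal(apply_boundary(st, b).position, st.position)

    def test_reflective_box_mirror(self):
        b = BoundarySpec(kind="box_reflective", dimensions=np.array([30.0, 30.0, 30.0]))
        st = RigidBodyState(np.array([31.0, -2.0, 15.0]))
        out = apply_boundary(st, b)
        np.testing.assert_allclose(out.position, [29.0, 2.0, 15.0])


def exclusion_solute(radius=3.0, position=(0.0, 0.0, 0.0)):
    excl, _ = build_exclusion_softcore([((0.0, 0.0, 0.0), radius)], spacing=0.5, probe=0.0)
    conf = Conformation(
        atom_positions=np.zeros((1, 3)), stokes_radius=radius,
        grid_set=SetOfGrid(exclusion_mask=excl),
    )
    s = Solute(conformations=[conf])
    s.state = RigidBodyState(np.asarray(position, dtype=float))
    return s


class TestExclusionMoves:
    def test_no_partners_keeps_proposal(self):
        s = make_point_solute()
        proposed = RigidBodyState(np.array([1.0, 1.0, 1.0]))
        out = attempt_move_with_exclusion(s, proposed, [])
        np.testing.assert_array_equal(out.position, proposed.position)

    def test_full_overlap_rejected(self):
        s = make_point_solute(position=(10.0, 0.0, 0.0))
        partner = exclusion_solute(radius=5.0)
        proposed = RigidBodyState(np.zeros(3))
        out = attempt_move_with_exclusion(s, proposed, [partner], redraw=None)
        # move rejected: solute stays put instead of adopting the proposal
        np.testing.assert_array_equal(out.position, [10.0, 0.0, 0.0])

    def test_rejection_decision_matches_hard_sphere_oracle(self, rng):
        # uniform trial positions around a hard sphere of radius 3: the
        # exclusion-grid decision must agree with the direct overlap test
        # (away from the one-cell interpolation shoulder at the surface)
        partner = exclusion_solute(radius=3.0)
        s = make_point_solute(position=(8.0, 0, 0))
        n_checked = 0
        for _ in range(2000):
            p = rng.uniform(-5.0, 5.0, size=3)
            r = np.linalg.norm(p)
            if abs(r - 3.0) < 1.0:
                continue
            out = attempt_move_with_exclusion(s, RigidBodyState(p), [partner], redraw=None)
            rejected = not np.allclose(out.position, p)
            assert rejected == (r < 3.0)
            n_checked += 1
        assert n_checked > 500

    def test_redraw_until_clear(self, rng):
        partner = exclusion_solute(radius=3.0)
        s = make_point_solute(position=(8.0, 0, 0))
        draws = iter([np.zeros(3), np.array([0.0, 1.0, 0.0]), np.array([6.0, 0.0, 0.0])])
        out = attempt_move_with_exclusion(
            s, RigidBodyState(np.zeros(3)), [partner],
            redraw=lambda: RigidBodyState(next(draws)),
        )
        np.testing.assert_array_equal(out.position, [6.0, 0.0, 0.0])
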