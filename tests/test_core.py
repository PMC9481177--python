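"""Unit and property tests for the Lotka-Volterra core."""

import numpy as np
import pytest

import lvscape as lv
from lvscape.core import (
    AttractorConditionError,
    NonCooperativeError,
    get_solver,
    mask_of,
    support_of,
)

from conftest import random_cooperative_system


class TestValidation:
    def test_decoupled_system_is_valid(self):
        s = lv.LVSystem(alpha=[0.1, -0.2], gamma=np.zeros((2, 2)), g=0.27)
        assert lv.validate_system(s) is s

    def test_negative_interaction_rejected(self):
        gamma = np.zeros((3, 3))
        gamma[0, 1] = -0.1
        with pytest.raises(NonCooperativeError):
            lv.validate_system(lv.LVSystem(alpha=np.ones(3), gamma=gamma, g=0.27))

    def test_nonzero_diagonal_rejected(self):
        gamma = np.eye(2) * 0.5
        with pytest.raises(NonCooperativeError):
            lv.validate_system(lv.LVSystem(alpha=np.ones(2), gamma=gamma, g=0.27))

    def test_coupling_bound_rejected_for_all_ones_matrix(self):
        # spectral radius of the all-ones (zero diagonal) 7x7 matrix is 6,
        # confirmed by eigendecomposition, so 0.27 * 6 = 1.62 >= 1
        gamma = np.ones((7, 7)) - np.eye(7)
        assert np.isclose(np.max(np.abs(np.linalg.eigvals(gamma))), 6.0)
        with pytest.raises(AttractorConditionError):
            lv.validate_system(lv.LVSystem(alpha=np.ones(7), gamma=gamma, g=0.27))


class TestSimulation:
    def test_equilibrium_start_stays_constant(self):
        s = lv.LVSystem(alpha=[0.5], gamma=np.zeros((1, 1)), g=0.27)
        traj = lv.simulate_forward(s, [0.5], h=1e-2, steps=100)
        assert np.allclose(traj, 0.5)

    def test_logistic_convergence_to_carrying_capacity(self):
        s = lv.LVSystem(alpha=[1.0], gamma=np.zeros((1, 1)), g=0.0)
        traj = lv.simulate_forward(s, [0.01], h=1e-3, steps=10**5)
        assert abs(traj[-1, 0] - 1.0) < 1e-6

    def test_negative_alpha_drives_extinction(self):
        s = lv.LVSystem(alpha=[1.0, -1.0], gamma=np.zeros((2, 2)), g=0.0)
        traj = lv.simulate_forward(s, [0.5, 0.5], h=1e-2, steps=5000)
        assert np.allclose(traj[-1], [1.0, 0.0], atol=1e-6)

    def test_first_row_is_initial_state_and_rows_nonnegative(self):
        s = random_cooperative_system(7)
        u0 = np.full(s.n, 0.3)
        traj = lv.simulate_forward(s, u0, h=1e-3, steps=50)
        assert np.array_equal(traj[0], u0)
        assert np.all(traj >= 0)

    def test_oversized_step_raises(self):
        s = lv.LVSystem(alpha=[-5.0], gamma=np.zeros((1, 1)), g=0.0)
        with pytest.raises(ValueError, match="step size too large"):
            lv.simulate_forward(s, [2.0], h=1.0, steps=10)


class TestStationaryPoints:
    def test_decoupled_singleton_support(self):
        s = lv.LVSystem(alpha=[0.7, -0.2], gamma=np.zeros((2, 2)), g=0.0)
        p = lv.stationary_point_for_support(s, {0})
        assert np.allclose(p.u_star, [0.7, 0.0])
        assert p.level == 1
        assert lv.stationary_point_for_support(s, {1}) is None

    def test_coupled_pair_solved_by_hand(self):
        # (I - g*gamma)|_{1,2} = [[1, -0.5], [-0.5, 1]] against alpha (1,1)
        s = lv.LVSystem(alpha=[1.0, 1.0], gamma=[[0, 1], [1, 0]], g=0.5)
        p = lv.stationary_point_for_support(s, {0, 1})
        assert np.allclose(p.u_star, [2.0, 2.0])

    def test_enumeration_counts_decoupled(self, decoupled7):
        assert len(lv.enumerate_stationary_points(decoupled7, stability=False)) == 128

    def test_all_negative_alpha_leaves_only_origin(self):
        s = lv.LVSystem(alpha=-np.ones(4), gamma=np.zeros((4, 4)), g=0.27)
        pts = lv.enumerate_stationary_points(s, stability=False)
        assert len(pts) == 1 and pts[0].support == frozenset()

    @pytest.mark.parametrize("seed", range(10))
    def test_enumerated_points_are_ode_roots(self, seed):
        """Residual oracle: substituting u* into the RHS gives ~0."""
        s = random_cooperative_system(seed, n_lo=4, n_hi=4)
        pts = lv.enumerate_stationary_points(s, stability=False)
        for p in pts:
            assert np.abs(s.rhs(p.u_star)).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_count_formula_without_coupling(self, seed):
        rng = np.random.default_rng(seed)
        alpha = rng.normal(0, 0.5, size=6)
        s = lv.LVSystem(alpha=alpha, gamma=np.zeros((6, 6)), g=0.27)
        pts = lv.enumerate_stationary_points(s, stability=False)
        assert len(pts) == 2 ** int(np.sum(alpha > 0))

    def test_sorted_by_level_then_support(self, decoupled7):
        pts = lv.enumerate_stationary_points(decoupled7, stability=False)
        keys = [(p.level, tuple(sorted(p.support))) for p in pts]
        assert keys == sorted(keys)


class TestStability:
    def test_logistic_point_stable_origin_unstable(self):
        s = lv.LVSystem(alpha=[1.0], gamma=np.zeros((1, 1)), g=0.0)
        top = lv.stationary_point_for_support(s, {0})
        origin = lv.stationary_point_for_support(s, set())
        stable, eig = lv.classify_stability(s, top)
        assert stable and np.isclose(eig[0], -1.0)
        stable, eig = lv.classify_stability(s, origin)
        assert not stable and np.isclose(eig[0], 1.0)

    def test_coupled_pair_spectrum(self):
        # Jacobian at (2,2) is [[-2, 1], [1, -2]] with eigenvalues {-1, -3}
        s = lv.LVSystem(alpha=[1.0, 1.0], gamma=[[0, 1], [1, 0]], g=0.5)
        p = lv.stationary_point_for_support(s, {0, 1})
        stable, eig = lv.classify_stability(s, p)
        assert stable
        assert np.allclose(sorted(eig), [-3.0, -1.0])


class TestGass:
    def test_decoupled_gass_is_positive_part(self):
        alpha = np.array([0.4, -0.3, 0.9, -0.1])
        s = lv.LVSystem(alpha=alpha, gamma=np.zeros((4, 4)), g=0.27)
        gass = lv.find_gass(s)
        assert np.allclose(gass.u_star, np.maximum(alpha, 0.0))
        assert gass.is_gass and gass.stable

    @pytest.mark.parametrize("seed", range(30))
    def test_gass_support_is_union_of_supports(self, seed):
        s = random_cooperative_system(seed)
        pts = lv.enumerate_stationary_points(s, stability=False)
        union = frozenset().union(*(p.support for p in pts))
        assert lv.find_gass(s, pts).support == union

    @pytest.mark.parametrize("seed", range(20))
    def test_forward_simulation_converges_to_gass(self, seed):
        """Integration oracle: the GASS attracts random interior states."""
        s = random_cooperative_system(seed)
        gass = lv.find_gass(s)
        rng = np.random.default_rng(seed + 999)
        u = rng.uniform(0.05, 2.0, size=(10, s.n))
        for step in range(600_000):
            du = 0.05 * u * (s.alpha - u + s.g * (u @ s.gamma.T))
            u = u + du
            if step % 500 == 0 and np.abs(du).max() < 1e-12:
                break
        assert np.abs(u - gass.u_star[None, :]).max() < 1e-5

    @pytest.mark.parametrize("seed", range(20))
    def test_raising_alpha_never_shrinks_gass_support(self, seed):
        """Monotonicity of attractor membership in the growth parameters."""
        s = random_cooperative_system(seed)
        base = lv.find_gass(s).support
        rng = np.random.default_rng(seed)
        for _ in range(5):
            i = int(rng.integers(s.n))
            bumped = np.array(s.alpha)
            bumped[i] += float(rng.uniform(0.05, 1.0))
            s2 = lv.LVSystem(alpha=bumped, gamma=s.gamma, g=s.g)
            assert base <= lv.find_gass(s2).support


class TestInvasionRate:
    def test_decoupled_rate_is_alpha(self):
        s = lv.LVSystem(alpha=[0.5, -0.3], gamma=np.zeros((2, 2)), g=0.0)
        p = lv.stationary_point_for_support(s, {0})
        assert np.isclose(lv.invasion_rate(s, p, 1), -0.3)

    def test_coupled_rate_by_hand(self):
        # rate of network 2 at (1, 0): -0.4 + 0.5 * 1 * 1 = 0.1
        s = lv.LVSystem(alpha=[1.0, -0.4], gamma=[[0, 0], [1, 0]], g=0.5)
        p = lv.stationary_point_for_support(s, {0})
        assert np.isclose(lv.invasion_rate(s, p, 1), 0.1)

    def test_present_component_rejected(self):
        s = lv.LVSystem(alpha=[0.5], gamma=np.zeros((1, 1)), g=0.0)
        p = lv.stationary_point_for_support(s, {0})
        with pytest.raises(ValueError):
            lv.invasion_rate(s, p, 0)

    @pytest.mark.parametrize("seed", range(15))
    def test_rate_sign_predicts_extended_support_feasibility(self, seed):
        """Positive invasion rate at the GASS <=> the extended support is feasible."""
        s = random_cooperative_system(seed)
        gass = lv.find_gass(s)
        for k in range(s.n):
            if k in gass.support:
                continue
            rate = lv.invasion_rate(s, gass, k)
            extended = lv.stationary_point_for_support(s, gass.support | {k})
            if rate > 1e-9:
                assert extended is not None
            elif rate < -1e-9:
                assert extended is None


def test_mask_support_roundtrip():
    sup = frozenset({0, 3, 5})
    assert support_of(mask_of(sup)) == sup


def test_solver_matches_direct_solve(sc7):
    solver = get_solver(lv.LVSystem(alpha=np.zeros(7), gamma=sc7, g=0.27))
    rng = np.random.default_rng(0)
    alpha = rng.normal(0.2, 0.4, size=7)
    a_full = np.eye(7) - 0.27 * sc7
    for mask in (0b1, 0b1010101, 0b1111111):
        idx = solver.indices(mask)
        expected = np.linalg.solve(a_full[np.ix_(idx, idx)], alpha[idx])
        assert np.allclose(solver.inverse(mask) @ alpha[idx], expected)
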