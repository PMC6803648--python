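import numpy as np
import pytest
import scipy.sparse as sp

from hepatam import (ConfigurationError, SimulationConfig, solve_cytokine,
                     solve_oxygen, solve_pressure_velocity, step_mde,
                     velocity_divergence)
from hepatam.config import CytokineSpec, MDEParams, MechanicsParams
from hepatam.grid import neumann_laplacian
from hepatam.rd import face_velocity
from hepatam.state import HYPOXIC, PROLIFERATING, RegionMap
from hepatam.vasculature import VesselNetwork, extravasation_conductance, vessel_indicator


def region_of(labels):
    return RegionMap(np.asarray(labels, dtype=np.int8))


def network_with(pre, n):
    net = VesselNetwork(n=n, pre_mask=np.zeros((n, n), dtype=bool),
                        neo_mask=np.zeros((n, n), dtype=bool))
    net.pre_mask[pre] = True
    return net


def small_cfg(n=16):
    cfg = SimulationConfig(grid_nodes_per_side=max(n, 16), node_spacing=2.0 / n)
    return cfg


class TestSolveOxygen:
    def test_no_vessels_gives_zero_field(self):
        n = 16
        cfg = small_cfg(n)
        net = network_with((slice(0, 0), slice(0, 0)), n)
        region = region_of(np.zeros((n, n)))
        sigma = solve_oxygen(region, net, np.zeros((n, n)), cfg)
        np.testing.assert_allclose(sigma, 0.0, atol=1e-12)

    def test_uniform_vessels_reach_zero_dimensional_fixed_point(self):
        # vessels everywhere with source s(1-sigma), uniform uptake lam:
        # sigma* = s/(s+lam) uniformly
        n = 16
        cfg = small_cfg(n)
        cfg.vessels.lambda_pre_sigma = 10.0
        cfg.vessels.hematocrit_h = 0.5
        cfg.oxygen.lambda_tissue_sigma = 3.0
        net = network_with((slice(None), slice(None)), n)
        region = region_of(np.zeros((n, n)))
        sigma = solve_oxygen(region, net, np.zeros((n, n)), cfg)
        s = 10.0 * 0.5
        np.testing.assert_allclose(sigma, s / (s + 3.0), rtol=1e-10)

    def test_single_line_matches_1d_analytic_profile(self):
        # a single vessel line in a large uniform-uptake domain decays as
        # exp(-x sqrt(lam/D)) away from the line
        n = 81
        cfg = SimulationConfig(grid_nodes_per_side=n, node_spacing=0.02)
        cfg.oxygen.D_sigma = 1.0
        cfg.oxygen.lambda_tissue_sigma = 25.0
        cfg.vessels.lambda_pre_sigma = 500.0
        net = network_with((slice(None), 40), n)
        region = region_of(np.zeros((n, n)))
        sigma = solve_oxygen(region, net, np.zeros((n, n)), cfg)
        profile = sigma[40, :]
        ell = np.sqrt(1.0 / 25.0)
        x = np.arange(n) * 0.02
        ref = profile[41] * np.exp(-(x[41:61] - x[41]) / ell)
        np.testing.assert_allclose(profile[41:61], ref, rtol=0.02)

    def test_agrees_with_dense_oracle_to_1e8(self):
        n = 16
        cfg = small_cfg(n)
        rng = np.random.default_rng(0)
        net = network_with((slice(None, None, 5), slice(None)), n)
        labels = (rng.random((n, n)) < 0.3).astype(np.int8) * PROLIFERATING
        region = region_of(labels)
        sigma = solve_oxygen(region, net, np.zeros((n, n)), cfg)
        # independent dense assembly and numpy solve
        from hepatam.rd import oxygen_uptake_field
        lap = neumann_laplacian(n, cfg.node_spacing).toarray()
        s = extravasation_conductance(net, np.zeros((n, n)), cfg).ravel()
        lam = oxygen_uptake_field(region, cfg).ravel()
        A = -cfg.oxygen.D_sigma * lap + np.diag(lam + s)
        ref = np.linalg.solve(A, s).reshape(n, n)
        np.testing.assert_allclose(sigma, ref, rtol=1e-8)


class TestSolveCytokine:
    def spec(self, **kw):
        base = dict(name="TNF", D_C=0.3, lambda_production_C=5.0,
                    lambda_circulation_C=1.0, lambda_decay_C=4.0,
                    production_region="viable_tumor")
        base.update(kw)
        return CytokineSpec(**base)

    def test_empty_production_region_gives_zero(self):
        n = 16
        net = network_with((slice(None, None, 5), slice(None)), n)
        c = solve_cytokine(self.spec(), region_of(np.zeros((n, n))), net, 0.1)
        np.testing.assert_allclose(c, 0.0, atol=1e-12)

    def test_zero_dimensional_fixed_point(self):
        # production everywhere, no vessels: C* = prod/(prod+decay)
        n = 16
        net = network_with((slice(0, 0), slice(0, 0)), n)
        region = region_of(np.full((n, n), PROLIFERATING))
        c = solve_cytokine(self.spec(), region, net, 0.1)
        np.testing.assert_allclose(c, 5.0 / 9.0, rtol=1e-10)

    def test_tenfold_production_raises_peak(self):
        n = 21
        net = network_with((slice(None, None, 5), slice(None)), n)
        labels = np.zeros((n, n), dtype=np.int8)
        labels[8:13, 8:13] = PROLIFERATING
        region = region_of(labels)
        lo = solve_cytokine(self.spec(), region, net, 0.1)
        hi = solve_cytokine(self.spec(lambda_production_C=50.0), region, net, 0.1)
        assert hi.max() > lo.max()
        assert (hi >= lo - 1e-12).all()  # production monotonicity, node-wise

    def test_agrees_with_dense_oracle_to_1e8(self):
        n = 16
        net = network_with((slice(None, None, 4), slice(None)), n)
        labels = np.zeros((n, n), dtype=np.int8)
        labels[5:11, 5:11] = HYPOXIC
        region = region_of(labels)
        spec = self.spec(production_region="hypoxic_tumor")
        h = 0.05
        c = solve_cytokine(spec, region, net, h)
        lap = neumann_laplacian(n, h).toarray()
        ind = region.hypoxic_mask.astype(float).ravel()
        ves = vessel_indicator(net, (n, n)).ravel()
        A = (-spec.D_C * lap
             + np.diag(spec.lambda_production_C * ind
                       + spec.lambda_circulation_C * ves + spec.lambda_decay_C))
        ref = np.linalg.solve(A, spec.lambda_production_C * ind).reshape(n, n)
        np.testing.assert_allclose(c, ref, rtol=1e-8)

    def test_bounds_hold_for_random_nonnegative_rates(self):
        rng = np.random.default_rng(42)
        n = 16
        for _ in range(20):
            spec = self.spec(D_C=rng.uniform(0.01, 1.0),
                             lambda_production_C=rng.uniform(0, 50),
                             lambda_circulation_C=rng.uniform(0, 50),
                             lambda_decay_C=rng.uniform(0.1, 50))
            labels = (rng.random((n, n)) < 0.4).astype(np.int8) * PROLIFERATING
            net = network_with((slice(None, None, rng.integers(3, 8)), slice(None)), n)
            c = solve_cytokine(spec, region_of(labels), net, 0.05)
            assert c.min() >= 0.0 and c.max() <= 1.0


class TestPressureVelocity:
    def test_zero_source_uniform_ecm_gives_constant_pressure(self):
        n = 21
        mech = MechanicsParams(mu=1.0, chi_E=0.02)
        P, vy, vx = solve_pressure_velocity(np.zeros((n, n)),
                                            np.full((n, n), 0.5), mech, 0.1)
        np.testing.assert_allclose(P, 0.0, atol=1e-10)
        np.testing.assert_allclose(vy, 0.0, atol=1e-9)
        np.testing.assert_allclose(vx, 0.0, atol=1e-9)

    def test_point_source_drives_outward_flow(self):
        n = 21
        mech = MechanicsParams(mu=1.0, chi_E=0.0)
        lam = np.zeros((n, n))
        lam[10, 10] = 1.0
        P, vy, vx = solve_pressure_velocity(lam, np.zeros((n, n)), mech, 0.1)
        for r, c in [(8, 10), (12, 10), (10, 8), (10, 12)]:
            radial = np.array([r - 10, c - 10], dtype=float)
            v = np.array([vy[r, c], vx[r, c]])
            assert v @ radial > 0

    def test_haptotaxis_ramp_in_closed_domain(self):
        # lambda_p = 0 with a linear ECM ramp: the haptotactic component
        # equals chi_E * grad E (within 1% in the interior), while in a
        # closed zero-flux domain the pressure relaxes to mu P = chi_E E
        # + const, so the net conservative flux vanishes identically
        n = 31
        h = 0.1
        mech = MechanicsParams(mu=100.0, chi_E=0.5)
        E = np.tile(np.linspace(0.0, 1.0, n), (n, 1))
        P, vy, vx = solve_pressure_velocity(np.zeros((n, n)), E, mech, h)
        grad = (E[0, 1] - E[0, 0]) / h
        ey, ex = np.gradient(E, h)
        np.testing.assert_allclose(mech.chi_E * ex[5:-5, 5:-5],
                                   mech.chi_E * grad, rtol=0.01)
        scaled = mech.mu * P - mech.chi_E * E
        np.testing.assert_allclose(scaled - scaled.mean(), 0.0, atol=1e-8)
        fy, fx = face_velocity(P, E, mech, h)
        np.testing.assert_allclose(fx, 0.0, atol=1e-9)
        np.testing.assert_allclose(fy, 0.0, atol=1e-9)

    def test_discrete_divergence_identity(self):
        n = 25
        rng = np.random.default_rng(5)
        mech = MechanicsParams(mu=1.3, chi_E=0.07)
        lam = rng.normal(size=(n, n))
        E = rng.random((n, n))
        h = 0.07
        P, *_ = solve_pressure_velocity(lam, E, mech, h)
        div = velocity_divergence(P, E, mech, h)
        np.testing.assert_allclose(div, lam - lam.mean(), atol=1e-8)

    def test_face_velocity_points_outward_from_source(self):
        n = 31
        mech = MechanicsParams(mu=1.0, chi_E=0.0)
        lam = np.zeros((n, n))
        lam[13:18, 13:18] = 1.0
        P, *_ = solve_pressure_velocity(lam, np.zeros((n, n)), mech, 0.1)
        fy, fx = face_velocity(P, np.zeros((n, n)), mech, 0.1)
        assert fx[15, 18] > 0 and fx[15, 11] < 0
        assert fy[18, 15] > 0 and fy[11, 15] < 0


class TestStepMDE:
    def setup_method(self):
        self.params = MDEParams(D_M=0.0, lambda_production_M=1.0,
                                lambda_sprout_production_M=0.0,
                                lambda_degradation_M=0.0, lambda_decay_M=0.0)
        self.n = 11
        self.tips = np.zeros((self.n, self.n), dtype=bool)

    def test_no_sources_stays_zero(self):
        region = region_of(np.zeros((self.n, self.n)))
        M = step_mde(np.zeros((self.n, self.n)), region, self.tips,
                     np.zeros((self.n, self.n)), self.params, 0.05, 0.1)
        assert not M.any()

    def test_hand_euler_step(self):
        # single viable node, D=0, prod=1, dt=0.1 -> M = 0.1
        labels = np.zeros((self.n, self.n), dtype=np.int8)
        labels[5, 5] = PROLIFERATING
        M = step_mde(np.zeros((self.n, self.n)), region_of(labels), self.tips,
                     np.zeros((self.n, self.n)), self.params, 0.05, 0.1)
        assert M[5, 5] == pytest.approx(0.1)
        assert M.sum() == pytest.approx(0.1)

    def test_saturation_blocks_production(self):
        labels = np.full((self.n, self.n), PROLIFERATING, dtype=np.int8)
        M = step_mde(np.ones((self.n, self.n)), region_of(labels), self.tips,
                     np.zeros((self.n, self.n)), self.params, 0.05, 0.1)
        np.testing.assert_allclose(M, 1.0)

    def test_cfl_violation_raises(self):
        params = MDEParams(D_M=1.0)
        region = region_of(np.zeros((self.n, self.n)))
        with pytest.raises(ConfigurationError, match="CFL"):
            step_mde(np.zeros((self.n, self.n)), region, self.tips,
                     np.zeros((self.n, self.n)), params, h=0.05, dt=0.1)

    def test_field_stays_in_unit_interval_under_cfl(self):
        rng = np.random.default_rng(1)
        params = MDEParams(D_M=0.004, lambda_production_M=2.0,
                           lambda_sprout_production_M=1.0,
                           lambda_degradation_M=1.0, lambda_decay_M=2.0)
        labels = (rng.random((self.n, self.n)) < 0.5).astype(np.int8)
        M = rng.random((self.n, self.n))
        E = rng.random((self.n, self.n)) * 2
        h = 0.2
        for _ in range(50):
            M = step_mde(M, region_of(labels), self.tips, E, params, h, 0.5)
            assert M.min() >= 0.0 and M.max() <= 1.0
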