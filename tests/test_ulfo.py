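"""QSS reduction and the ULFO diagnostics."""

import numpy as np
import pytest
from scipy.optimize import bisect

from enzscale import fixtures, ulfo
from enzscale.enzyme_model import (
    CircuitParams,
    Circuit,
    InputProgram,
    build_system,
    simulate,
    steady_state,
)
from enzscale.topology import Topology
from enzscale.ulfo import (
    ReducedSystem,
    UlfoReport,
    UlfoThresholds,
    fd_jacobians,
    homogeneity_deviation,
    jacobians,
    qss_output,
    selfloop_contribution,
    steady_state_map,
    timescale_ratio,
    ulfo_verdict,
    uniformity,
)


IFFL = Topology.from_dict({("A", "B"): +1, ("A", "C"): +1, ("B", "C"): -1})


def _iffl_circuit(kAC=2.0, KAC=0.3, kBC=3.0, KBC=0.8):
    params = CircuitParams({
        "I->A": (0.7, 1.3), "A->B": (1.1, 0.4), "A->C": (kAC, KAC),
        "B->C": (kBC, KBC), "F_A": (0.5, 2.0), "F_B": (0.9, 0.05),
    })
    return Circuit(IFFL, params)


class TestQssOutput:
    def test_zero_production_gives_zero(self):
        theta = qss_output(_iffl_circuit())
        assert theta(np.array([0.0, 0.5])) == 0.0

    def test_symmetric_balance_gives_one_half(self):
        # same k and K on activation and deactivation, equal activities
        c = _iffl_circuit(kAC=2.0, KAC=0.3, kBC=2.0, KBC=0.3)
        theta = qss_output(c)
        for ab in (0.2, 0.5, 0.9):
            assert theta(np.array([ab, ab])) == pytest.approx(0.5, abs=1e-12)

    def test_quadratic_root_matches_bisection_oracle(self):
        c = _iffl_circuit()
        system = build_system(c)
        theta = qss_output(c)
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b = rng.uniform(0.01, 0.99, 2)

            def balance(cval):
                return system.rhs(np.array([a, b, cval]), 0.0)[2]

            root = bisect(balance, 0.0, 1.0, xtol=1e-12)
            assert theta(np.array([a, b])) == pytest.approx(root, abs=1e-10)

    def test_multi_term_output_node_uses_bracketed_root(self):
        # C with a self-loop: three terms in the balance, still a unique root
        topo = Topology.from_dict({("A", "B"): +1, ("A", "C"): +1,
                                   ("B", "C"): -1, ("C", "C"): +1})
        params = CircuitParams({
            "I->A": (0.7, 1.3), "A->B": (1.1, 0.4), "A->C": (2.0, 0.3),
            "B->C": (3.0, 0.8), "C->C": (0.5, 1.0),
            "F_A": (0.5, 2.0), "F_B": (0.9, 0.05),
        })
        system = build_system(Circuit(topo, params))
        theta = qss_output(system)
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.uniform(0.05, 0.95, 2)
            root = theta(np.array([a, b]))
            resid = system.rhs(np.array([a, b, root]), 0.0)[2]
            assert abs(resid) < 1e-10


class TestReduce:
    def test_substitution_oracle(self):
        """Reduced vector field equals the full rhs with c at its QSS."""
        c = _iffl_circuit()
        system = build_system(c)
        rs = ReducedSystem(system)
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b = rng.uniform(0.02, 0.98, 2)
            u = rng.uniform(0.1, 1.5)
            xs = np.array([a, b])
            full = system.rhs(np.array([a, b, rs.theta(xs)]), u)
            np.testing.assert_allclose(rs.rhs(xs, u), full[:2], rtol=1e-12)

    def test_reduction_vacuous_when_c_regulates_nothing(self):
        # C feeds back on nothing: reduced (a,b) dynamics = full (a,b) dynamics
        c = _iffl_circuit()
        system = build_system(c)
        rs = ReducedSystem(system)
        rng = np.random.default_rng(6)
        for _ in range(20):
            xs = rng.uniform(0.05, 0.95, 2)
            u = rng.uniform(0.1, 1.0)
            full = system.rhs(np.array([xs[0], xs[1], 0.37]), u)[:2]
            np.testing.assert_allclose(rs.rhs(xs, u), full, rtol=1e-12)

    def test_qss_convergence_as_output_speeds_up(self):
        """The full output trajectory converges to the reduced one as the
        output node's rates are scaled by 1/eps."""
        cfg_u0, t_final = 0.1, 800.0
        t_grid = np.linspace(0, t_final, 300)
        errs = []
        for eps in (1.0, 0.1, 0.01):
            c = fixtures.make_ulfo_family(eps=eps)
            system = build_system(c)
            rs = ReducedSystem(system)
            ss = steady_state(system, cfg_u0)
            prog = InputProgram.make_step(cfg_u0, 1.2 * cfg_u0, 0.0)
            traj = simulate(system, prog, ss.x, (0, t_final), t_grid=t_grid)
            rtraj = simulate(rs, prog, ss.x[:2], (0, t_final), t_grid=t_grid)
            y_red = np.array([rs.theta(xs, u)
                              for xs, u in zip(rtraj.x, rtraj.u)])
            errs.append(np.max(np.abs(traj.y - y_red)))
        assert errs[0] > errs[1] > errs[2]


class TestSelfloop:
    def test_zero_without_selfloop_or_constitutive(self):
        c = _iffl_circuit()
        system = build_system(c)
        ss = steady_state(system, 0.5)
        prog = InputProgram.make_step(0.5, 0.6, 0.0)
        traj = simulate(system, prog, ss.x, (0.0, 50.0))
        assert selfloop_contribution(system, traj) == 0.0

    def test_termwise_hand_evaluation(self):
        topo = Topology.from_dict({("A", "C"): +1, ("C", "C"): -1})
        params = CircuitParams({
            "I->A": (0.7, 1.3), "A->C": (2.0, 0.3), "C->C": (0.4, 0.9),
            "E_B": (1.0, 1.0), "F_A": (0.5, 2.0), "F_B": (0.8, 0.6),
        })
        system = build_system(Circuit(topo, params))
        rng = np.random.default_rng(8)
        for _ in range(10):
            a, b, c = rng.uniform(0.05, 0.95, 3)
            u = rng.uniform(0.1, 1.0)
            fluxes = dict(zip(system.names, system.term_fluxes([a, b, c], u)))
            # hand-evaluated Michaelis-Menten terms
            f_AC = a * 2.0 * (1 - c) / ((1 - c) + 0.3)
            f_CC = -c * 0.4 * c / (c + 0.9)       # self-loop deactivation
            f_EB = 1.0 * (1 - b) / ((1 - b) + 1.0)  # constitutive, activity 1
            f_IA = u * 0.7 * (1 - a) / ((1 - a) + 1.3)
            assert fluxes["A->C"] == pytest.approx(f_AC, rel=1e-12)
            assert fluxes["C->C"] == pytest.approx(f_CC, rel=1e-12)
            assert fluxes["E_B"] == pytest.approx(f_EB, rel=1e-12)
            assert fluxes["I->A"] == pytest.approx(f_IA, rel=1e-12)

    def test_ulfo_fixture_below_one_percent(self):
        c = fixtures.make_ulfo_family(eps=0.01)
        system = build_system(c)
        ss = steady_state(system, 0.1)
        prog = InputProgram.make_step(0.1, 0.12, 0.0)
        traj = simulate(system, prog, ss.x, (0.0, 2000.0))
        assert selfloop_contribution(system, traj) < 0.01


class TestSteadyStateMap:
    def test_linear_memory_proportionality_is_exact(self):
        rs = ReducedSystem(fixtures.make_exact_fcd(1e-3))
        u_grid = np.geomspace(0.2, 1.6, 6)
        states, conv, prop_dev = steady_state_map(rs, u_grid)
        assert conv.all()
        np.testing.assert_allclose(states[:, 0] / u_grid, 1.0, atol=1e-8)
        assert prop_dev < 1e-7

    def test_eq3_fixture_proportional_but_not_ulfo(self):
        system = fixtures.make_non_si_adaptive()
        rs = ReducedSystem(system)
        _, conv, prop_dev = steady_state_map(rs, np.geomspace(0.5, 2.0, 6))
        assert conv.all() and prop_dev < 1e-7
        report = ulfo.ulfo_report(system, u0=0.5)
        assert not report.verdict and not report.conditions["timescale"]


class TestJacobians:
    def test_analytic_matches_finite_differences(self):
        for seed in (0, 1, 2, 13):
            system = build_system(fixtures.random_circuit(seed))
            rs = ReducedSystem(system)
            res = steady_state(rs, 0.5)
            if not res.converged:
                continue
            A, B = jacobians(rs, 0.5, res.x)
            A_fd, B_fd = fd_jacobians(rs, 0.5, res.x)
            scale = max(np.abs(A).max(), 1e-12)
            assert np.abs(A - A_fd).max() / scale < 1e-6
            assert np.abs(B - B_fd).max() / max(np.abs(B).max(), 1e-12) < 1e-6

    def test_linear_fixture_jacobian_constant_in_u(self):
        rs = ReducedSystem(fixtures.make_exact_fcd(1e-3))
        A1, B1 = jacobians(rs, 0.3)
        A2, B2 = jacobians(rs, 1.2)
        np.testing.assert_allclose(A1, A2, atol=1e-12)
        np.testing.assert_allclose(A1, [[-1.0]], atol=1e-12)
        dA, dB = uniformity(rs, np.geomspace(0.3, 1.2, 5))
        assert dA == pytest.approx(0.0, abs=1e-12)
        assert dB == pytest.approx(0.0, abs=1e-12)

    def test_uniformity_stable_under_grid_refinement(self):
        c = fixtures.make_ulfo_family(eps=0.01, input_scale=30)
        rs = ReducedSystem(build_system(c))
        dA8, _ = uniformity(rs, np.geomspace(0.1, 0.4, 8))
        dA16, _ = uniformity(rs, np.geomspace(0.1, 0.4, 16))
        # mean consecutive-pair differences roughly halve with a doubled grid;
        # the accumulated (summed) variation is grid-stable
        assert 7 * dA8 == pytest.approx(15 * dA16, rel=0.10)


class TestTimescaleAndVerdict:
    def test_explicit_eps_sets_the_ratio(self):
        for eps in (0.01, 0.1):
            c = fixtures.make_ulfo_family(eps=eps)
            system = build_system(c)
            ss = steady_state(system, 0.1)
            r = timescale_ratio(system, ss.x, 0.1)
            r1 = timescale_ratio(build_system(fixtures.make_ulfo_family(eps=1.0)),
                                 steady_state(build_system(
                                     fixtures.make_ulfo_family(eps=1.0)), 0.1).x, 0.1)
            assert r == pytest.approx(r1 / eps, rel=0.2)

    def test_speeding_output_tenfold_scales_ratio(self):
        c1 = fixtures.make_ulfo_family(eps=0.1)
        c2 = fixtures.make_ulfo_family(eps=0.01)
        s1, s2 = build_system(c1), build_system(c2)
        r1 = timescale_ratio(s1, steady_state(s1, 0.1).x, 0.1)
        r2 = timescale_ratio(s2, steady_state(s2, 0.1).x, 0.1)
        assert r2 / r1 == pytest.approx(10.0, rel=0.05)

    def test_eq3_fixture_unit_ratio(self):
        system = fixtures.make_non_si_adaptive()
        ss = steady_state(system, 0.5)
        # d(dc/dt)/dc = -b = -u0; memory eigenvalues are -1
        assert timescale_ratio(system, ss.x, 0.5) == pytest.approx(0.5, abs=1e-9)

    def test_verdict_is_a_conjunction(self):
        report = UlfoReport(timescale=100.0, selfloop_frac=0.0,
                            homogeneity_dev=0.0, prop_dev=0.0,
                            dA=0.0, dB=0.0, u_grid=[0.1, 0.4])
        assert ulfo_verdict(report).verdict
        report.prop_dev = 0.2  # one failed condition flips the verdict
        assert not ulfo_verdict(report).verdict
        assert report.conditions["proportionality"] is False

    def test_homogeneity_exact_for_pure_pushpull_output(self):
        rs = ReducedSystem(build_system(_iffl_circuit()))
        pts = np.array([[0.01, 0.02], [0.1, 0.05], [0.2, 0.4]])
        assert homogeneity_deviation(rs, pts, p=2.0) < 1e-12
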