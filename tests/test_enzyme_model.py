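"""Michaelis-Menten model assembly, integration, steady states."""

import numpy as np
import pytest
import sympy as sp

from enzscale import fixtures
from enzscale.enzyme_model import (
    Circuit,
    CircuitParams,
    InputProgram,
    MIDPOINT_STATE,
    _odeint_segment,
    build_rhs,
    build_system,
    implied_interactions,
    simulate,
    steady_state,
)
from enzscale.topology import Topology


IFFL = Topology.from_dict({("A", "B"): +1, ("A", "C"): +1, ("B", "C"): -1})

IFFL_PARAMS = CircuitParams({
    "I->A": (0.7, 1.3), "A->B": (1.1, 0.4), "A->C": (2.0, 0.09),
    "B->C": (3.0, 0.8), "F_A": (0.5, 2.0), "F_B": (0.9, 0.05),
})


def _mm_act(s, k, K, x):
    return s * k * (1 - x) / ((1 - x) + K)


def _mm_deact(s, k, K, x):
    return s * k * x / (x + K)


def test_rhs_matches_symbolic_expansion():
    """The assembled vector field of the worked incoherent-feedforward
    topology equals an independently hand-expanded symbolic model."""
    a, b, c, u = sp.symbols("a b c u", positive=True)
    P = {n: kv for n, kv in IFFL_PARAMS.values.items()}
    # A: input activation, constitutive deactivation
    fa = (u * P["I->A"][0] * (1 - a) / ((1 - a) + P["I->A"][1])
          - P["F_A"][0] * a / (a + P["F_A"][1]))
    # B: activated by A, constitutively deactivated
    fb = (a * P["A->B"][0] * (1 - b) / ((1 - b) + P["A->B"][1])
          - P["F_B"][0] * b / (b + P["F_B"][1]))
    # C: activated by A, deactivated by B; no constitutive terms
    fc = (a * P["A->C"][0] * (1 - c) / ((1 - c) + P["A->C"][1])
          - b * P["B->C"][0] * c / (c + P["B->C"][1]))
    subs = {a: sp.Rational(1, 2), b: sp.Rational(1, 2),
            c: sp.Rational(1, 2), u: sp.Rational(1, 2)}
    expected = [float(f.subs(subs)) for f in (fa, fb, fc)]

    rhs = build_rhs(Circuit(IFFL, IFFL_PARAMS))
    got = rhs(np.array([0.5, 0.5, 0.5]), 0.5)
    np.testing.assert_allclose(got, expected, rtol=1e-14)


def test_constitutive_insertion_rules():
    # B with no activator gets exactly one constitutive activation term
    topo = Topology.from_dict({("A", "C"): +1, ("B", "C"): -1})
    names = [i.name for i in implied_interactions(topo)]
    assert names.count("E_B") == 1
    assert "E_A" not in names            # input replaces it on A
    assert "F_C" not in names            # C has an enzymatic deactivator
    assert "E_C" not in names            # C has an enzymatic activator
    assert {"F_A", "F_B"} <= set(names)  # A, B lack deactivators

    # a node with both an activator and a deactivator gets no constitutive term
    topo2 = Topology.from_dict({("A", "B"): +1, ("C", "B"): -1, ("A", "C"): +1})
    names2 = [i.name for i in implied_interactions(topo2)]
    assert "E_B" not in names2 and "F_B" not in names2


def test_params_topology_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        Circuit(Topology.from_dict({("A", "C"): +1}), IFFL_PARAMS)


@pytest.mark.parametrize("seed", range(5))
def test_boundary_fluxes_vanish(seed):
    """Activation flux into a node vanishes at full activity and the
    deactivation flux at zero activity, so the unit cube is invariant."""
    c = fixtures.random_circuit(seed)
    system = build_system(c)
    u = 0.7
    for i in range(3):
        x = np.array([0.3, 0.6, 0.4])
        x[i] = 1.0
        assert system.rhs(x, u)[i] <= 0.0
        x[i] = 0.0
        assert system.rhs(x, u)[i] >= 0.0


def test_fixed_point_trajectory_is_constant():
    c = fixtures.make_ulfo_family()
    system = build_system(c)
    ss = steady_state(system, 0.1)
    assert ss.converged
    traj = simulate(system, InputProgram.constant(0.1), ss.x, (0.0, 200.0))
    assert np.max(np.abs(traj.x - ss.x)) < 10 * 1e-7


def test_unit_cube_forward_invariance():
    """Random circuits under random steps stay inside [0,1]^3 up to the
    excursion tolerance (simulate raises otherwise)."""
    rng = np.random.default_rng(42)
    for seed in range(60):
        c = fixtures.random_circuit(seed)
        system = build_system(c)
        x0 = rng.uniform(0, 1, 3)
        u0, u1 = rng.uniform(0.05, 2.0, 2)
        prog = InputProgram.make_step(u0, u1, 1.0)
        traj = simulate(system, prog, x0, (0.0, 50.0), n_points=80)
        assert traj.x.min() >= 0.0 and traj.x.max() <= 1.0


def test_output_converges_in_tolerance():
    c = fixtures.make_ulfo_family()
    system = build_system(c)
    ss = steady_state(system, 0.1)
    prog = InputProgram.make_step(0.1, 0.12, 0.0)
    y = [simulate(system, prog, ss.x, (0.0, 500.0), tol=tol, n_points=200).y
         for tol in (1e-8, 5e-9)]
    assert np.max(np.abs(y[0] - y[1])) < 1e-6


def test_steady_state_linear_memory_fixture():
    # da/dt = u - a  =>  steady state a = u exactly
    system = fixtures.make_non_si_adaptive()
    for u0 in (0.2, 0.5, 1.7):
        res = steady_state(system, u0)
        assert res.converged
        np.testing.assert_allclose(res.x, [u0, u0, 1.0], atol=1e-9)
        assert res.residual < 1e-9


def test_steady_state_agrees_with_long_integration():
    """Newton-polished settling matches a pure long integration."""
    n_checked = 0
    for seed in range(40):
        system = build_system(fixtures.random_circuit(seed))
        res = steady_state(system, 0.5)
        if not res.converged:
            continue
        x_long = _odeint_segment(system, np.array(MIDPOINT_STATE),
                                 0.5, np.array([0.0, 1e5]), 1e-10, 1e-12)[-1]
        if np.max(np.abs(system.rhs(x_long, 0.5))) > 1e-10:
            continue  # oscillatory or still drifting: not a fixed-point case
        np.testing.assert_allclose(res.x, x_long, atol=1e-7)
        n_checked += 1
    assert n_checked >= 20


def test_circuit_json_roundtrip_is_bit_exact():
    c = fixtures.random_circuit(7)
    c2 = Circuit.from_json(c.to_json())
    assert c2.topology == c.topology
    assert c2.params.values == c.params.values
    assert c2.meta == c.meta
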