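"""Quasi-steady-state reduction and ULFO diagnostics.

ULFO — uniform linearizations with fast output — is the structural property
characterizing approximately scale-invariant circuits:

1. the output node relaxes much faster than the memory nodes (time-scale
   separation), so the system is well approximated by a planar reduction in
   which the output variable is replaced by the root of its own rate balance;
2. that quasi-steady-state output depends (to high accuracy) only on the
   ratio of the memory variables — equivalently, self-loop and constitutive
   contributions to the output equation are negligible and the output map is
   homogeneous of degree zero;
3. the reduced steady state is proportional to the input, and the reduced
   Jacobians (state and input) are the same at every operating point.

This module computes each diagnostic for an arbitrary system with a
designated fast node and combines them into a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .enzyme_model import (
    Circuit,
    MMSystem,
    InputProgram,
    build_system,
    simulate,
    steady_state,
    SRC_CONST,
)

_QSS_XTOL = 1e-14


def _as_system(c):
    return build_system(c) if isinstance(c, Circuit) else c


# ---------------------------------------------------------------------------
# Quasi-steady state of the fast node
# ---------------------------------------------------------------------------

def _fast_balance(system, fast, x_slow, slow_idx, u):
    """Residual of the fast node's rate balance as a function of its value."""
    x = np.empty(system.n)
    x[list(slow_idx)] = x_slow

    def g(cval):
        x[fast] = cval
        return system.rhs(x, u)[fast]

    return g


def qss_root(system, fast: int, x_slow, u: float) -> float:
    """Root of the fast node's balance equation.

    For unit-cube systems the root is bracketed in [0, 1]: production
    vanishes at 1 and removal at 0, so the balance is positive at 0 and
    negative at 1 and strictly decreasing in between.  For unbounded
    hand-built systems the bracket is expanded geometrically.
    """
    slow_idx = [i for i in range(system.n) if i != fast]
    g = _fast_balance(system, fast, np.asarray(x_slow, dtype=float), slow_idx, u)
    if getattr(system, "bounded_states", True):
        g0, g1 = g(0.0), g(1.0)
        if g0 <= 0.0:
            # no production at the fast node (degenerate coefficients)
            return 0.0
        if g1 >= 0.0:
            return 1.0
        return brentq(g, 0.0, 1.0, xtol=_QSS_XTOL)
    hi = 1.0
    for _ in range(60):
        if g(hi) < 0.0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the fast-node quasi-steady state")
    return brentq(g, 0.0, hi, xtol=_QSS_XTOL)


def _quadratic_qss(p, Kp, q, Kq) -> float:
    """Closed-form root in [0, 1] of p*(1-c)/((1-c)+Kp) = q*c/(c+Kq).

    Cross-multiplying gives (q-p)*c^2 + (p*(1-Kq) - q*(1+Kp))*c + p*Kq = 0;
    the balance is strictly decreasing on [0, 1], positive at 0 and negative
    at 1, so exactly one root lies inside.
    """
    A = q - p
    B = p * (1.0 - Kq) - q * (1.0 + Kp)
    C = p * Kq
    if A == 0.0:
        return min(1.0, max(0.0, -C / B))
    disc = B * B - 4.0 * A * C
    disc = max(disc, 0.0)
    r = np.sqrt(disc)
    for c in ((-B - r) / (2 * A), (-B + r) / (2 * A)):
        if -1e-12 <= c <= 1.0 + 1e-12:
            return min(1.0, max(0.0, c))
    raise RuntimeError("quadratic balance has no root in [0, 1]")


def qss_output(c, u: float = 0.0):
    """The output map theta(a, b): the unique root c_ss in [0, 1] of the
    output node's rate balance, as a function of the memory state.

    For a circuit whose output node carries exactly one production and one
    removal term the cross-multiplied balance is quadratic and solved in
    closed form; otherwise the root is isolated by bracketing.  Returns a
    callable ``theta(x_slow, u)``.
    """
    system = _as_system(c)
    fast = system.output
    if isinstance(system, MMSystem):
        prod = [(i, t) for i, t in enumerate(system.interactions)
                if t.target == fast and t.sign > 0]
        rem = [(i, t) for i, t in enumerate(system.interactions)
               if t.target == fast and t.sign < 0]
        slow_idx = [i for i in range(system.n) if i != fast]

        def activity(term, x_slow, u_):
            if term.source == -1:
                return float(u_)
            if term.source == SRC_CONST:
                return 1.0
            if term.source == fast:
                return None  # self-loop: activity equals the unknown root
            return float(x_slow[slow_idx.index(term.source)])

        if len(prod) == 1 and len(rem) == 1:
            ip, tp = prod[0]
            ir, tr = rem[0]

            def theta(x_slow, u_=0.0):
                sp = activity(tp, x_slow, u_)
                sr = activity(tr, x_slow, u_)
                if sp is None or sr is None:  # self-loop: fall back to bracketing
                    return qss_root(system, fast, x_slow, u_)
                p = sp * system.k[ip]
                q = sr * system.k[ir]
                if p <= 0.0:
                    return 0.0
                if q <= 0.0:
                    return 1.0
                return _quadratic_qss(p, system.K[ip], q, system.K[ir])

            return theta

    def theta(x_slow, u_=0.0):
        return qss_root(system, fast, x_slow, u_)

    return theta


# ---------------------------------------------------------------------------
# Planar (or (n-1)-dimensional) reduction
# ---------------------------------------------------------------------------

class ReducedSystem:
    """System obtained by substituting the fast node's quasi-steady state.

    State variables are the parent's slow nodes in their original order; the
    output map ``theta`` returns the substituted fast-node value.  Jacobians
    ``A = dF/dx`` and ``B = dF/du`` are computed analytically from the parent
    Jacobian with implicit differentiation through the quasi-steady state.
    """

    def __init__(self, parent, fast: int = None):
        self.parent = parent
        self.fast = parent.output if fast is None else fast
        self.slow = tuple(i for i in range(parent.n) if i != self.fast)
        self.n = parent.n - 1
        self.theta = qss_output(parent) if isinstance(parent, MMSystem) else (
            lambda xs, u=0.0: qss_root(parent, self.fast, xs, u))
        self.bounded_states = getattr(parent, "bounded_states", True)
        self.output = None  # output is theta, not a state coordinate

    def embed(self, x_slow, u):
        x = np.empty(self.parent.n)
        x[list(self.slow)] = x_slow
        x[self.fast] = self.theta(np.asarray(x_slow, dtype=float), u)
        return x

    def rhs(self, x_slow, u):
        x = self.embed(x_slow, u)
        return self.parent.rhs(x, u)[list(self.slow)]

    def jac(self, x_slow, u):
        x = self.embed(x_slow, u)
        J = self.parent.jac(x, u)
        s = list(self.slow)
        Jss = J[np.ix_(s, s)]
        Jsf = J[s, self.fast]
        Jfs = J[self.fast, s]
        Jff = J[self.fast, self.fast]
        if Jff == 0.0:
            return Jss
        dc_dx = -Jfs / Jff
        return Jss + np.outer(Jsf, dc_dx)

    def dfdu(self, x_slow, u):
        x = self.embed(x_slow, u)
        J = self.parent.jac(x, u)
        bu = self.parent.dfdu(x, u)
        s = list(self.slow)
        Jff = J[self.fast, self.fast]
        out = bu[s]
        if Jff != 0.0 and bu[self.fast] != 0.0:
            dc_du = -bu[self.fast] / Jff
            out = out + J[s, self.fast] * dc_du
        return out


def reduce(c) -> ReducedSystem:
    """Planar reduction of a circuit: fast output node replaced by its QSS."""
    return ReducedSystem(_as_system(c))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def selfloop_contribution(c, traj) -> float:
    """Largest relative weight of self-loop plus constitutive terms in the
    output node's rate budget along a trajectory.

    Scale-invariant circuits have (nearly) no such terms: the output balance
    then involves only the memory variables, making the quasi-steady-state
    output a function of their ratio.
    """
    system = _as_system(c)
    if not isinstance(system, MMSystem):
        val = getattr(system, "selfloop_fraction", None)
        if val is None:
            raise TypeError("selfloop_contribution needs a term-structured system")
        return float(val)
    fast = system.output
    idx_all = [i for i, t in enumerate(system.interactions) if t.target == fast]
    idx_sl = [i for i, t in enumerate(system.interactions)
              if t.target == fast and (t.source == fast or t.source == SRC_CONST)]
    if not idx_sl:
        return 0.0
    worst = 0.0
    for x, u in zip(traj.x, traj.u):
        fluxes = system.term_fluxes(x, u)
        denom = np.sum(np.abs(fluxes[idx_all]))
        if denom <= 0:
            continue
        worst = max(worst, float(np.sum(np.abs(fluxes[idx_sl])) / denom))
    return worst


def steady_state_map(rs: ReducedSystem, u_grid, **ss_kwargs):
    """Reduced steady states over an input grid, plus the proportionality
    deviation of x_bar(u)/u from its grid mean.

    ULFO requires the pre-adapted memory state to scale linearly with the
    background input (an integration mechanism); ``prop_dev`` measures the
    worst relative departure from that proportionality.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    states, converged = [], []
    for u in u_grid:
        res = steady_state(rs, u, **ss_kwargs)
        states.append(res.x)
        converged.append(res.converged)
    states = np.array(states)
    v = states / u_grid[:, None]
    vbar = v.mean(axis=0)
    denom = np.linalg.norm(vbar)
    prop_dev = (float(np.max(np.linalg.norm(v - vbar, axis=1)) / denom)
                if denom > 0 else np.inf)
    return states, np.array(converged), prop_dev


def jacobians(rs: ReducedSystem, u: float, x_bar=None):
    """Reduced state Jacobian A and input Jacobian B at the operating point."""
    if x_bar is None:
        res = steady_state(rs, u)
        if not res.converged:
            raise RuntimeError(f"no reduced steady state at u={u}")
        x_bar = res.x
    return rs.jac(x_bar, u), rs.dfdu(x_bar, u)


def fd_jacobians(rs: ReducedSystem, u: float, x_bar, h: float = 1e-6):
    """Central finite-difference cross-check of :func:`jacobians`."""
    x_bar = np.asarray(x_bar, dtype=float)
    A = np.empty((rs.n, rs.n))
    for j in range(rs.n):
        dx = np.zeros(rs.n)
        dx[j] = h
        A[:, j] = (rs.rhs(x_bar + dx, u) - rs.rhs(x_bar - dx, u)) / (2 * h)
    hu = h * max(1.0, abs(u))
    B = (rs.rhs(x_bar, u + hu) - rs.rhs(x_bar, u - hu)) / (2 * hu)
    return A, B


def uniformity(rs: ReducedSystem, u_grid, states=None):
    """Mean consecutive-pair relative differences of the reduced Jacobians.

    Delta_A = mean_i ||A(u_{i+1}) - A(u_i)||_F / ||A(u_i)||_F, and likewise
    Delta_B with the Euclidean norm.  Near-zero values mean the linearization
    is the same at every pre-adapted operating point — the "uniform" part of
    ULFO.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    As, Bs = [], []
    for i, u in enumerate(u_grid):
        x_bar = None if states is None else states[i]
        A, B = jacobians(rs, u, x_bar)
        As.append(A)
        Bs.append(B)
    dA, dB = [], []
    for i in range(len(u_grid) - 1):
        nA = np.linalg.norm(As[i])
        nB = np.linalg.norm(Bs[i])
        dA.append(np.linalg.norm(As[i + 1] - As[i]) / nA if nA > 0 else np.inf)
        dB.append(np.linalg.norm(Bs[i + 1] - Bs[i]) / nB if nB > 0 else np.inf)
    return float(np.mean(dA)), float(np.mean(dB))


def homogeneity_deviation(rs: ReducedSystem, states, u_grid=None, p: float = 2.0):
    """Max over test states of |theta(p*x) - theta(x)|.

    Exact degree-zero homogeneity holds whenever the output balance is a pure
    push-pull in the memory variables (no self-loop, no constitutive terms).
    The input argument, when the output map depends on it, is scaled together
    with the state.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if u_grid is None:
        u_grid = np.zeros(len(states))
    worst = 0.0
    for xs, u in zip(states, np.asarray(u_grid, dtype=float)):
        worst = max(worst, abs(float(rs.theta(p * xs, p * u)) -
                               float(rs.theta(xs, u))))
    return worst


def timescale_ratio(c, x_bar, u0: float) -> float:
    """Speed of the output node relative to the reduced memory dynamics.

    rho_ts = |d(dc/dt)/dc| at the full steady state, divided by the spectral
    radius of the reduced state Jacobian.  Large values justify the
    quasi-steady-state substitution.
    """
    system = _as_system(c)
    fast = system.output
    J = system.jac(np.asarray(x_bar, dtype=float), u0)
    lam_fast = abs(J[fast, fast])
    rs = ReducedSystem(system)
    xs = np.asarray(x_bar, dtype=float)[list(rs.slow)]
    A = rs.jac(xs, u0)
    rad = np.max(np.abs(np.linalg.eigvals(A)))
    if rad == 0:
        return np.inf
    return float(lam_fast / rad)


# ---------------------------------------------------------------------------
# Report and verdict
# ---------------------------------------------------------------------------

@dataclass
class UlfoThresholds:
    """Cutoffs turning the continuous diagnostics into a verdict.

    The diagnostics of genuinely scale-invariant circuits sit far from these
    cutoffs (near-zero deviations, large time-scale ratios), so the verdict is
    not sensitive to their exact placement; all are configurable.
    """

    ts_min: float = 10.0
    selfloop_max: float = 0.01
    homogeneity_max: float = 0.01
    prop_max: float = 0.05
    dA_max: float = 0.05
    dB_max: float = 0.05


@dataclass
class UlfoReport:
    timescale: float
    selfloop_frac: float
    homogeneity_dev: float
    prop_dev: float
    dA: float
    dB: float
    u_grid: list
    conditions: dict = field(default_factory=dict)
    verdict: bool = False
    thresholds: UlfoThresholds = field(default_factory=UlfoThresholds)
    notes: list = field(default_factory=list)

    def to_dict(self):
        d = asdict(self)
        return d


def ulfo_verdict(report: UlfoReport,
                 thresholds: UlfoThresholds = None) -> UlfoReport:
    """Fill in per-condition booleans and the overall conjunction."""
    th = thresholds or report.thresholds
    report.thresholds = th
    report.conditions = {
        "timescale": report.timescale >= th.ts_min,
        "selfloop": report.selfloop_frac <= th.selfloop_max,
        "homogeneity": report.homogeneity_dev <= th.homogeneity_max,
        "proportionality": report.prop_dev <= th.prop_max,
        "uniform_A": report.dA <= th.dA_max,
        "uniform_B": report.dB <= th.dB_max,
    }
    report.verdict = all(report.conditions.values())
    return report


def ulfo_report(c, u0: float, n_grid: int = 8, u_span: float = 4.0,
                p: float = 2.0, thresholds: UlfoThresholds = None,
                step_fraction: float = 0.2, **ss_kwargs) -> UlfoReport:
    """Compute every ULFO diagnostic for a circuit at background input u0.

    The input grid spans [u0, u_span*u0] in log space (covering the scaled
    step experiment with margin).  The self-loop budget is evaluated along a
    ``step_fraction`` step response from u0.
    """
    system = _as_system(c)
    notes = []
    rs = ReducedSystem(system)
    u_grid = np.geomspace(u0, u_span * u0, n_grid)

    states, conv, prop_dev = steady_state_map(rs, u_grid, **ss_kwargs)
    if not conv.all():
        notes.append("reduced steady state did not converge on the whole grid")
    dA, dB = uniformity(rs, u_grid, states)
    hom = homogeneity_deviation(rs, states, u_grid, p=p)

    ss_full = steady_state(system, u0, **ss_kwargs)
    if not ss_full.converged:
        notes.append("full steady state did not converge at u0")
    ts = timescale_ratio(system, ss_full.x, u0)

    u1 = u0 * (1.0 + step_fraction)
    prog = InputProgram.make_step(u0, u1, 0.0)
    # horizon covers the slow (memory) transient
    rad = np.max(np.abs(np.linalg.eigvals(rs.jac(states[0], u_grid[0]))))
    horizon = min(20.0 / max(rad, 1e-6), 1e4)
    traj = simulate(system, prog, ss_full.x, (0.0, horizon), n_points=300)
    sl = selfloop_contribution(system, traj)

    report = UlfoReport(timescale=ts, selfloop_frac=sl, homogeneity_dev=hom,
                        prop_dev=prop_dev, dA=dA, dB=dB,
                        u_grid=list(u_grid), notes=notes)
    return ulfo_verdict(report, thresholds or UlfoThresholds())


def near_boundary(report: UlfoReport, margin: float = 0.25) -> bool:
    """True when any diagnostic lies within ``margin`` (relative) of its
    cutoff — verdicts for such circuits are threshold artifacts and are
    logged rather than trusted in concordance checks."""
    th = report.thresholds
    pairs = [
        (report.timescale, th.ts_min),
        (report.selfloop_frac, th.selfloop_max),
        (report.homogeneity_dev, th.homogeneity_max),
        (report.prop_dev, th.prop_max),
        (report.dA, th.dA_max),
        (report.dB, th.dB_max),
    ]
    for value, cut in pairs:
        if np.isfinite(value) and cut * (1 - margin) <= value <= cut * (1 + margin):
            return True
    return False
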