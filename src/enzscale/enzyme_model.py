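"""Michaelis-Menten ODE models of enzymatic activation/deactivation networks.

Each node N holds an enzyme cycling between active (fraction ``x_N``) and
inactive (fraction ``1 - x_N``) forms.  An activating regulator X of N drives
the forward reaction with flux ``x_X * k * (1 - x_N) / ((1 - x_N) + K)`` and a
deactivating regulator the reverse flux ``x_X * k' * x_N / (x_N + K')``.  Node
A is activated by the external input u(t) instead of by a constitutive enzyme.
Whenever a node would otherwise lack a forward (or reverse) reaction, a
constitutive activating (deactivating) enzyme with fixed unit activity is
inserted, so that every cycle stays reversible.

The right-hand side is compiled with numba from a flat term table so that the
large parameter screens stay affordable; the same table drives the analytic
Jacobian used by the stiff integrator and by Newton refinement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit
from scipy.integrate import odeint, solve_ivp
from scipy.optimize import root

from .topology import NODES, PAIRS, Topology

# Source codes used in the flat term table.
SRC_INPUT = -1  # the external input u(t)
SRC_CONST = -2  # constitutive enzyme, activity buffered at 1.0

#: Constitutive enzymes are buffered at constant concentration; their activity
#: is fixed at 1.0 and the concentration absorbed into the catalytic constant.
CONSTITUTIVE_ACTIVITY = 1.0


@dataclass(frozen=True)
class Interaction:
    """One regulatory arrow contributing a Michaelis-Menten flux term."""

    name: str        # e.g. "A->C", "I->A", "E_B", "F_C"
    target: int      # state index of the regulated node
    source: int      # state index, SRC_INPUT, or SRC_CONST
    sign: int        # +1 activation, -1 deactivation


def implied_interactions(t: Topology) -> list:
    """The full interaction list a topology implies.

    Ordering is canonical: the input term on A first, then topology edges in
    row-major pair order, then constitutive activators E_N, then constitutive
    deactivators F_N.  Node A never receives a constitutive activator — the
    external input takes that role.
    """
    inter = [Interaction("I->A", 0, SRC_INPUT, +1)]
    for (x, y) in PAIRS:
        s = t.edge(x, y)
        if s != 0:
            inter.append(Interaction(f"{x}->{y}", NODES.index(y), NODES.index(x), s))
    for n in NODES[1:]:  # constitutive activation, never on A
        if not t.activators_of(n):
            inter.append(Interaction(f"E_{n}", NODES.index(n), SRC_CONST, +1))
    for n in NODES:
        if not t.deactivators_of(n):
            inter.append(Interaction(f"F_{n}", NODES.index(n), SRC_CONST, -1))
    return inter


@dataclass
class CircuitParams:
    """(k, K) pairs keyed by interaction name.

    ``k`` is the catalytic rate constant (1/time) and ``K`` the Michaelis
    constant in fractional-activity units; both strictly positive.
    """

    values: dict  # name -> (k, K)

    def __post_init__(self):
        for name, (k, K) in self.values.items():
            if not (k > 0 and K > 0):
                raise ValueError(f"rate constants must be positive ({name}: k={k}, K={K})")

    def __getitem__(self, name):
        return self.values[name]

    def __contains__(self, name):
        return name in self.values


@dataclass
class Circuit:
    """A topology together with a concrete parameter choice."""

    topology: Topology
    params: CircuitParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        want = {i.name for i in implied_interactions(self.topology)}
        have = set(self.params.values)
        if want != have:
            raise ValueError(
                f"parameters inconsistent with topology: missing {sorted(want - have)}, "
                f"extra {sorted(have - want)}"
            )

    # -- JSON round-trip ---------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "topology": list(self.topology.edges),
            "params": {n: {"k": k, "K": K} for n, (k, K) in self.params.values.items()},
            "meta": self.meta,
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "Circuit":
        obj = json.loads(s)
        return cls(
            topology=Topology(tuple(obj["topology"])),
            params=CircuitParams({n: (d["k"], d["K"]) for n, d in obj["params"].items()}),
            meta=obj.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# Compiled Michaelis-Menten kernels
# ---------------------------------------------------------------------------

@njit(fastmath=False)
def _mm_rhs(x, u, tgt, src, sgn, kk, KK, out):  # pragma: no cover - numba
    out[:] = 0.0
    for i in range(tgt.shape[0]):
        t = tgt[i]
        xt = x[t]
        if xt < 0.0:
            xt = 0.0
        elif xt > 1.0:
            xt = 1.0
        if src[i] == -1:
            s = u
        elif src[i] == -2:
            s = 1.0
        else:
            s = x[src[i]]
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
        if sgn[i] > 0:
            out[t] += s * kk[i] * (1.0 - xt) / ((1.0 - xt) + KK[i])
        else:
            out[t] -= s * kk[i] * xt / (xt + KK[i])


@njit(fastmath=False)
def _mm_jac(x, u, tgt, src, sgn, kk, KK, out):  # pragma: no cover - numba
    out[:, :] = 0.0
    for i in range(tgt.shape[0]):
        t = tgt[i]
        xt = x[t]
        if xt < 0.0:
            xt = 0.0
        elif xt > 1.0:
            xt = 1.0
        if src[i] == -1:
            s = u
        elif src[i] == -2:
            s = 1.0
        else:
            s = x[src[i]]
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
        if sgn[i] > 0:
            den = (1.0 - xt) + KK[i]
            out[t, t] += -s * kk[i] * KK[i] / (den * den)
            if src[i] >= 0:
                out[t, src[i]] += kk[i] * (1.0 - xt) / den
        else:
            den = xt + KK[i]
            out[t, t] -= s * kk[i] * KK[i] / (den * den)
            if src[i] >= 0:
                out[t, src[i]] -= kk[i] * xt / den


@njit(fastmath=False)
def _mm_dfdu(x, u, tgt, src, sgn, kk, KK, out):  # pragma: no cover - numba
    out[:] = 0.0
    for i in range(tgt.shape[0]):
        if src[i] != -1:
            continue
        t = tgt[i]
        xt = x[t]
        if xt < 0.0:
            xt = 0.0
        elif xt > 1.0:
            xt = 1.0
        if sgn[i] > 0:
            out[t] += kk[i] * (1.0 - xt) / ((1.0 - xt) + KK[i])
        else:
            out[t] -= kk[i] * xt / (xt + KK[i])


class MMSystem:
    """Flat-term-table view of a circuit with compiled rhs/Jacobian.

    Also usable directly for hand-built Michaelis-Menten systems of any
    dimension (``linres`` exploits this for n-node extensions).
    """

    def __init__(self, interactions: Sequence[Interaction], params: CircuitParams,
                 n: int = 3, output: int = 2):
        self.interactions = list(interactions)
        self.params = params
        self.n = n
        self.output = output
        self.names = [i.name for i in self.interactions]
        self.tgt = np.array([i.target for i in self.interactions], dtype=np.int64)
        self.src = np.array([i.source for i in self.interactions], dtype=np.int64)
        self.sgn = np.array([i.sign for i in self.interactions], dtype=np.int64)
        self.k = np.array([params[i.name][0] for i in self.interactions])
        self.K = np.array([params[i.name][1] for i in self.interactions])
        self._f = np.empty(n)
        self._J = np.empty((n, n))

    def rhs(self, x, u):
        out = np.empty(self.n)
        _mm_rhs(np.asarray(x, dtype=float), float(u), self.tgt, self.src, self.sgn,
                self.k, self.K, out)
        return out

    def jac(self, x, u):
        out = np.empty((self.n, self.n))
        _mm_jac(np.asarray(x, dtype=float), float(u), self.tgt, self.src, self.sgn,
                self.k, self.K, out)
        return out

    def dfdu(self, x, u):
        out = np.empty(self.n)
        _mm_dfdu(np.asarray(x, dtype=float), float(u), self.tgt, self.src, self.sgn,
                 self.k, self.K, out)
        return out

    def term_fluxes(self, x, u):
        """Signed flux of every interaction term at state ``x``, input ``u``."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        out = np.empty(len(self.interactions))
        for i, inter in enumerate(self.interactions):
            xt = x[inter.target]
            if inter.source == SRC_INPUT:
                s = float(u)
            elif inter.source == SRC_CONST:
                s = CONSTITUTIVE_ACTIVITY
            else:
                s = x[inter.source]
            if inter.sign > 0:
                out[i] = s * self.k[i] * (1.0 - xt) / ((1.0 - xt) + self.K[i])
            else:
                out[i] = -s * self.k[i] * xt / (xt + self.K[i])
        return out


def build_system(c: Circuit) -> MMSystem:
    """Instantiate the compiled ODE system of a circuit."""
    return MMSystem(implied_interactions(c.topology), c.params)


def build_rhs(c: Circuit) -> Callable:
    """The vector field f(state, u) of a circuit (3-dimensional)."""
    return build_system(c).rhs


class GenericSystem:
    """A hand-written ODE system with the same duck interface as MMSystem.

    Used for analytic fixture families and for n-node extensions (reporter
    nodes, input pre-filters) whose states need not live in the unit cube.
    """

    def __init__(self, n, rhs, jac=None, dfdu=None, output=None,
                 bounded_states=False, name=""):
        self.n = n
        self._rhs = rhs
        self._jac = jac
        self._dfdu = dfdu
        self.output = n - 1 if output is None else output
        self.bounded_states = bounded_states
        self.name = name

    def rhs(self, x, u):
        return np.asarray(self._rhs(np.asarray(x, dtype=float), float(u)))

    @property
    def jac(self):
        # hasattr(system, "jac") is the protocol probe for an analytic Jacobian
        if self._jac is None:
            raise AttributeError("no analytic Jacobian for this system")
        fn = self._jac
        return lambda x, u: np.asarray(fn(np.asarray(x, dtype=float), float(u)))

    def dfdu(self, x, u):
        if self._dfdu is not None:
            return np.asarray(self._dfdu(np.asarray(x, dtype=float), float(u)))
        h = max(1e-6, 1e-6 * abs(u))
        return (self.rhs(x, u + h) - self.rhs(x, u - h)) / (2 * h)


# ---------------------------------------------------------------------------
# Input programs and trajectories
# ---------------------------------------------------------------------------

@dataclass
class InputProgram:
    """A bounded scalar input u(t); steps are the screen's workhorse."""

    fn: Callable
    u_min: float
    u_max: float
    step: Optional[tuple] = None  # (u0, u1, t_step) when a pure step

    @classmethod
    def constant(cls, u0: float) -> "InputProgram":
        return cls(fn=lambda t: u0, u_min=u0, u_max=u0, step=(u0, u0, 0.0))

    @classmethod
    def make_step(cls, u0: float, u1: float, t_step: float = 0.0) -> "InputProgram":
        lo, hi = min(u0, u1), max(u0, u1)
        return cls(fn=lambda t: u1 if t >= t_step else u0,
                   u_min=lo, u_max=hi, step=(u0, u1, t_step))

    def __call__(self, t: float) -> float:
        return self.fn(t)


@dataclass
class Trajectory:
    """A simulated path: time grid, states, input and output series."""

    t: np.ndarray
    x: np.ndarray        # shape (len(t), n)
    u: np.ndarray
    y: np.ndarray        # output series (active fraction of the output node)
    system: object = None

    def to_frame(self):
        import pandas as pd
        cols = {"t": self.t}
        labels = ["a", "b", "c", "d", "e"]
        for j in range(self.x.shape[1]):
            cols[labels[j] if j < len(labels) else f"x{j}"] = self.x[:, j]
        cols["u"] = self.u
        return pd.DataFrame(cols)


DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
STATE_TOL = 1e-6  # allowed numerical excursion outside [0, 1]


class IntegrationError(RuntimeError):
    pass


def _odeint_segment(system, x0, u_const, t_grid, rtol, atol):
    """Integrate one constant-input segment with LSODA."""
    def f(x, t):
        return system.rhs(x, u_const)

    def Df(x, t):
        return system.jac(x, u_const)

    jac = Df if hasattr(system, "jac") else None
    out, info = odeint(f, x0, t_grid, Dfun=jac, rtol=rtol, atol=atol,
                       full_output=True, mxstep=100000)
    if info["message"] != "Integration successful.":
        raise IntegrationError(info["message"])
    return out


def simulate(system, input_program: InputProgram, x0, t_span, tol=None,
             n_points: int = 400, t_grid=None) -> Trajectory:
    """Integrate a system under an input program.

    Piecewise-constant (step) inputs are integrated segment-wise with the
    stiff LSODA solver; general time-varying inputs fall back to ``solve_ivp``
    (LSODA as well).  States are checked against the unit-cube invariance
    contract and clipped within the excursion tolerance.
    """
    rtol = DEFAULT_RTOL if tol is None else tol
    atol = DEFAULT_ATOL if tol is None else tol * 1e-2
    x0 = np.asarray(x0, dtype=float)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t_grid is None:
        t_grid = np.linspace(t0, t1, n_points)
    else:
        t_grid = np.asarray(t_grid, dtype=float)

    step = input_program.step
    if step is not None:
        u0, u1, ts = step
        if ts <= t_grid[0] or u0 == u1:
            x = _odeint_segment(system, x0, u1 if ts <= t_grid[0] else u0,
                                t_grid, rtol, atol)
        elif ts >= t_grid[-1]:
            x = _odeint_segment(system, x0, u0, t_grid, rtol, atol)
        else:
            pre = t_grid[t_grid < ts]
            post = t_grid[t_grid >= ts]
            seg1 = _odeint_segment(system, x0, u0, np.concatenate([pre, [ts]]),
                                   rtol, atol)
            seg2 = _odeint_segment(system, seg1[-1], u1,
                                   np.concatenate([[ts], post]), rtol, atol)
            x = np.vstack([seg1[:-1], seg2[1:]])
    else:
        sol = solve_ivp(lambda t, x: system.rhs(x, input_program(t)),
                        (t_grid[0], t_grid[-1]), x0, method="LSODA",
                        t_eval=t_grid, rtol=rtol, atol=atol,
                        jac=(lambda t, x: system.jac(x, input_program(t)))
                        if hasattr(system, "jac") else None)
        if not sol.success:
            raise IntegrationError(sol.message)
        x = sol.y.T

    bounded = getattr(system, "bounded_states", True)
    if bounded:
        if x.min() < -STATE_TOL or x.max() > 1.0 + STATE_TOL:
            raise IntegrationError(
                f"state excursion beyond tolerance: min={x.min():.3g}, max={x.max():.3g}")
        x = np.clip(x, 0.0, 1.0)
    u = np.array([input_program(t) for t in t_grid])
    y = x[:, getattr(system, "output", system.n - 1)]
    return Trajectory(t=t_grid, x=x, u=u, y=y, system=system)


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateResult:
    x: np.ndarray
    converged: bool
    residual: float
    t_used: float
    reason: str = "ok"


MIDPOINT_STATE = (0.5, 0.5, 0.5)
SS_RESIDUAL_TOL = 1e-9
SS_T_MAX = 1e4

# Settling is probed at geometrically growing horizons; Newton polish is only
# accepted when its correction is small, i.e. when integration has already
# brought the state near the fixed point (large corrections may jump to an
# unstable root).
_SETTLE_CHUNKS = (20.0, 80.0, 400.0, 1500.0, 8000.0)
_NEWTON_TRUST = 0.05


def _newton_polish(system, x, u0, tol):
    jac = (lambda z: system.jac(z, u0)) if hasattr(system, "jac") else None
    try:
        sol = root(lambda z: system.rhs(z, u0), x, jac=jac, method="hybr",
                   tol=1e-12)
    except Exception:
        return None
    if not sol.success:
        return None
    xn = sol.x
    bounded = getattr(system, "bounded_states", True)
    if bounded and (xn.min() < -STATE_TOL or xn.max() > 1.0 + STATE_TOL):
        return None
    if np.max(np.abs(xn - x)) > _NEWTON_TRUST:
        return None
    if np.max(np.abs(system.rhs(xn, u0))) >= tol:
        return None
    return np.clip(xn, 0.0, 1.0) if bounded else xn


def steady_state(system, u0: float, x0=None, tol: float = SS_RESIDUAL_TOL,
                 t_max: float = SS_T_MAX, rtol: float = DEFAULT_RTOL,
                 atol: float = DEFAULT_ATOL) -> SteadyStateResult:
    """Pre-adapted steady state under constant input ``u0``.

    Integrates from the midpoint state in growing chunks, polishing with
    Newton once the state stops moving; reports non-convergence as a flag so
    screening stays total (oscillatory or very slow circuits are classified,
    not crashed on).
    """
    if x0 is None:
        x0 = MIDPOINT_STATE[: system.n] if system.n <= 3 else (0.5,) * system.n
    x = np.asarray(x0, dtype=float)
    t_done = 0.0
    for dt in _SETTLE_CHUNKS:
        if t_done >= t_max:
            break
        dt = min(dt, t_max - t_done)
        try:
            x = _odeint_segment(system, x, u0, np.array([0.0, dt]), rtol, atol)[-1]
        except IntegrationError:
            return SteadyStateResult(x, False, np.inf, t_done, "integration_failure")
        t_done += dt
        xn = _newton_polish(system, x, u0, tol)
        if xn is not None:
            res = float(np.max(np.abs(system.rhs(xn, u0))))
            return SteadyStateResult(xn, True, res, t_done)
        res = float(np.max(np.abs(system.rhs(x, u0))))
        if res < tol:
            return SteadyStateResult(x, True, res, t_done)
    res = float(np.max(np.abs(system.rhs(x, u0))))
    return SteadyStateResult(x, res < tol, res, t_done,
                             "ok" if res < tol else "no_settle")
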