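"""Analytic circuit families with known ground truth.

Three hand-built families bracket the behaviors the screen must be able to
tell apart:

* ``non_si_adaptive`` — a linear-memory incoherent feedforward system that
  adapts perfectly (the steady-state output is input-independent) yet is not
  scale invariant: the transient depends on the absolute input scale.
* ``exact_fcd`` — a ratio-output variant that is an exact fold-change
  detector: after pre-adaptation, scaled steps give identical responses.
* ``ulfo_family`` — a genuine Michaelis-Menten incoherent-feedforward circuit
  whose output-node rates carry an explicit 1/eps speed-up and whose memory
  nodes sit in a near-linear regime, so that all ULFO conditions hold for
  small eps and the time-scale condition fails as eps -> 1.

These are the backbone of the test suite: every metric, screen verdict and
ULFO diagnostic is validated against their analytic behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzyme_model import Circuit, CircuitParams, GenericSystem, build_system
from .topology import Topology, from_index, has_io_path, N_TOPOLOGIES


@dataclass
class FixtureSpec:
    """Name, parameters and documented ground truth of a fixture family."""

    family: str
    params: dict = field(default_factory=dict)
    adapts: bool = None
    asi: bool = None
    ulfo: bool = None


def make_non_si_adaptive() -> GenericSystem:
    """Perfectly adapting, not scale invariant.

        da/dt = u - a,   db/dt = a - b,   dc/dt = a - b*c

    A activates both B and C; B enhances deactivation of C.  For constant
    input the steady state is (u, u, 1): the output adapts exactly, for every
    input level.  But the early transient of c grows with the input scale, so
    responses from scaled backgrounds do not overlap.
    """

    def rhs(x, u):
        a, b, c = x
        return np.array([u - a, a - b, a - b * c])

    def jac(x, u):
        a, b, c = x
        return np.array([[-1.0, 0.0, 0.0], [1.0, -1.0, 0.0], [1.0, -c, -b]])

    def dfdu(x, u):
        return np.array([1.0, 0.0, 0.0])

    sys = GenericSystem(3, rhs, jac=jac, dfdu=dfdu, output=2,
                        bounded_states=False, name="non_si_adaptive")
    sys.selfloop_fraction = 0.0  # no self-loop or constitutive term on the output
    return sys


def make_exact_fcd(eps: float = 1e-3) -> GenericSystem:
    """Exact fold-change detector with a fast ratio-form output.

        da/dt = u - a,   eps * dc/dt = u/(u + a) - c

    Pre-adapted to u0 the memory is a = u0; replacing u by p*u scales a by p
    and leaves the ratio u/(u+a) unchanged, so the output transient is exactly
    invariant under input scaling (for every eps, not only in the fast limit).
    The steady-state output is 1/2 for every constant input.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")

    def rhs(x, u):
        a, c = x
        return np.array([u - a, (u / (u + a) - c) / eps])

    def jac(x, u):
        a, c = x
        return np.array([[-1.0, 0.0], [-u / (u + a) ** 2 / eps, -1.0 / eps]])

    def dfdu(x, u):
        a, c = x
        return np.array([1.0, a / (u + a) ** 2 / eps])

    sys = GenericSystem(2, rhs, jac=jac, dfdu=dfdu, output=1,
                        bounded_states=False, name=f"exact_fcd(eps={eps})")
    sys.selfloop_fraction = 0.0
    return sys


#: The incoherent feedforward topology used by the ULFO family:
#: A -> B (+), A -> C (+), B -> C (-).
ULFO_TOPOLOGY = Topology.from_dict({("A", "B"): +1, ("A", "C"): +1, ("B", "C"): -1})

#: Same motif with the nested negative feedback loop closed (C -> B (+)),
#: the structure shared by scale-invariant circuits.
ULFO_TOPOLOGY_FB = Topology.from_dict(
    {("A", "B"): +1, ("A", "C"): +1, ("B", "C"): -1, ("C", "B"): +1})


def make_ulfo_family(eps: float = 0.01, input_scale: float = 1.0,
                     u0: float = 0.1, feedback: bool = True) -> Circuit:
    """A Michaelis-Menten circuit engineered to satisfy ULFO for small eps.

    The memory nodes A and B run far below saturation (small activities,
    large Michaelis constants on their own reactions), so their steady states
    are nearly proportional to the input and their linearizations nearly
    input-independent.  The output node C has a balanced push-pull pair
    (activation by A, deactivation by B) with no self-loop and no constitutive
    term, so its quasi-steady state depends only on the ratio a/b; its rates
    carry an explicit 1/eps factor setting the time-scale separation.

    ``input_scale`` multiplies the input drive: larger values push the memory
    nodes toward saturation and degrade the uniform-linearization conditions.
    ``u0`` is the intended background input; the family is designed for
    operating inputs within roughly [u0, 5*u0].  With ``feedback`` the nested
    negative loop C -> B (+) of the scale-invariant motif is included; its
    coupling is weak so the memory steady states stay proportional to the
    input.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    values = {
        "I->A": (0.001 * input_scale, 10.0),
        "A->B": (0.1, 10.0),
        "A->C": (10.0 / 1.1 / eps, 0.05),
        "B->C": (10.0 / eps, 0.05),
        "F_A": (1.0, 100.0),
        "F_B": (1.0, 100.0),
    }
    topo = ULFO_TOPOLOGY
    if feedback:
        topo = ULFO_TOPOLOGY_FB
        values["C->B"] = (1e-7, 10.0)
    params = CircuitParams(values)
    return Circuit(topology=topo, params=params,
                   meta={"family": "ulfo_family", "eps": eps,
                         "input_scale": input_scale, "u0": u0,
                         "feedback": feedback})


def ulfo_family_system(eps: float = 0.01, input_scale: float = 1.0):
    return build_system(make_ulfo_family(eps, input_scale))


def random_circuit(seed: int, k_range=(0.1, 10.0), K_range=(1e-3, 100.0)) -> Circuit:
    """A uniformly random retained topology with one Latin-hypercube draw.

    Topologies are rejection-sampled until an input-to-output path exists;
    the draw is fully determined by ``seed``.
    """
    from .screen import sample_params  # local import to keep modules acyclic

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5eed]))
    while True:
        idx = int(rng.integers(0, N_TOPOLOGIES))
        topo = from_index(idx)
        if has_io_path(topo):
            break
    params = sample_params(topo, 1, seed=seed, k_range=k_range, K_range=K_range)[0]
    return Circuit(topology=topo, params=params,
                   meta={"seed": seed, "topology_index": idx, "param_id": 0})
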