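"""Enumeration and motif classification of signed three-node interaction graphs.

A network wires three enzymes A, B, C, each switching between an active and an
inactive form.  Node A receives the external input, node C reports the output,
and B is an auxiliary element.  Every ordered pair of nodes (including
self-loops) either carries an activating edge (+1), a deactivating edge (-1),
or no edge (0), giving 3**9 = 19,683 labeled topologies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

NODES = ("A", "B", "C")

#: Ordered pairs in canonical (row-major) order; first entry is most
#: significant in the base-3 index.
PAIRS = tuple((x, y) for x in NODES for y in NODES)

N_TOPOLOGIES = 3 ** 9

_LABEL_TO_DIGIT = {0: 0, 1: 1, -1: 2}
_DIGIT_TO_LABEL = {0: 0, 1: 1, 2: -1}


@dataclass(frozen=True)
class Topology:
    """Signed interaction map over nodes {A, B, C}.

    ``edges`` maps each ordered pair (source, target) to +1 (activation),
    -1 (deactivation) or 0 (no interaction).  Node roles are fixed: A is the
    sole input-receiving node and C the sole output node.
    """

    edges: tuple  # nine labels, in PAIRS order

    def __post_init__(self):
        if len(self.edges) != 9:
            raise ValueError("a topology has exactly 9 ordered node pairs")
        if any(e not in (-1, 0, 1) for e in self.edges):
            raise ValueError("edge labels must be in {-1, 0, +1}")

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        """Build from a mapping like ``{("A", "C"): +1, ...}``; missing pairs are 0."""
        return cls(tuple(d.get(p, 0) for p in PAIRS))

    def __getitem__(self, pair) -> int:
        return self.edges[PAIRS.index(tuple(pair))]

    def edge(self, source: str, target: str) -> int:
        return self.edges[PAIRS.index((source, target))]

    def as_dict(self) -> dict:
        return {p: e for p, e in zip(PAIRS, self.edges) if e != 0}

    @property
    def index(self) -> int:
        return topology_index(self)

    def activators_of(self, node: str):
        """Nodes X with an activating edge X -> node."""
        return [x for x in NODES if self.edge(x, node) == +1]

    def deactivators_of(self, node: str):
        return [x for x in NODES if self.edge(x, node) == -1]


@dataclass(frozen=True)
class MotifFlags:
    """Structural motif indicators relevant to scale-invariant adaptation."""

    has_direct_AC: bool
    has_indirect_via_B: bool
    is_feedforward: bool
    is_incoherent: bool
    has_BC_positive_CB_negative_feedback: bool
    #: a negative two-cycle between B and C in either orientation
    #: (sign(B->C) * sign(C->B) == -1)
    has_nested_negative_BC_loop: bool
    has_C_self_loop: bool


def topology_index(t: Topology) -> int:
    """Canonical base-3 index, pair order ``PAIRS`` (A->A most significant),
    digit values 0: absent, 1: +1, 2: -1."""
    i = 0
    for e in t.edges:
        i = 3 * i + _LABEL_TO_DIGIT[e]
    return i


def from_index(i: int) -> Topology:
    """Inverse of :func:`topology_index`."""
    if not 0 <= i < N_TOPOLOGIES:
        raise ValueError(f"topology index {i} out of range [0, {N_TOPOLOGIES - 1}]")
    digits = []
    for _ in range(9):
        digits.append(_DIGIT_TO_LABEL[i % 3])
        i //= 3
    return Topology(tuple(reversed(digits)))


def enumerate_topologies() -> Iterator[Topology]:
    """Yield all 19,683 labeled topologies in ascending canonical index order."""
    for i in range(N_TOPOLOGIES):
        yield from_index(i)


def has_io_path(t: Topology) -> bool:
    """True iff a directed path of nonzero edges leads from input node A to
    output node C.  With three nodes this reduces to a direct A->C edge or the
    two-step route through B; self-loops never create a path."""
    direct = t.edge("A", "C") != 0
    via_b = t.edge("A", "B") != 0 and t.edge("B", "C") != 0
    return direct or via_b


def classify_motifs(t: Topology) -> MotifFlags:
    """Compute the motif flags of a topology.

    The feedforward motif requires both the direct A->C interaction and the
    indirect route A->B->C; it is incoherent when the sign of the direct edge
    differs from the product of signs along the indirect route.
    """
    ac, ab, bc = t.edge("A", "C"), t.edge("A", "B"), t.edge("B", "C")
    direct = ac != 0
    indirect = ab != 0 and bc != 0
    ff = direct and indirect
    incoherent = ff and (ac != ab * bc)
    return MotifFlags(
        has_direct_AC=direct,
        has_indirect_via_B=indirect,
        is_feedforward=ff,
        is_incoherent=incoherent,
        has_BC_positive_CB_negative_feedback=(bc == +1 and t.edge("C", "B") == -1),
        has_nested_negative_BC_loop=(bc * t.edge("C", "B") == -1),
        has_C_self_loop=t.edge("C", "C") != 0,
    )


def retained_topology_indices() -> list:
    """Indices of all topologies that pass :func:`has_io_path` (the screen's
    working set; 16,038 of the 19,683)."""
    return [i for i in range(N_TOPOLOGIES) if has_io_path(from_index(i))]
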