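"""Graph-level necessary conditions for adaptation.

The screening-relevant structure of a signed digraph is carried by its
simple cycles (feedback loops) and its simple input -> output paths
(forward paths), each with a cumulative sign (product of edge signs).
The necessary condition for a topology of any size to adapt perfectly is
the presence of *either*

* an admissible negative feedback loop — cumulative sign -1 and not
  traversing the output -> input edge (a loop closed through that edge can
  never make the input-row/output-column minor vanish while staying
  controllable), or
* an incoherent feed-forward pair — two forward paths of opposite
  cumulative sign.

These are necessary only: parameters must still realize stability and the
zero-minor balance.  Additional cheap exclusions implemented here: an
N-node network (N >= 3) needs at least N edges, and the output must be
reachable from the input at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SignedDigraph

__all__ = [
    "Loop",
    "ForwardPath",
    "StructuralReport",
    "ThreeNodeClosedLoop",
    "find_loops",
    "find_forward_paths",
    "theorem2_edge_check",
    "classify_motif",
    "table1_conditions",
    "decompose_det_3node",
]


@dataclass(frozen=True)
class Loop:
    """A simple directed cycle, canonicalized to start at its smallest node
    (in graph node order); ``sign`` is the product of edge signs."""

    cycle: tuple[str, ...]
    sign: int
    contains_output_to_input_edge: bool

    @property
    def length(self) -> int:
        return len(self.cycle)


@dataclass(frozen=True)
class ForwardPath:
    """A simple directed path from the input node to the output node."""

    path: tuple[str, ...]
    sign: int

    @property
    def n_edges(self) -> int:
        return len(self.path) - 1


@dataclass
class StructuralReport:
    loops: list[Loop]
    forward_paths: list[ForwardPath]
    has_admissible_negative_feedback: bool
    has_incoherent_feedforward: bool
    motif_class: str                    # NFBLB | IFFLP | BOTH | NONE
    edge_count_ok: bool
    input_output_connected: bool
    necessary_condition_met: bool
    excluded: bool = field(init=False)

    def __post_init__(self) -> None:
        # excluded topologies are guaranteed non-adaptive; the complement is
        # only a candidate set (necessity, not sufficiency)
        self.excluded = not (self.necessary_condition_met
                             and self.edge_count_ok
                             and self.input_output_connected)

    def to_dict(self) -> dict:
        return {
            "motif_class": self.motif_class,
            "necessary_condition_met": self.necessary_condition_met,
            "has_admissible_negative_feedback": self.has_admissible_negative_feedback,
            "has_incoherent_feedforward": self.has_incoherent_feedforward,
            "edge_count_ok": self.edge_count_ok,
            "input_output_connected": self.input_output_connected,
            "excluded": self.excluded,
            "loops": [{"cycle": list(l.cycle), "sign": l.sign,
                       "contains_output_to_input_edge": l.contains_output_to_input_edge}
                      for l in self.loops],
            "forward_paths": [{"path": list(p.path), "sign": p.sign}
                              for p in self.forward_paths],
        }


def _canonical_cycle(cycle: tuple[str, ...], order: dict[str, int]) -> tuple[str, ...]:
    k = min(range(len(cycle)), key=lambda i: order[cycle[i]])
    return cycle[k:] + cycle[:k]


def find_loops(g: SignedDigraph) -> list[Loop]:
    """All simple directed cycles (self-loops included), canonical order.

    Intended for small N (<= ~8); cycle counts explode beyond that.
    """
    import networkx as nx

    order = {lab: i for i, lab in enumerate(g.nodes)}
    out, inp = g.output_node, g.input_node
    loops = []
    for cyc in nx.simple_cycles(g.to_networkx()):
        cyc = _canonical_cycle(tuple(cyc), order)
        sign = 1
        contains_oi = False
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            sign *= g.sign(a, b)
            if (a, b) == (out, inp):
                contains_oi = True
        loops.append(Loop(cyc, sign, contains_oi))
    loops.sort(key=lambda l: (l.length, tuple(order[n] for n in l.cycle)))
    return loops


def find_forward_paths(g: SignedDigraph) -> list[ForwardPath]:
    """All simple input -> output paths with cumulative signs.

    When the input and output coincide the trivial zero-edge path is
    returned (sign +1): the input trivially reaches the output.
    """
    import networkx as nx

    order = {lab: i for i, lab in enumerate(g.nodes)}
    if g.input_node == g.output_node:
        return [ForwardPath((g.input_node,), 1)]
    paths = []
    for p in nx.all_simple_paths(g.to_networkx(), g.input_node, g.output_node):
        sign = 1
        for a, b in zip(p, p[1:]):
            sign *= g.sign(a, b)
        paths.append(ForwardPath(tuple(p), sign))
    paths.sort(key=lambda fp: (fp.n_edges, tuple(order[n] for n in fp.path)))
    return paths


def theorem2_edge_check(g: SignedDigraph) -> bool:
    """At least N edges are needed for an N-node network (N >= 3) to adapt;
    vacuously true for N < 3."""
    if g.n_nodes < 3:
        return True
    return g.n_edges >= g.n_nodes


def classify_motif(g: SignedDigraph) -> StructuralReport:
    """Full structural report with the necessary-condition verdict.

    ``necessary_condition_met`` is exactly "admissible negative feedback OR
    incoherent feed-forward"; the aggregate ``excluded`` flag additionally
    requires input->output reachability and the minimum edge count.
    """
    import networkx as nx

    loops = find_loops(g)
    paths = find_forward_paths(g)
    has_nf = any(l.sign < 0 and not l.contains_output_to_input_edge for l in loops)
    signs = {p.sign for p in paths if p.n_edges > 0}
    has_iff = 1 in signs and -1 in signs
    if has_nf and has_iff:
        motif = "BOTH"
    elif has_nf:
        motif = "NFBLB"
    elif has_iff:
        motif = "IFFLP"
    else:
        motif = "NONE"
    connected = (g.input_node == g.output_node) or bool(paths)
    return StructuralReport(
        loops=loops,
        forward_paths=paths,
        has_admissible_negative_feedback=has_nf,
        has_incoherent_feedforward=has_iff,
        motif_class=motif,
        edge_count_ok=theorem2_edge_check(g),
        input_output_connected=connected,
        necessary_condition_met=has_nf or has_iff,
    )


# -- minimal three-node controller algebra -----------------------------------

@dataclass(frozen=True)
class ThreeNodeClosedLoop:
    """Closed loop of a two-node open system (x1 input-facing, x2 output)
    plus one controller node B with linear controller dynamics
    ``udot = alpha_ab x1 + alpha_cb x2 + alpha_bb u``.

    The assembled closed-loop matrix is::

        A_cl = [[a11,      a12,      beta2 ],
                [a21,      a22,      beta3 ],
                [alpha_ab, alpha_cb, alpha_bb]]

    with the external disturbance entering x1 through beta1.
    """

    a11: float
    a12: float
    a21: float
    a22: float
    beta1: float
    beta2: float
    beta3: float
    alpha_ab: float
    alpha_cb: float
    alpha_bb: float

    def a_cl(self) -> np.ndarray:
        return np.array([
            [self.a11, self.a12, self.beta2],
            [self.a21, self.a22, self.beta3],
            [self.alpha_ab, self.alpha_cb, self.alpha_bb],
        ])

    def b_cl(self) -> np.ndarray:
        return np.array([self.beta1, 0.0, 0.0])


def table1_conditions(p: ThreeNodeClosedLoop, tol: float = 0.0) -> dict:
    """Evaluate the minimal-motif sign conditions on the closed loop.

    The steady-state balance for adaptation of x2 is
    ``a21 * alpha_bb - beta3 * alpha_ab = 0``.  Feasible realizations:

    * negative-feedback rows (NFBLB): ``a21 * alpha_cb * beta2 < 0``
      (gross negative feedback through x1), ``alpha_cb * beta3 < 0``
      (negative feedback between controller and output), or
      ``alpha_ab * beta2 < 0`` (negative feedback between input and
      controller);
    * incoherent feed-forward (IFFLP): both products nonzero and equal,
      with the two disturbance -> x2 routes (direct via a21, and via the
      controller, a_ab * beta3) of opposite sign.

    Degenerate scenarios are rejected: all balance terms zero (singular
    closed loop) and a21 = 0 (x2 unobservable from the output path; and
    restoring the balance then needs beta3 = 0 or alpha_ab = 0, losing
    controllability of x2 by the controller or by the disturbance).
    """
    balance = p.a21 * p.alpha_bb - p.beta3 * p.alpha_ab
    all_zero = (p.a21 * p.alpha_bb == 0.0) and (p.beta3 * p.alpha_ab == 0.0) \
        and p.a21 == 0 and p.alpha_bb == 0 and p.beta3 == 0 and p.alpha_ab == 0
    rejected = None
    if all_zero:
        rejected = "all balance terms zero: singular closed loop"
    elif p.a21 == 0.0:
        rejected = "a21 = 0: x2 unobservable / uncontrollable mode"
    incoherent = (
        rejected is None
        and abs(balance) <= tol
        and p.a21 * p.alpha_bb != 0.0
        and p.beta3 * p.alpha_ab != 0.0
        and np.sign(p.a21) != np.sign(p.alpha_ab * p.beta3)
    )
    return {
        "balance": balance,
        "balance_satisfied": abs(balance) <= tol,
        "gross_negative_feedback": p.a21 * p.alpha_cb * p.beta2 < 0,
        "negative_feedback_b_c": p.alpha_cb * p.beta3 < 0,
        "negative_feedback_a_b": p.alpha_ab * p.beta2 < 0,
        "incoherent_feedforward": bool(incoherent),
        "rejected": rejected,
    }


def decompose_det_3node(A: np.ndarray) -> dict:
    """Decompose det(A) of a 3-node Jacobian into elementary-topology terms.

    For input node 1 and output node 3 the determinant splits into four
    three-edge elementary-topology determinants::

        L1 = -a12 a21 a33   (2-loop between nodes 1 and 2, diagonal 3)
        L2 = -a11 a23 a32   (2-loop between nodes 2 and 3, diagonal 1)
        L3 = +a12 a23 a31   (3-loop 1 -> 3 -> 2 -> 1)
        L4 = +a11 a22 a33   (pure feed-forward: diagonals only)

    ``L1 + L2 + L3 + L4 = det A`` whenever ``a13 = 0`` (no output -> input
    edge).  A nonzero ``a13`` contributes the two extra cofactor terms
    ``a13 (a21 a32 - a22 a31)``, reported as ``residual`` so the identity
    always closes: ``L1 + L2 + L3 + L4 + residual = det A``.  A negative
    L1, L2 or L3 indicates negative feedback; L4 as the sole negative term
    indicates an incoherent feed-forward route to stability.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape != (3, 3):
        raise ValueError("decompose_det_3node requires a 3x3 matrix")
    L1 = float(np.linalg.det(np.array([[A[0, 0], A[0, 1], 0], [A[1, 0], 0, 0], [A[2, 0], 0, A[2, 2]]])))
    L2 = float(np.linalg.det(np.array([[A[0, 0], 0, 0], [0, 0, A[1, 2]], [A[2, 0], A[2, 1], A[2, 2]]])))
    L3 = float(np.linalg.det(np.array([[A[0, 0], A[0, 1], 0], [0, 0, A[1, 2]], [A[2, 0], 0, A[2, 2]]])))
    L4 = float(np.linalg.det(np.array([[A[0, 0], 0, 0], [A[1, 0], A[1, 1], 0], [A[2, 0], A[2, 1], A[2, 2]]])))
    det = float(np.linalg.det(A))
    residual = A[0, 2] * (A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0])
    return {
        "L1": L1, "L2": L2, "L3": L3, "L4": L4,
        "residual": float(residual),
        "det": det,
        "negative_terms": [name for name, v in
                           (("L1", L1), ("L2", L2), ("L3", L3), ("L4", L4)) if v < 0],
        "feedback_attribution": any(v < 0 for v in (L1, L2, L3)),
        "feedforward_attribution": L4 < 0,
    }
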