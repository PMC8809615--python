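"""Canonical reference networks with frozen kinetic parameters.

These fixtures reproduce the qualitative behavior classes used throughout
the test suite: two-node integral feedback (adaptation at every staircase
plateau), a two-node bounded-buffer ("conservation-law") network that
adapts exactly once, the minimal three-node incoherent feed-forward
(IFFLP) and negative-feedback-with-buffer (NFBLB) motifs (oscillatory and
hyperbolic parameter variants), their combination, five-node counterparts,
and downstream-augmented variants of each adaptive motif.

Parameter choices follow two standard operating regimes:

* *proportioner* nodes (IFFLP): activation saturated (small K on the
  incoming edge) and basal deactivation far from saturation (large basal
  K), so the node's steady level is proportional to its driver — the two
  forward paths then cancel exactly at steady state;
* *buffer* nodes (NFBLB): both the incoming activation and the basal
  deactivation saturated (small K), so the node integrates its driver's
  deviation from a set point (zero-order ultrasensitivity), pinning the
  output's steady state.

All reference parameters are frozen synthetic choices made to land every
node near mid-range (~0.5) at the reference disturbance level d = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kinetics import (BasalParams, EdgeParams, KineticParameters, RateField,
                       build_rate_field)
from .network import SignedDigraph

__all__ = ["Fixture", "builtin_fixtures", "get_fixture", "fixture_names"]


@dataclass(frozen=True)
class Fixture:
    """A named reference network plus frozen parameters and dynamics."""

    name: str
    graph: SignedDigraph
    params: KineticParameters | None
    flavor: str                       # mm_variant | linear | custom
    description: str
    behavior: str                     # expected qualitative class
    _field_builder: Callable[["Fixture"], RateField] | None = None

    def rate_field(self) -> RateField:
        if self._field_builder is not None:
            return self._field_builder(self)
        return build_rate_field(self.graph, self.params, self.flavor)


def _mm_edges(**kw: tuple[float, float]) -> dict[tuple[str, str], EdgeParams]:
    return {tuple(k.split("__")): EdgeParams(*v) for k, v in kw.items()}


# -- bespoke two-node dynamics ------------------------------------------------

def _integral_field(fx: Fixture) -> RateField:
    """x1' = d - x1 - x2,  x2' = x1 - r.

    x2 integrates the output's deviation from the set point r, so x1 adapts
    perfectly to every step; the zero diagonal of the integrator forces the
    DC gain to zero at any operating point.
    """
    r = 0.2

    def f(x: np.ndarray, d: float) -> np.ndarray:
        return np.array([d - x[0] - x[1], x[0] - r])

    return RateField(fx.graph, "custom", f,
                     jacobian=lambda x, d: np.array([[-1.0, -1.0], [1.0, 0.0]]),
                     dfdd=lambda x, d: np.array([1.0, 0.0]))


def _conservation_field(fx: Fixture) -> RateField:
    """Integral feedback through a *bounded* buffer pool.

    x1' = d - x1 - x2,  x2' = k (x1 - r) x2 (M - x2): the buffer x2 is one
    form of a conserved pool of total size M (active + inactive = M), so the
    integral action works only while x2 is interior.  Once a step drives the
    required buffer level past M, x2 saturates at the pool boundary, the
    coupling x1 -> x2 vanishes (A[2][1] = k x2 (M - x2) = 0) and the
    linearized model loses controllability: the network adapts to the first
    step and fails afterwards (toilet flush).
    """
    r, m, k = 0.2, 0.5, 8.0

    def f(x: np.ndarray, d: float) -> np.ndarray:
        return np.array([d - x[0] - x[1], k * (x[0] - r) * x[1] * (m - x[1])])

    def jac(x: np.ndarray, d: float) -> np.ndarray:
        return np.array([
            [-1.0, -1.0],
            [k * x[1] * (m - x[1]), k * (x[0] - r) * (m - 2 * x[1])],
        ])

    return RateField(fx.graph, "custom", f, jacobian=jac,
                     dfdd=lambda x, d: np.array([1.0, 0.0]))


# -- fixture table ------------------------------------------------------------

def _build() -> dict[str, Fixture]:
    fx: dict[str, Fixture] = {}

    def add(name: str, nodes, edges, inp, out, params, flavor, desc, behavior,
            builder=None) -> None:
        g = SignedDigraph(tuple(nodes), edges, inp, out)
        fx[name] = Fixture(name, g, params, flavor, desc, behavior, builder)

    # two-node, input = output (the only adaptive two-node configuration)
    add("twonode_integral", ("x1", "x2"),
        {("x1", "x1"): -1, ("x2", "x1"): -1, ("x1", "x2"): 1},
        "x1", "x1", None, "custom",
        "two-node integral feedback; adapts at every staircase plateau", "PA",
        _integral_field)
    add("twonode_conservation", ("x1", "x2"),
        {("x1", "x1"): -1, ("x2", "x1"): -1, ("x1", "x2"): 1},
        "x1", "x1", None, "custom",
        "two-node integral feedback through a bounded (conserved) buffer "
        "pool; adapts once, then loses controllability", "PA_ONCE",
        _conservation_field)

    # shared input-node regime: the disturbance enzyme is saturated and the
    # basal deactivation operates far below saturation, so A* tracks d
    # proportionally (A* = d at the reference level 0.5)
    dist = EdgeParams(k=0.5, K=1e-6)

    def prop(rate: float) -> BasalParams:
        # deactivating enzyme in its linear regime with effective rate `rate`
        return BasalParams(k=rate * 2.0 * 2000.0, K=2000.0)

    a_basal = {"A": prop(0.5)}

    # minimal three-node IFFLP: A -> B -> C(-), A -> C(+).  The proportioner
    # B has saturated activation and linear deactivation, so B* tracks A and
    # the two forward paths cancel at steady state (to ~0.03%).
    add("ifflp3", "ABC",
        {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): -1},
        "A", "C",
        KineticParameters(
            edges=_mm_edges(A__B=(0.1, 1e-6), A__C=(2.0, 0.1), B__C=(2.0, 0.1)),
            disturbance=dist,
            basal={**a_basal, "B": prop(0.1)},
        ),
        "mm_variant",
        "minimal incoherent feed-forward loop with proportioner node B",
        "adaptive_hyperbolic")

    # minimal three-node NFBLB: A -> C, C -> B, B -| C.  The buffer B runs in
    # deep zero-order saturation on both sides (tiny K), integrating C's
    # deviation from the set point 0.5.
    def nfblb3(k_loop: float) -> KineticParameters:
        return KineticParameters(
            edges=_mm_edges(A__C=(2.0, 0.1), C__B=(k_loop, 1e-6),
                            B__C=(2.0, 0.1)),
            disturbance=dist,
            basal={**a_basal, "B": BasalParams(k=k_loop, K=1e-6)},
        )

    add("nfblb3_bc", "ABC",
        {("A", "C"): 1, ("C", "B"): 1, ("B", "C"): -1},
        "A", "C", nfblb3(0.03), "mm_variant",
        "negative feedback between buffer B and output C; damped-real "
        "(hyperbolic) parameter variant", "adaptive_hyperbolic")
    add("nfblb3_bc_osc", "ABC",
        {("A", "C"): 1, ("C", "B"): 1, ("B", "C"): -1},
        "A", "C", nfblb3(0.2), "mm_variant",
        "negative feedback between buffer B and output C; oscillatory "
        "parameter variant (complex eigenvalues)", "adaptive_oscillatory")

    # combined motif: IFFLP plus a negative (self-)feedback on the proportioner
    add("iffl_nfb3", "ABC",
        {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): -1, ("B", "B"): -1},
        "A", "C",
        KineticParameters(
            edges=_mm_edges(A__B=(0.1, 1e-6), B__B=(0.1, 1e-4),
                            A__C=(2.0, 0.1), B__C=(2.0, 0.1)),
            disturbance=dist,
            basal=dict(a_basal),
        ),
        "mm_variant",
        "incoherent feed-forward plus negative feedback in one network",
        "adaptive_hyperbolic")

    # non-adaptive control: coherent feed-forward
    add("coherent_ff3", "ABC",
        {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1},
        "A", "C",
        KineticParameters(
            edges=_mm_edges(A__B=(0.1, 1e-6), B__C=(2.0, 0.1), A__C=(2.0, 0.1)),
            disturbance=dist,
            basal={**a_basal, "B": prop(0.1), "C": BasalParams(k=10.0, K=1.0)},
        ),
        "mm_variant",
        "coherent feed-forward control network; responds but never adapts",
        "non_adaptive")

    # five-node IFFLP: A -> C -> E(+ +) against A -> B -> D -> E(+ + -);
    # the repressive arm is slower, giving a clear transient before the
    # steady-state cancellation
    add("ifflp5", "ABCDE",
        {("A", "C"): 1, ("C", "E"): 1, ("A", "B"): 1, ("B", "D"): 1,
         ("D", "E"): -1},
        "A", "E",
        KineticParameters(
            edges=_mm_edges(A__C=(0.3, 1e-6), C__E=(2.0, 0.1),
                            A__B=(0.5, 1e-6), B__D=(0.1, 1e-6), D__E=(2.0, 0.1)),
            disturbance=dist,
            basal={**a_basal, "B": prop(0.5), "C": prop(0.3), "D": prop(0.1)},
        ),
        "mm_variant",
        "five-node incoherent feed-forward network (proportioner chain)",
        "adaptive_hyperbolic")

    # five-node NFBLB: chain A -> B -> C -> E with zero-order buffer D
    add("nfblb5", "ABCDE",
        {("A", "B"): 1, ("B", "C"): 1, ("C", "E"): 1, ("E", "D"): 1,
         ("D", "E"): -1},
        "A", "E",
        KineticParameters(
            edges=_mm_edges(A__B=(0.5, 1e-6), B__C=(0.4, 1e-6),
                            C__E=(2.0, 0.1), E__D=(0.05, 1e-6), D__E=(2.0, 0.1)),
            disturbance=dist,
            basal={**a_basal, "B": prop(0.5), "C": prop(0.4),
                   "D": BasalParams(k=0.05, K=1e-6)},
        ),
        "mm_variant",
        "five-node negative feedback with buffer D on the output node",
        "adaptive_oscillatory")

    # downstream-augmented variants: the upstream output node is coupled in
    # feedback with one downstream node Z (canonical coupling).  NFBLB
    # upstreams tolerate a plain enzymatic load; IFFLP upstreams get an
    # integrating downstream node whose set point sits below the upstream
    # one, which keeps the combined operating point pinned and makes the
    # output <-> Z negative loop visibly oscillatory.
    def with_downstream(base: str, name: str, desc: str, behavior: str,
                        z_zero_order: bool, k_feedback: float) -> None:
        b = fx[base]
        out = b.graph.output_node
        edges = dict(b.graph.edges)
        edges[(out, "Z")] = 1
        edges[("Z", out)] = -1
        theta = b.params
        new_edges = dict(theta.edges)
        if z_zero_order:
            new_edges[(out, "Z")] = EdgeParams(1.0, 1e-6)
            new_edges[("Z", out)] = EdgeParams(k_feedback, 1.0)
            basal_z = BasalParams(k=0.8, K=1e-6)
        else:
            new_edges[(out, "Z")] = EdgeParams(1.0, 1.0)
            new_edges[("Z", out)] = EdgeParams(k_feedback, 1.0)
            basal_z = BasalParams(k=1.0, K=1.0)
        theta = KineticParameters(new_edges, theta.disturbance,
                                  {**theta.basal, "Z": basal_z}, theta.beta,
                                  theta.decay)
        add(name, b.graph.nodes + ("Z",), edges, b.graph.input_node, out,
            theta, "mm_variant", desc, behavior)

    with_downstream("nfblb3_bc_osc", "nfblb3_bc_down",
                    "three-node NFBLB with a downstream node coupled in "
                    "feedback to the output", "adaptive_oscillatory", False, 0.5)
    with_downstream("ifflp3", "ifflp3_down",
                    "three-node IFFLP with an integrating downstream node in "
                    "feedback with the output; oscillatory transient",
                    "adaptive_oscillatory", True, 1.0)
    with_downstream("nfblb5", "nfblb5_down",
                    "five-node NFBLB with downstream feedback node",
                    "adaptive_oscillatory", False, 0.5)
    with_downstream("ifflp5", "ifflp5_down",
                    "five-node IFFLP with an integrating downstream node",
                    "adaptive_oscillatory", True, 0.6)

    return fx


_FIXTURES: dict[str, Fixture] | None = None


def builtin_fixtures() -> dict[str, Fixture]:
    """All named reference networks (built once, cached)."""
    global _FIXTURES
    if _FIXTURES is None:
        _FIXTURES = _build()
    return _FIXTURES


def fixture_names() -> list[str]:
    return sorted(builtin_fixtures())


def get_fixture(name: str) -> Fixture:
    try:
        return builtin_fixtures()[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(fixture_names())}") from None
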