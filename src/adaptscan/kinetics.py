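"""Rate fields on signed networks: Michaelis-Menten-variant and linear
dynamics, steady-state location, and linearization to a state-space model.

States are normalized protein concentrations, one per node, living in the
box [0, 1]^N for the enzymatic flavor.  Each edge ``j -> i`` contributes an
additive rate term that is class K in x_j (zero at x_j = 0, strictly
monotone with the edge's sign), and every term is Lipschitz on the closed
state box, so the Jacobian at an interior steady state reproduces the
graph's sign pattern exactly.

The enzymatic (``mm_variant``) flavor uses activation/deactivation
Michaelis-Menten terms: an activator j of node i converts inactive protein
(1 - x_i) at rate ``k * x_j * (1 - x_i) / ((1 - x_i) + K)`` and a repressor
deactivates at rate ``k * x_j * x_i / (x_i + K)``.  The external disturbance
d acts as one more activating enzyme on the input node.  Nodes lacking a
repressor receive a basal deactivating enzyme at a fixed level (default
0.5), and nodes lacking both an activator and the disturbance receive a
basal activating enzyme, so every state has turnover in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import json
import numpy as np

from .network import SignedDigraph

__all__ = [
    "EdgeParams",
    "BasalParams",
    "KineticParameters",
    "RateField",
    "SteadyStateResult",
    "SteadyStateError",
    "build_rate_field",
    "find_steady_state",
    "linearize",
    "parse_parameters",
    "write_parameters",
]

BASAL_ENZYME_LEVEL = 0.5  # fixed concentration of basal (de)activating enzymes


@dataclass(frozen=True)
class EdgeParams:
    """Catalytic rate and Michaelis constant of one enzymatic interaction."""

    k: float = 1.0
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.K <= 0:
            raise ValueError("rate constants must be strictly positive")


@dataclass(frozen=True)
class BasalParams:
    """Basal enzyme acting on a node (level fixed by convention)."""

    k: float = 1.0
    K: float = 1.0
    level: float = BASAL_ENZYME_LEVEL

    def __post_init__(self) -> None:
        if self.k <= 0 or self.K <= 0 or self.level <= 0:
            raise ValueError("basal parameters must be strictly positive")


@dataclass(frozen=True)
class KineticParameters:
    """Full parameterization of a rate field on a signed digraph.

    ``edges`` maps ``(source, target)`` to :class:`EdgeParams`;
    ``disturbance`` parameterizes the external input acting on the input
    node; ``basal`` holds per-node overrides for the basal enzymes
    (defaults applied where a node needs one); ``beta`` gives linear-flavor
    disturbance couplings (defaults to 1 on the input node).
    """

    edges: dict[tuple[str, str], EdgeParams] = field(default_factory=dict)
    disturbance: EdgeParams = field(default_factory=EdgeParams)
    basal: dict[str, BasalParams] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    decay: dict[str, float] = field(default_factory=dict)  # linear flavor

    def edge(self, source: str, target: str) -> EdgeParams:
        try:
            return self.edges[(source, target)]
        except KeyError:
            raise KeyError(f"missing kinetic parameters for edge {source} -> {target}") from None

    def basal_for(self, node: str) -> BasalParams:
        return self.basal.get(node, BasalParams())

    def with_edge(self, source: str, target: str, k: float, K: float) -> "KineticParameters":
        edges = dict(self.edges)
        edges[(source, target)] = EdgeParams(k, K)
        return replace(self, edges=edges)


@dataclass
class RateField:
    """Evaluator of the vector field ``xdot = f(x, d)`` on a network.

    ``flavor`` is ``"mm_variant"``, ``"linear"`` or ``"custom"`` (bespoke
    fixture dynamics).  ``jacobian`` returns the analytic state Jacobian and
    ``dfdd`` the disturbance derivative; both are used by the root finder
    and available as a fast alternative to finite differences.
    """

    graph: SignedDigraph
    flavor: str
    f: Callable[[np.ndarray, float], np.ndarray]
    jacobian: Callable[[np.ndarray, float], np.ndarray] | None = None
    dfdd: Callable[[np.ndarray, float], np.ndarray] | None = None
    params: KineticParameters | None = None

    @property
    def dim(self) -> int:
        return self.graph.n_nodes

    def __call__(self, x: np.ndarray, d: float) -> np.ndarray:
        return self.f(np.asarray(x, dtype=float), float(d))


@dataclass(frozen=True)
class SteadyStateResult:
    x: np.ndarray
    d0: float
    residual: float
    converged: bool
    multiplicity_note: str = ""
    on_boundary: bool = False


class SteadyStateError(RuntimeError):
    """No steady state found from any start."""


# -- rate-field construction ----------------------------------------------

def _mm_act(x_t: np.ndarray | float, K: float):
    """Saturating activation factor (1 - x)/((1 - x) + K)."""
    u = 1.0 - x_t
    return u / (u + K)


def _mm_rep(x_t: np.ndarray | float, K: float):
    """Saturating deactivation factor x/(x + K)."""
    return x_t / (x_t + K)


def build_rate_field(g: SignedDigraph, theta: KineticParameters,
                     flavor: str = "mm_variant") -> RateField:
    """Build the nonlinear enzymatic or the linear rate field on ``g``.

    Raises ``KeyError`` if ``theta`` misses parameters for an edge of ``g``.
    """
    if flavor == "mm_variant":
        return _build_mm(g, theta)
    if flavor == "linear":
        return _build_linear(g, theta)
    raise ValueError(f"unknown flavor {flavor!r}")


def _build_mm(g: SignedDigraph, theta: KineticParameters) -> RateField:
    n = g.n_nodes
    idx = {lab: i for i, lab in enumerate(g.nodes)}
    in_idx = g.input_index

    # Per-node term lists: (source index, k, K, sign).  Basal enzymes use a
    # pseudo-source index of -1 with a fixed level.
    act_terms: list[list[tuple[int, float, float]]] = [[] for _ in range(n)]
    rep_terms: list[list[tuple[int, float, float]]] = [[] for _ in range(n)]
    basal_act = np.zeros(n)
    basal_act_K = np.ones(n)
    basal_rep = np.zeros(n)
    basal_rep_K = np.ones(n)
    for t_lab in g.nodes:
        i = idx[t_lab]
        for s_lab, sg in g.predecessors(t_lab):
            ep = theta.edge(s_lab, t_lab)
            (act_terms if sg > 0 else rep_terms)[i].append((idx[s_lab], ep.k, ep.K))
        has_act = bool(g.activators(t_lab)) or i == in_idx
        has_rep = bool(g.repressors(t_lab))
        bp = theta.basal_for(t_lab)
        if not has_rep:
            basal_rep[i] = bp.k * bp.level
            basal_rep_K[i] = bp.K
        if not has_act:
            basal_act[i] = bp.k * bp.level
            basal_act_K[i] = bp.K
    dk, dK = theta.disturbance.k, theta.disturbance.K

    def f(x: np.ndarray, d: float) -> np.ndarray:
        out = np.zeros(n)
        for i in range(n):
            tot = 0.0
            for j, k, K in act_terms[i]:
                tot += k * x[j] * _mm_act(x[i], K)
            for j, k, K in rep_terms[i]:
                tot -= k * x[j] * _mm_rep(x[i], K)
            if basal_act[i]:
                tot += basal_act[i] * _mm_act(x[i], basal_act_K[i])
            if basal_rep[i]:
                tot -= basal_rep[i] * _mm_rep(x[i], basal_rep_K[i])
            if i == in_idx:
                tot += dk * d * _mm_act(x[i], dK)
            out[i] = tot
        return out

    def jac(x: np.ndarray, d: float) -> np.ndarray:
        A = np.zeros((n, n))
        for i in range(n):
            xi = x[i]
            for j, k, K in act_terms[i]:
                # d/dx_j and d/dx_i of k x_j (1-x_i)/((1-x_i)+K)
                A[i, j] += k * _mm_act(xi, K)
                A[i, i] += -k * x[j] * K / ((1.0 - xi) + K) ** 2
            for j, k, K in rep_terms[i]:
                A[i, j] -= k * _mm_rep(xi, K)
                A[i, i] -= k * x[j] * K / (xi + K) ** 2
            if basal_act[i]:
                A[i, i] += -basal_act[i] * basal_act_K[i] / ((1.0 - xi) + basal_act_K[i]) ** 2
            if basal_rep[i]:
                A[i, i] -= basal_rep[i] * basal_rep_K[i] / (xi + basal_rep_K[i]) ** 2
            if i == in_idx:
                A[i, i] += -dk * d * dK / ((1.0 - xi) + dK) ** 2
        return A

    def dfdd(x: np.ndarray, d: float) -> np.ndarray:
        b = np.zeros(n)
        b[in_idx] = dk * _mm_act(x[in_idx], dK)
        return b

    return RateField(g, "mm_variant", f, jac, dfdd, theta)


def _build_linear(g: SignedDigraph, theta: KineticParameters) -> RateField:
    """Linear flavor: xdot = A x + B d with A signed by the graph.

    Off-diagonal A[i][j] = sign(j->i) * k(j->i).  Diagonals: the self-edge's
    signed rate when present, otherwise a first-order decay (default 1,
    overridable per node via ``theta.decay``).  B has ``theta.beta`` on the
    input node (default 1).
    """
    n = g.n_nodes
    idx = {lab: i for i, lab in enumerate(g.nodes)}
    A = np.zeros((n, n))
    for (s, t), sg in g.edges.items():
        A[idx[t], idx[s]] += sg * theta.edge(s, t).k
    for lab in g.nodes:
        if (lab, lab) not in g.edges:
            A[idx[lab], idx[lab]] -= theta.decay.get(lab, 1.0)
    B = np.zeros(n)
    for lab, b in (theta.beta or {g.input_node: 1.0}).items():
        B[idx[lab]] = b

    def f(x: np.ndarray, d: float) -> np.ndarray:
        return A @ x + B * d

    return RateField(g, "linear", f, lambda x, d: A.copy(), lambda x, d: B.copy(), theta)


# -- steady state ----------------------------------------------------------

def _start_grid(n: int, n_starts: int | None, seed: int = 0) -> np.ndarray:
    """Deterministic start points: the 3^N grid over {0.25, 0.5, 0.75}^N for
    N <= 4, else seeded Latin-hypercube starts (default 50)."""
    if n <= 4 and n_starts is None:
        grids = np.meshgrid(*([np.array([0.25, 0.5, 0.75])] * n), indexing="ij")
        pts = np.stack([a.ravel() for a in grids], axis=1)
        center_first = np.argsort(np.abs(pts - 0.5).sum(axis=1), kind="stable")
        return pts[center_first]
    m = n_starts or 50
    from scipy.stats import qmc

    sampler = qmc.LatinHypercube(d=n, seed=seed)
    return 0.1 + 0.8 * sampler.random(m)


def find_steady_state(field: RateField, d0: float, n_starts: int | None = None,
                      tol: float = 1e-10, first_only: bool = False) -> SteadyStateResult:
    """Locate a root of ``f(., d0)`` from a deterministic grid of starts.

    Uses scipy's damped hybrid (Powell) iteration with the field's analytic
    Jacobian when available.  Distinct roots are reported in the
    multiplicity note; ``first_only`` stops at the first converged root
    (used by high-throughput screening).
    """
    from scipy.optimize import root

    roots: list[np.ndarray] = []
    box = field.flavor == "mm_variant"
    if box:
        # the enzymatic field has poles just outside the state box (x = -K,
        # x = 1 + K); solve a clamped surrogate whose roots coincide with the
        # in-box roots and whose out-of-box extension pulls back linearly
        def fun(x: np.ndarray) -> np.ndarray:
            xc = np.clip(x, 0.0, 1.0)
            return field.f(xc, d0) - (x - xc)

        def jac_fun(x: np.ndarray) -> np.ndarray:
            xc = np.clip(x, 0.0, 1.0)
            J = field.jacobian(xc, d0).copy()
            outside = (x < 0.0) | (x > 1.0)
            J[:, outside] = 0.0
            J[outside, outside] = -1.0
            return J

        jac = jac_fun if field.jacobian is not None else None
    else:
        fun = lambda x: field.f(x, d0)
        jac = (lambda x: field.jacobian(x, d0)) if field.jacobian is not None else None
    for x0 in _start_grid(field.dim, n_starts):
        sol = root(fun, x0, jac=jac, method="hybr", tol=1e-12)
        x = sol.x
        if box:
            x = np.clip(x, 0.0, 1.0)
        res = float(np.max(np.abs(field.f(x, d0))))
        if res <= tol:
            if not any(np.allclose(x, r, atol=1e-7) for r in roots):
                roots.append(x)
            if first_only:
                break
    if not roots:
        raise SteadyStateError(f"no steady state found at d0={d0} (tol={tol})")
    # prefer dynamically reachable roots: stable first, then interior ones
    def preference(x: np.ndarray) -> tuple:
        stable = True
        if field.jacobian is not None:
            stable = bool(np.max(np.linalg.eigvals(field.jacobian(x, d0)).real) < 0)
        interior = float(np.min(np.minimum(x, 1.0 - x))) if box else 0.0
        return (stable, interior)

    roots.sort(key=preference, reverse=True)
    x_best = roots[0]
    note = "" if len(roots) == 1 else f"{len(roots)} distinct steady states found"
    on_boundary = box and bool(np.any((x_best < 1e-9) | (x_best > 1 - 1e-9)))
    return SteadyStateResult(x_best, float(d0), float(np.max(np.abs(field.f(x_best, d0)))),
                             True, note, on_boundary)


# -- linearization ---------------------------------------------------------

def linearize(field: RateField, x_star: np.ndarray, d0: float,
              residual_tol: float = 1e-8, method: str = "fd"):
    """Linearize the rate field at a steady state into a StateSpace.

    ``A`` and ``B`` are central finite-difference Jacobians (step scaled to
    the state magnitude); states on the box boundary fall back to one-sided
    differences and the result is flagged.  ``C`` selects the output node
    and ``D = 0`` (the output has no direct feedthrough).  ``method
    ="analytic"`` uses the field's analytic Jacobian instead.
    """
    from .linear import StateSpace

    x_star = np.asarray(x_star, dtype=float)
    res = float(np.max(np.abs(field.f(x_star, d0))))
    if res > residual_tol:
        raise ValueError(f"x* is not a steady state (residual {res:.3e} > {residual_tol:.1e})")
    n = field.dim
    box = field.flavor == "mm_variant"
    boundary_flag = False
    if method == "analytic" and field.jacobian is not None:
        A = field.jacobian(x_star, d0)
        B = field.dfdd(x_star, d0)
    else:
        A = np.zeros((n, n))
        for j in range(n):
            h = 1e-6 * max(abs(x_star[j]), 1e-3)
            lo_ok = (not box) or (x_star[j] - h >= 0.0)
            hi_ok = (not box) or (x_star[j] + h <= 1.0)
            xp, xm = x_star.copy(), x_star.copy()
            if lo_ok and hi_ok:
                xp[j] += h
                xm[j] -= h
                A[:, j] = (field.f(xp, d0) - field.f(xm, d0)) / (2 * h)
            else:
                boundary_flag = True
                if hi_ok:
                    xp[j] += h
                    A[:, j] = (field.f(xp, d0) - field.f(x_star, d0)) / h
                else:
                    xm[j] -= h
                    A[:, j] = (field.f(x_star, d0) - field.f(xm, d0)) / h
        hd = 1e-6 * max(abs(d0), 1e-3)
        B = (field.f(x_star, d0 + hd) - field.f(x_star, d0 - hd)) / (2 * hd)
    C = np.zeros(n)
    C[field.graph.output_index] = 1.0
    return StateSpace(A=np.asarray(A), B=np.asarray(B), C=C, D=0.0,
                      node_index_map={lab: i for i, lab in enumerate(field.graph.nodes)},
                      boundary_linearization=boundary_flag)


# -- parameter file I/O -----------------------------------------------------

def parse_parameters(text: str) -> KineticParameters:
    """Parse the JSON parameter dialect.

    Keys containing ``->`` are edges (``"d-><node>"`` parameterizes the
    disturbance); ``"basal"`` maps node -> {k, K, level}; ``"beta"`` maps
    node -> linear disturbance coupling; ``"decay"`` maps node -> linear
    decay rate.
    """
    doc = json.loads(text)
    edges: dict[tuple[str, str], EdgeParams] = {}
    disturbance = EdgeParams()
    basal: dict[str, BasalParams] = {}
    beta: dict[str, float] = {}
    decay: dict[str, float] = {}
    for key, val in doc.items():
        if "->" in key:
            s, t = (p.strip() for p in key.split("->", 1))
            ep = EdgeParams(float(val.get("k", 1.0)), float(val.get("K", 1.0)))
            if s == "d":
                disturbance = ep
            else:
                edges[(s, t)] = ep
        elif key == "basal":
            for node, rec in val.items():
                basal[node] = BasalParams(float(rec.get("k", 1.0)), float(rec.get("K", 1.0)),
                                          float(rec.get("level", BASAL_ENZYME_LEVEL)))
        elif key == "beta":
            beta = {node: float(v) for node, v in val.items()}
        elif key == "decay":
            decay = {node: float(v) for node, v in val.items()}
        else:
            raise ValueError(f"unknown parameter key {key!r}")
    return KineticParameters(edges, disturbance, basal, beta, decay)


def write_parameters(theta: KineticParameters) -> str:
    doc: dict = {f"{s}->{t}": {"k": ep.k, "K": ep.K} for (s, t), ep in theta.edges.items()}
    doc["d->input"] = {"k": theta.disturbance.k, "K": theta.disturbance.K}
    if theta.basal:
        doc["basal"] = {n: {"k": b.k, "K": b.K, "level": b.level} for n, b in theta.basal.items()}
    if theta.beta:
        doc["beta"] = dict(theta.beta)
    if theta.decay:
        doc["decay"] = dict(theta.decay)
    return json.dumps(doc, indent=2) + "\n"
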