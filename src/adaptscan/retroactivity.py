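"""Downstream coupling and modularity of adaptive networks.

An adaptive module is *modular* (non-retroactive) when coupling its output
node to a downstream system — in feedback, but only through the output
node — preserves adaptation.  The combined Jacobian has block form::

    A' = [[A1, E1],
          [E,  A2]]

where ``E1`` (upstream rows x downstream columns) is nonzero only in the
output node's row and ``E`` (downstream rows x upstream columns) only in
the output node's column.  Deleting the input row and output column of
``A'`` then leaves a block-triangular matrix, so

    minor(A') = det(~A1) * det(A2)

with ``~A1`` the upstream minor.  An adaptive upstream (``det(~A1) = 0``)
therefore keeps a vanishing combined minor; adaptation survives as long as
the combined system stays stable (the lemma's proviso).  Coupling any
*non-output* upstream node breaks the block shape and, in general, the
adaptation property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import KineticParameters, RateField, build_rate_field, find_steady_state, linearize
from .linear import FD_ZERO_TOL, adaptation_verdict, is_hurwitz, minor_condition
from .network import NetworkValidationError, SignedDigraph
from .response import DEFAULT_S_MIN, PERFECT_P, step_metrics

__all__ = ["AugmentedNetwork", "augment_downstream", "combined_minor_identity",
           "verify_modularity"]


@dataclass
class AugmentedNetwork:
    """Upstream + downstream graphs joined by canonical output-node coupling."""

    upstream: SignedDigraph
    downstream: SignedDigraph
    couplings: dict[tuple[str, str], int]
    combined: SignedDigraph

    @property
    def n_upstream(self) -> int:
        return self.upstream.n_nodes

    @property
    def n_downstream(self) -> int:
        return self.downstream.n_nodes

    def blocks(self, A: np.ndarray) -> dict[str, np.ndarray]:
        """Split a combined Jacobian into the A1 / A2 / E / E1 blocks."""
        n = self.n_upstream
        return {"A1": A[:n, :n], "E1": A[:n, n:], "E": A[n:, :n], "A2": A[n:, n:]}


def augment_downstream(up: SignedDigraph, down: SignedDigraph | None,
                       couplings: dict[tuple[str, str], int]) -> AugmentedNetwork:
    """Join a downstream system to the upstream output node.

    ``couplings`` maps ``(source, target) -> sign``; every coupling edge must
    touch the upstream output node on its upstream side (both directions
    allowed — that is the feedback fashion).  An empty downstream returns the
    upstream unchanged inside the wrapper.  Couplings to non-output upstream
    nodes are rejected: they void the block shape the modularity argument
    rests on.
    """
    if down is None or down.n_nodes == 0:
        if couplings:
            raise NetworkValidationError("couplings given but no downstream system")
        empty = SignedDigraph((), {}, "", "")
        return AugmentedNetwork(up, empty, {}, up)
    overlap = set(up.nodes) & set(down.nodes)
    if overlap:
        raise NetworkValidationError(f"node labels shared across modules: {sorted(overlap)}")
    out = up.output_node
    up_nodes, down_nodes = set(up.nodes), set(down.nodes)
    for (s, t), sign in couplings.items():
        up_side = s if s in up_nodes else t if t in up_nodes else None
        if up_side is None or (s in up_nodes and t in up_nodes):
            raise NetworkValidationError(f"coupling ({s}, {t}) must join the two modules")
        if up_side != out:
            raise NetworkValidationError(
                f"non-canonical coupling ({s} -> {t}): upstream side must be "
                f"the output node {out!r}")
        if sign not in (1, -1):
            raise NetworkValidationError(f"coupling ({s}, {t}) has invalid sign {sign!r}")
    edges = dict(up.edges)
    edges.update(down.edges)
    edges.update(couplings)
    combined = SignedDigraph(up.nodes + down.nodes, edges, up.input_node, out)
    return AugmentedNetwork(up, down, dict(couplings), combined)


def combined_minor_identity(an: AugmentedNetwork, A_combined: np.ndarray,
                            rtol: float = 1e-8) -> dict:
    """Check minor(A') = +/- det(~A1) det(A2) on a combined Jacobian."""
    n = an.n_upstream
    in_idx = an.combined.input_index
    out_idx = an.combined.output_index
    minor, _ = minor_condition(A_combined, in_idx, out_idx, tol=rtol)
    blocks = an.blocks(np.asarray(A_combined, dtype=float))
    up_minor, _ = minor_condition(blocks["A1"], an.upstream.input_index,
                                  an.upstream.output_index, tol=rtol)
    det_a2 = float(np.linalg.det(blocks["A2"])) if an.n_downstream else 1.0
    product = up_minor * det_a2
    scale = max(abs(minor), abs(product), 1.0)
    return {
        "minor_combined": minor,
        "minor_upstream": up_minor,
        "det_downstream": det_a2,
        "identity_holds": bool(min(abs(minor - product), abs(minor + product))
                               <= rtol * scale),
    }


def verify_modularity(an: AugmentedNetwork, theta: KineticParameters | None = None,
                      field: RateField | None = None, d0: float = 0.5, d1: float = 0.6,
                      p_threshold: float = PERFECT_P, simulate: bool = True) -> dict:
    """Verify that canonical downstream coupling preserves adaptation.

    Three layers: (i) the block-determinant identity and the vanishing of the
    combined minor, (ii) stability of the combined Jacobian (the proviso —
    reported as ``modularity_proviso_violated`` when lost, not an error),
    (iii) optionally a nonlinear step simulation of the combined network
    whose output precision must stay above ``p_threshold``.
    """
    if field is None:
        if theta is None:
            raise ValueError("provide either a rate field or kinetic parameters")
        field = build_rate_field(an.combined, theta, "mm_variant")
    st = find_steady_state(field, d0)
    ss = linearize(field, st.x, d0, residual_tol=1e-6)
    ident = combined_minor_identity(an, ss.A, rtol=1e-6)
    stable, eig = is_hurwitz(ss.A)
    diag = adaptation_verdict(ss, zero_tol=FD_ZERO_TOL)
    report = {
        **ident,
        "combined_stable": stable,
        "max_re_eig": float(np.max(eig.real)),
        "modularity_proviso_violated": not stable,
        "combined_verdict": diag.verdict,
    }
    if simulate and stable:
        metrics, _ = step_metrics(field, d0, d1, p_min=p_threshold,
                                  s_min=DEFAULT_S_MIN, x_star=st.x)
        report["precision"] = metrics.precision
        report["sensitivity"] = metrics.sensitivity
        report["adaptation_preserved"] = bool(metrics.precision >= p_threshold)
    return report
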