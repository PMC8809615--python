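"""Shared helpers: deterministic RNGs and brute-force graph oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from adaptscan.network import SignedDigraph


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def brute_force_cycles(g: SignedDigraph) -> set[tuple[tuple[str, ...], int]]:
    """All simple directed cycles by exhaustive subset/rotation search.

    Independent of networkx: enumerates every node subset and every cyclic
    arrangement, keeping those whose consecutive pairs are all edges.
    Cycles are canonicalized to start at the node earliest in graph order.
    """
    order = {lab: i for i, lab in enumerate(g.nodes)}
    found = set()
    for r in range(1, g.n_nodes + 1):
        for subset in itertools.combinations(g.nodes, r):
            anchor, rest = subset[0], subset[1:]
            for perm in itertools.permutations(rest):
                cyc = (anchor,) + perm
                pairs = list(zip(cyc, cyc[1:] + cyc[:1]))
                if all(g.sign(a, b) != 0 for a, b in pairs):
                    sign = 1
                    for a, b in pairs:
                        sign *= g.sign(a, b)
                    k = min(range(len(cyc)), key=lambda i: order[cyc[i]])
                    found.add((cyc[k:] + cyc[:k], sign))
    return found


def brute_force_paths(g: SignedDigraph) -> set[tuple[tuple[str, ...], int]]:
    """All simple input->output paths by exhaustive permutation search."""
    if g.input_node == g.output_node:
        return {((g.input_node,), 1)}
    inner = [n for n in g.nodes if n not in (g.input_node, g.output_node)]
    found = set()
    for r in range(len(inner) + 1):
        for mid in itertools.permutations(inner, r):
            path = (g.input_node,) + mid + (g.output_node,)
            pairs = list(zip(path, path[1:]))
            if all(g.sign(a, b) != 0 for a, b in pairs):
                sign = 1
                for a, b in pairs:
                    sign *= g.sign(a, b)
                found.add((path, sign))
    return found


def random_signed_graph(rng: np.random.Generator, n: int, p_edge: float = 0.4,
                        input_node: str | None = None,
                        output_node: str | None = None) -> SignedDigraph:
    nodes = tuple(chr(ord("A") + i) for i in range(n))
    edges = {}
    for s in nodes:
        for t in nodes:
            u = rng.random()
            if u < p_edge / 2:
                edges[(s, t)] = 1
            elif u < p_edge:
                edges[(s, t)] = -1
    return SignedDigraph(nodes, edges, input_node or nodes[0],
                         output_node or nodes[-1])
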