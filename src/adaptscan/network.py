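"""Signed directed network topologies: representation, I/O and enumeration.

A topology is a signed digraph over named protein nodes.  A directed edge
``j -> i`` with sign ``+1`` means node *j* activates node *i* (the entry
``A[i][j]`` of any Jacobian built on the graph is positive at an interior
steady state); sign ``-1`` means repression.  One node receives the external
disturbance (the *input* node) and one node is read out (the *output* node).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "SignedDigraph",
    "NetworkValidationError",
    "NetworkParseError",
    "parse_network",
    "write_network",
    "encode_topology",
    "decode_topology",
    "enumerate_topologies",
]

_SIGN_CHARS = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


class NetworkParseError(ValueError):
    """Malformed serialized network text."""


class NetworkValidationError(ValueError):
    """Structurally invalid network (duplicate edge, dangling reference...)."""


@dataclass(frozen=True)
class SignedDigraph:
    """A signed digraph with designated input and output nodes.

    Parameters
    ----------
    nodes
        Ordered node labels.  Order is authoritative: it fixes state-vector
        indices for every matrix built from the graph.
    edges
        Mapping ``(source, target) -> sign`` with sign in ``{+1, -1}``.
        At most one edge per ordered pair; self-edges are allowed.
    input_node, output_node
        Labels of the disturbed node and of the read-out node.  They may
        coincide (required for two-node adaptive networks).
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    input_node: str = ""
    output_node: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", dict(self.edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkValidationError("duplicate node labels")
        members = set(self.nodes)
        for (s, t), sign in self.edges.items():
            if s not in members or t not in members:
                raise NetworkValidationError(f"edge ({s!r}, {t!r}) references unknown node")
            if sign not in (1, -1):
                raise NetworkValidationError(f"edge ({s!r}, {t!r}) has sign {sign!r}, expected +/-1")
        if self.nodes or self.input_node or self.output_node:
            for which, label in (("input", self.input_node), ("output", self.output_node)):
                if label not in members:
                    raise NetworkValidationError(f"{which} node {label!r} not among nodes")

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, label: str) -> int:
        return self.nodes.index(label)

    @property
    def input_index(self) -> int:
        return self.index(self.input_node)

    @property
    def output_index(self) -> int:
        return self.index(self.output_node)

    def sign(self, source: str, target: str) -> int:
        """Edge sign, or 0 when the interaction is absent."""
        return self.edges.get((source, target), 0)

    def predecessors(self, target: str) -> list[tuple[str, int]]:
        """(source, sign) pairs of all edges into ``target``."""
        return [(s, sg) for (s, t), sg in self.edges.items() if t == target]

    def activators(self, target: str) -> list[str]:
        return [s for s, sg in self.predecessors(target) if sg > 0]

    def repressors(self, target: str) -> list[str]:
        return [s for s, sg in self.predecessors(target) if sg < 0]

    def sign_matrix(self) -> list[list[int]]:
        """Dense sign pattern S with S[i][j] = sign of edge j -> i."""
        n = self.n_nodes
        mat = [[0] * n for _ in range(n)]
        for (s, t), sg in self.edges.items():
            mat[self.index(t)][self.index(s)] = sg
        return mat

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), sg in self.edges.items():
            g.add_edge(s, t, sign=sg)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.input_node == other.input_node
            and self.output_node == other.output_node
        )

    def __hash__(self) -> int:
        return hash((self.nodes, frozenset(self.edges.items()), self.input_node, self.output_node))


# -- serialization -------------------------------------------------------

def _parse_sign(token: str) -> int:
    try:
        return _SIGN_CHARS[token.strip()]
    except KeyError:
        raise NetworkParseError(f"unknown edge sign {token!r} (expected '+' or '-')") from None


def parse_network(text: str, fmt: str = "json") -> SignedDigraph:
    """Parse a serialized network.

    JSON dialect::

        {"nodes": [...],
         "edges": [{"source": s, "target": t, "sign": "+"|"-"}, ...],
         "input": label, "output": label}

    TSV dialect: header-free ``source<TAB>target<TAB>+|-`` lines plus
    directive lines ``#nodes<TAB>A,B,...`` (optional), ``#input<TAB>label``
    and ``#output<TAB>label``.
    """
    if fmt == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise NetworkParseError(f"invalid JSON: {exc}") from exc
        for key in ("nodes", "input", "output"):
            if key not in doc:
                raise NetworkParseError(f"missing {key!r} declaration")
        edges: dict[tuple[str, str], int] = {}
        for rec in doc.get("edges", []):
            try:
                pair = (str(rec["source"]), str(rec["target"]))
                sign = rec["sign"]
            except (KeyError, TypeError) as exc:
                raise NetworkParseError(f"malformed edge record {rec!r}") from exc
            sign = _parse_sign(sign) if isinstance(sign, str) else int(sign)
            if pair in edges:
                raise NetworkValidationError(f"duplicate edge {pair[0]} -> {pair[1]}")
            edges[pair] = sign
        return SignedDigraph(tuple(str(n) for n in doc["nodes"]), edges,
                             str(doc["input"]), str(doc["output"]))
    if fmt == "tsv":
        nodes: list[str] = []
        edges = {}
        input_node = output_node = None
        seen: list[str] = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if line.startswith("#"):
                if len(parts) != 2:
                    raise NetworkParseError(f"line {lineno}: malformed directive {line!r}")
                key = parts[0][1:].strip().lower()
                if key == "input":
                    input_node = parts[1].strip()
                elif key == "output":
                    output_node = parts[1].strip()
                elif key == "nodes":
                    nodes = [n.strip() for n in parts[1].split(",")]
                else:
                    raise NetworkParseError(f"line {lineno}: unknown directive {key!r}")
                continue
            if len(parts) != 3:
                raise NetworkParseError(f"line {lineno}: expected 'source<TAB>target<TAB>sign'")
            s, t, sg = (p.strip() for p in parts)
            if (s, t) in edges:
                raise NetworkValidationError(f"duplicate edge {s} -> {t}")
            edges[(s, t)] = _parse_sign(sg)
            for lab in (s, t):
                if lab not in seen:
                    seen.append(lab)
        if input_node is None or output_node is None:
            raise NetworkParseError("missing #input or #output directive")
        if not nodes:
            nodes = seen
            for lab in (input_node, output_node):
                if lab not in nodes:
                    nodes.append(lab)
        return SignedDigraph(tuple(nodes), edges, input_node, output_node)
    raise ValueError(f"unknown format {fmt!r} (expected 'json' or 'tsv')")


def write_network(g: SignedDigraph, fmt: str = "json") -> str:
    """Serialize a network; ``parse_network(write_network(g), fmt) == g``."""
    order = {lab: i for i, lab in enumerate(g.nodes)}
    items = sorted(g.edges.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]]))
    if fmt == "json":
        doc = {
            "nodes": list(g.nodes),
            "edges": [{"source": s, "target": t, "sign": "+" if sg > 0 else "-"}
                      for (s, t), sg in items],
            "input": g.input_node,
            "output": g.output_node,
        }
        return json.dumps(doc, indent=2) + "\n"
    if fmt == "tsv":
        lines = ["#nodes\t" + ",".join(g.nodes),
                 f"#input\t{g.input_node}", f"#output\t{g.output_node}"]
        lines += [f"{s}\t{t}\t{'+' if sg > 0 else '-'}" for (s, t), sg in items]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r} (expected 'json' or 'tsv')")


# -- exhaustive enumeration ----------------------------------------------
#
# An n-node topology assigns one of {absent, activation, repression} to each
# of the n^2 ordered node pairs (self-pairs included), so there are 3^(n^2)
# topologies.  Codes are base-3 integers: the ordered pair (target i,
# source j) occupies digit position i*n + j (row-major in the Jacobian sign
# pattern, i.e. target-major), with digit 0 = absent, 1 = activation,
# 2 = repression.  The mapping is frozen: it is the reproducible identifier
# of a topology in all screening outputs.

_DIGIT_TO_SIGN = {0: 0, 1: 1, 2: -1}
_SIGN_TO_DIGIT = {0: 0, 1: 1, -1: 2}


def encode_topology(g: SignedDigraph) -> int:
    """Base-3 code of a topology's sign pattern (target-major digit order)."""
    n = g.n_nodes
    code = 0
    mat = g.sign_matrix()
    for i in range(n):
        for j in range(n):
            code += _SIGN_TO_DIGIT[mat[i][j]] * 3 ** (i * n + j)
    return code


def decode_topology(code: int, nodes: Iterable[str], input_node: str,
                    output_node: str) -> SignedDigraph:
    """Inverse of :func:`encode_topology` for the given node labels."""
    nodes = tuple(nodes)
    n = len(nodes)
    if not 0 <= code < 3 ** (n * n):
        raise ValueError(f"code {code} out of range [0, 3^{n * n})")
    edges: dict[tuple[str, str], int] = {}
    c = code
    for pos in range(n * n):
        c, digit = c // 3, c % 3
        sign = _DIGIT_TO_SIGN[digit]
        if sign:
            i, j = divmod(pos, n)
            edges[(nodes[j], nodes[i])] = sign
    return SignedDigraph(nodes, edges, input_node, output_node)


def enumerate_topologies(n_nodes: int, input_node: str, output_node: str,
                         nodes: Iterable[str] | None = None) -> Iterator[SignedDigraph]:
    """Yield all 3^(n^2) signed topologies in increasing code order.

    Node labels default to ``A, B, C, ...``.  The caller bounds ``n_nodes``;
    the stream is lazy so partial consumption is cheap.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    labels = tuple(nodes) if nodes is not None else _default_labels(n_nodes)
    if len(labels) != n_nodes:
        raise ValueError("node label count does not match n_nodes")
    for code in range(3 ** (n_nodes * n_nodes)):
        yield decode_topology(code, labels, input_node, output_node)


def _default_labels(n: int) -> tuple[str, ...]:
    if n <= 26:
        return tuple(chr(ord("A") + i) for i in range(n))
    return tuple(f"N{i}" for i in range(n))
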