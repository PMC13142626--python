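"""Construction of the anchor multigraph from reads.

Nodes are MUS anchor words plus two terminals, ``FIRST_NODE`` and
``LAST_NODE``.  Every read contributes one edge instance per consecutive
pair of anchor occurrences, plus a prefix edge from the source terminal
when the first occurrence does not start the read, and a suffix edge to
the sink terminal when the last occurrence does not end it.  An edge
instance carries a positional offset delta (difference of 1-based starts)
and a tag tau: the intervening sequence when the anchors are separated by
a gap, the empty string when they overlap or abut.  The flow f(u, v) of an
edge is simply its number of instances.

Storage is a :class:`networkx.MultiDiGraph`; one parallel edge per
instance, so flows fall out of edge multiplicity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .mus_core import AnchorSet, ContractViolation, MusOccurrence, Read, ReadSet, locate_occurrences

USTART = "FIRST_NODE"
UEND = "LAST_NODE"
TERMINALS = (USTART, UEND)


@dataclass(eq=False)
class EdgeInstance:
    """One (delta, tau) transition observed in one read.

    ``parts`` is populated when the instance results from collapsing a
    strictly linear node: it stores the two source instances and the removed
    node's word, so spelling can always expand back to raw transitions.
    Instances compare by identity; ``label()`` gives the (delta, tau) pair.
    """

    delta: int
    tau: str
    read_id: str = ""
    parts: tuple["EdgeInstance", str, "EdgeInstance"] | None = None

    def label(self) -> tuple[int, str]:
        return (self.delta, self.tau)


@dataclass
class NodeProps:
    """Longest observed context on each side of a node across all reads."""

    max_prefix: str = ""
    max_suffix: str = ""

    def update_prefix(self, seq: str) -> None:
        if len(seq) > len(self.max_prefix):
            self.max_prefix = seq

    def update_suffix(self, seq: str) -> None:
        if len(seq) > len(self.max_suffix):
            self.max_suffix = seq


class VmusGraph:
    """Directed multigraph (U, V, f, I, P) over anchor words and terminals."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        for t in TERMINALS:
            self._g.add_node(t, props=NodeProps())
        self.skipped_reads = 0

    # -- nodes -------------------------------------------------------------

    def add_anchor_node(self, word: str) -> None:
        if word in TERMINALS:
            raise ValueError("terminal names are reserved")
        if word not in self._g:
            self._g.add_node(word, props=NodeProps())

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def anchor_nodes(self) -> list[str]:
        return [n for n in self._g.nodes if n not in TERMINALS]

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def props(self, node: str) -> NodeProps:
        return self._g.nodes[node]["props"]

    def remove_node(self, node: str) -> None:
        self._g.remove_node(node)

    @staticmethod
    def seq(node: str) -> str:
        """Nucleotide sequence of a node: its word; terminals are empty."""
        return "" if node in TERMINALS else node

    # -- edges -------------------------------------------------------------

    def add_instance(self, u: str, v: str, inst: EdgeInstance) -> None:
        if u == UEND or v == USTART:
            raise ContractViolation("terminal direction violated")
        for n in (u, v):
            if n not in self._g:
                self._g.add_node(n, props=NodeProps())
        self._g.add_edge(u, v, inst=inst)

    def remove_instance(self, u: str, v: str, inst: EdgeInstance) -> None:
        for key, data in list(self._g[u][v].items()):
            if data["inst"] is inst:
                self._g.remove_edge(u, v, key)
                return
        raise KeyError("instance not present on edge")

    def flow(self, u: str, v: str) -> int:
        if not self._g.has_edge(u, v):
            return 0
        return self._g.number_of_edges(u, v)

    def instances(self, u: str, v: str) -> list[EdgeInstance]:
        if not self._g.has_edge(u, v):
            return []
        return [d["inst"] for _, d in sorted(self._g[u][v].items())]

    def edges(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        marked: set[tuple[str, str]] = set()
        for u, v in self._g.edges():
            if (u, v) not in marked:
                marked.add((u, v))
                seen.append((u, v))
        return seen

    def successors(self, node: str) -> list[str]:
        return list(self._g.successors(node))

    def predecessors(self, node: str) -> list[str]:
        return list(self._g.predecessors(node))

    def unique_out_degree(self, node: str) -> int:
        return self._g.out_degree(node) and len(set(self._g.successors(node)))

    def unique_in_degree(self, node: str) -> int:
        return self._g.in_degree(node) and len(set(self._g.predecessors(node)))

    def out_flow(self, node: str) -> int:
        return self._g.out_degree(node)

    def in_flow(self, node: str) -> int:
        return self._g.in_degree(node)

    # -- misc --------------------------------------------------------------

    def copy(self) -> "VmusGraph":
        other = VmusGraph()
        other._g = self._g.copy()
        # node props are mutable; deep-copy them so simplification of the
        # copy never touches the original
        for n in other._g.nodes:
            p = other._g.nodes[n]["props"]
            other._g.nodes[n]["props"] = NodeProps(p.max_prefix, p.max_suffix)
        other.skipped_reads = self.skipped_reads
        return other

    def to_networkx(self) -> nx.MultiDiGraph:
        return self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VmusGraph):
            return NotImplemented
        if set(self.nodes) != set(other.nodes):
            return False
        for n in self.nodes:
            a, b = self.props(n), other.props(n)
            if (a.max_prefix, a.max_suffix) != (b.max_prefix, b.max_suffix):
                return False
        if set(self.edges()) != set(other.edges()):
            return False
        for u, v in self.edges():
            mine = sorted((i.label(), i.read_id) for i in self.instances(u, v))
            theirs = sorted((i.label(), i.read_id) for i in other.instances(u, v))
            if mine != theirs:
                return False
        return True


# ---------------------------------------------------------------------------
# edge construction rules
# ---------------------------------------------------------------------------


def add_prefix_edge(graph: VmusGraph, read: Read, first_occ: MusOccurrence) -> VmusGraph:
    """Source-terminal edge for a read whose first anchor starts after base 1."""
    if first_occ.start <= 1:
        raise ContractViolation("prefix rule requires s1 > 1")
    delta = first_occ.start - 1
    tau = read.seq[: first_occ.start - 1]
    graph.add_instance(USTART, first_occ.word, EdgeInstance(delta, tau, read.id))
    graph.props(first_occ.word).update_prefix(tau)
    graph.props(USTART).update_prefix(tau)
    return graph


def add_internal_edge(
    graph: VmusGraph, read: Read, occ_i: MusOccurrence, occ_next: MusOccurrence
) -> VmusGraph:
    """Edge between two consecutive anchor occurrences of one read."""
    if occ_i.start >= occ_next.start:
        raise ContractViolation("occurrences must be in increasing start order")
    delta = occ_next.start - occ_i.start
    if delta > len(occ_i.word):
        tau = read.seq[occ_i.end : occ_next.start - 1]
    else:
        tau = ""
    graph.add_instance(occ_i.word, occ_next.word, EdgeInstance(delta, tau, read.id))
    return graph


def add_suffix_edge(graph: VmusGraph, read: Read, last_occ: MusOccurrence) -> VmusGraph:
    """Sink-terminal edge for a read whose last anchor ends before the read does."""
    if last_occ.end >= len(read.seq):
        raise ContractViolation("suffix rule requires ep < |Rk|")
    delta = len(read.seq) - last_occ.end
    tau = read.seq[last_occ.end :]
    graph.add_instance(last_occ.word, UEND, EdgeInstance(delta, tau, read.id))
    graph.props(last_occ.word).update_suffix(tau)
    graph.props(UEND).update_suffix(tau)
    return graph


def build_graph(reads: ReadSet, anchors: AnchorSet) -> VmusGraph:
    """Apply the prefix/internal/suffix rules read by read.

    Reads containing no anchor occurrence contribute nothing (counted in
    ``graph.skipped_reads``).  A read whose sorted occurrence list has p
    entries contributes exactly (p - 1) internal instances plus its prefix
    and suffix instances when those boundary conditions hold.
    """
    if not len(reads):
        raise ValueError("empty read set")
    if not len(anchors):
        raise ValueError("empty anchor set")
    graph = VmusGraph()
    for word in anchors.words:
        graph.add_anchor_node(word)
    for k, read in enumerate(reads):
        occ = locate_occurrences((read.id, read.seq), k, anchors)
        if not occ:
            graph.skipped_reads += 1
            continue
        if occ[0].start > 1:
            add_prefix_edge(graph, read, occ[0])
        for a, b in itertools.pairwise(occ):
            add_internal_edge(graph, read, a, b)
        if occ[-1].end < len(read.seq):
            add_suffix_edge(graph, read, occ[-1])
    return graph


# ---------------------------------------------------------------------------
# best-instance selection (shared with traversal)
# ---------------------------------------------------------------------------


def pick_best_instance(instances: list[EdgeInstance], terminal: bool) -> EdgeInstance:
    """Terminal edges keep the longest tag; internal edges the smallest delta.

    Remaining ties break on the other component, then lexicographic tau,
    then read id, so selection is total and deterministic.
    """
    if not instances:
        raise ValueError("no instances to select from")
    if terminal:
        key = lambda i: (-len(i.tau), i.delta, i.tau, i.read_id)
    else:
        key = lambda i: (i.delta, -len(i.tau), i.tau, i.read_id)
    return min(instances, key=key)


# ---------------------------------------------------------------------------
# GFA 1.0 export
# ---------------------------------------------------------------------------


def export_gfa(graph: VmusGraph) -> str:
    """GFA 1.0 text: S line per node, L line per distinct edge.

    Terminal nodes are zero-length segments flagged ``tn:i:1``.  Each link
    carries the flow (``fc``) and the best instance's delta (``dw``) and tag
    (``dt``, ``*`` when empty).
    """
    lines = ["H\tVN:Z:1.0"]
    for node in sorted(graph.anchor_nodes):
        lines.append(f"S\t{node}\t{node}\tLN:i:{len(node)}")
    for node in TERMINALS:
        lines.append(f"S\t{node}\t*\tLN:i:0\ttn:i:1")
    for u, v in sorted(graph.edges()):
        best = pick_best_instance(graph.instances(u, v), u in TERMINALS or v in TERMINALS)
        tag = best.tau if best.tau else "*"
        lines.append(
            f"L\t{u}\t+\t{v}\t+\t0M\tfc:i:{graph.flow(u, v)}\tdw:i:{best.delta}\tdt:Z:{tag}"
        )
    return "\n".join(lines) + "\n"


def parse_gfa(text: str) -> tuple[set[str], dict[tuple[str, str], int]]:
    """Recover the node set and flow map from :func:`export_gfa` output."""
    nodes: set[str] = set()
    flows: dict[tuple[str, str], int] = {}
    for line in text.splitlines():
        fields = line.rstrip("\n").split("\t")
        if not fields or not fields[0]:
            continue
        if fields[0] == "S":
            nodes.add(fields[1])
        elif fields[0] == "L":
            flow = 1
            for tag in fields[6:]:
                if tag.startswith("fc:i:"):
                    flow = int(tag[5:])
            flows[(fields[1], fields[3])] = flow
    return nodes, flows
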