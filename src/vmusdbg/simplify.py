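"""Collapsing strictly linear nodes into merged edges.

A node is *strictly linear* when it has exactly one distinct predecessor,
one distinct successor, and total in- and out-flow of 1.  Such a node sits
on an unambiguous chain and can be folded into a single edge whose
instance is (delta1 + delta2, tau1 + word(v) + tau2).  The merged instance
keeps references to its two sources so path spelling can expand it back to
raw transitions; the concatenated tag alone over-represents overlapping
anchors and is only a serialization convenience.

Collapsing is applied in lexicographic node order until no strictly
linear node remains.  The result is confluent: any collapse order yields
the same simplified graph up to instance-list order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_build import TERMINALS, EdgeInstance, VmusGraph
from .mus_core import ContractViolation


@dataclass(frozen=True)
class CollapseRecord:
    removed_node: str
    merged_edge: tuple[str, str]
    merged_delta: int
    merged_tag: str


def is_strictly_linear(graph: VmusGraph, node: str) -> bool:
    if node in TERMINALS:
        raise ContractViolation("terminal nodes are never collapsible")
    return (
        graph.unique_in_degree(node) == 1
        and graph.unique_out_degree(node) == 1
        and graph.in_flow(node) == 1
        and graph.out_flow(node) == 1
    )


def _collapsible(graph: VmusGraph, node: str) -> bool:
    if not is_strictly_linear(graph, node):
        return False
    (u,) = set(graph.predecessors(node))
    (w,) = set(graph.successors(node))
    # the merge formula presumes three distinct path nodes; a self-loop
    # neighbourhood is left alone
    return u != node and w != node


def collapse_once(graph: VmusGraph, node: str) -> CollapseRecord:
    """Remove one strictly linear node, merging its two edges in place."""
    if not _collapsible(graph, node):
        raise ContractViolation(f"node {node!r} is not strictly linear")
    (u,) = set(graph.predecessors(node))
    (w,) = set(graph.successors(node))
    (e1,) = graph.instances(u, node)
    (e2,) = graph.instances(node, w)
    merged = EdgeInstance(
        delta=e1.delta + e2.delta,
        tau=e1.tau + graph.seq(node) + e2.tau,
        read_id=f"{e1.read_id}+{e2.read_id}",
        parts=(e1, node, e2),
    )
    graph.remove_node(node)
    graph.add_instance(u, w, merged)
    return CollapseRecord(
        removed_node=node,
        merged_edge=(u, w),
        merged_delta=merged.delta,
        merged_tag=merged.tau,
    )


def simplify_graph(graph: VmusGraph) -> tuple[VmusGraph, list[CollapseRecord]]:
    """Iterate collapsing to a fixed point; the input graph is not modified."""
    gs = graph.copy()
    records: list[CollapseRecord] = []
    changed = True
    while changed:
        changed = False
        for node in sorted(gs.anchor_nodes):
            if _collapsible(gs, node):
                records.append(collapse_once(gs, node))
                changed = True
    return gs, records
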