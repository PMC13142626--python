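"""Graph traversal: junction detection, unitig extraction, contig spelling.

Traversal happens in three steps.  First the simplified graph is
decomposed into maximal non-branching paths (unitigs): every path starts
and ends at a junction -- a terminal node, or a node whose number of
distinct predecessors or successors differs from one -- and consumes each
edge instance at most once, preferring the best instance per hop.
Isolated cycles with no junction at all are emitted as circular unitigs.

Second, unitigs are chained into final contigs.  Read boundaries put
source/sink edges all over an otherwise linear genome, which turns interior
anchors into junctions and would shred the assembly into read-sized
pieces; chaining reconnects a unitig that *enters* a junction through an
anchor-to-anchor edge with the unique unitig that *leaves* it through one.
A chain that closes on itself becomes a circular contig, which is how a
fully covered circular genome comes back as a single sequence.

Third, each path is spelled.  Every hop appends the part of the next
anchor not covered by the positional overlap phi = |seq(u)| - delta, or
tag-plus-anchor when the anchors are separated by a gap; terminal hops
contribute their tags verbatim.  Merged instances from simplification are
expanded back to raw transitions first, so overlaps are always resolved
against genuine anchor sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_build import TERMINALS, UEND, USTART, EdgeInstance, VmusGraph, pick_best_instance


class SpellingError(ValueError):
    """A path's deltas are inconsistent with its node sequences."""


@dataclass(frozen=True)
class DegreeSummary:
    unique_in: int
    unique_out: int
    total_in: int
    total_out: int


@dataclass(eq=False)
class UnitigPath:
    """A maximal non-branching path and the instances chosen along it.

    For a linear path there are ``len(nodes) - 1`` instances.  For a
    circular path the node list holds each cycle node once and the final
    instance closes the cycle back to ``nodes[0]``.
    """

    nodes: list[str]
    chosen_instances: list[EdgeInstance]
    circular: bool = False


@dataclass(eq=False)
class Contig:
    id: str
    seq: str
    path: UnitigPath
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# degrees and junctions
# ---------------------------------------------------------------------------


def degree_summary(graph: VmusGraph, node: str) -> DegreeSummary:
    if node not in graph:
        raise KeyError(f"unknown node {node!r}")
    return DegreeSummary(
        unique_in=graph.unique_in_degree(node),
        unique_out=graph.unique_out_degree(node),
        total_in=graph.in_flow(node),
        total_out=graph.out_flow(node),
    )


def is_junction(graph: VmusGraph, node: str) -> bool:
    """Terminal, or unique in-degree != 1, or unique out-degree != 1."""
    if node in TERMINALS:
        return True
    return graph.unique_in_degree(node) != 1 or graph.unique_out_degree(node) != 1


def best_instance(graph: VmusGraph, edge: tuple[str, str]) -> EdgeInstance:
    u, v = edge
    instances = graph.instances(u, v)
    if not instances:
        raise KeyError(f"edge {edge!r} absent")
    return pick_best_instance(instances, u in TERMINALS or v in TERMINALS)


# ---------------------------------------------------------------------------
# unitig extraction
# ---------------------------------------------------------------------------


def _node_order(nodes: list[str]) -> list[str]:
    return sorted(nodes, key=lambda n: (n == UEND, n != USTART, n))


class _InstancePool:
    """Tracks which edge instances remain unused during traversal."""

    def __init__(self, graph: VmusGraph):
        self._graph = graph
        self._used: set[int] = set()

    def take_best(self, u: str, v: str) -> EdgeInstance | None:
        free = [i for i in self._graph.instances(u, v) if id(i) not in self._used]
        if not free:
            return None
        best = pick_best_instance(free, u in TERMINALS or v in TERMINALS)
        self._used.add(id(best))
        return best

    def has_free(self, u: str, v: str) -> bool:
        return any(id(i) not in self._used for i in self._graph.instances(u, v))

    def unused(self) -> list[tuple[str, str, EdgeInstance]]:
        return [
            (u, v, i)
            for u, v in self._graph.edges()
            for i in self._graph.instances(u, v)
            if id(i) not in self._used
        ]


def extract_mnbps(graph: VmusGraph) -> list[UnitigPath]:
    """Decompose the graph into maximal non-branching paths.

    One path starts per (junction, distinct successor) pair; interior hops
    consume the best unused instance toward the unique next node.  Edge
    instances are used at most once across all paths; surplus parallel
    instances stay unused rather than forcing duplicate paths.  Cycles in
    which no node is a junction are emitted as circular paths starting at
    their lexicographically smallest node.
    """
    pool = _InstancePool(graph)
    junction = {n: is_junction(graph, n) for n in graph.nodes}
    paths: list[UnitigPath] = []
    visited: set[str] = set()

    for u in _node_order(graph.nodes):
        if not junction[u]:
            continue
        for v in sorted(graph.successors(u)):
            first = pool.take_best(u, v)
            if first is None:
                continue
            nodes, chosen = [u, v], [first]
            current = v
            while current not in TERMINALS and not junction[current]:
                visited.add(current)
                (succ,) = set(graph.successors(current))
                inst = pool.take_best(current, succ)
                if inst is None:
                    break  # parallel flow exhausted; end the path here
                nodes.append(succ)
                chosen.append(inst)
                current = succ
            paths.append(UnitigPath(nodes, chosen))

    # components left untouched are junction-free cycles
    for start in sorted(graph.anchor_nodes):
        if junction[start] or start in visited:
            continue
        if not any(pool.has_free(start, s) for s in graph.successors(start)):
            continue
        nodes, chosen = [start], []
        current = start
        while True:
            visited.add(current)
            (succ,) = set(graph.successors(current))
            inst = pool.take_best(current, succ)
            if inst is None:
                if chosen:  # uneven parallel flow: keep the partial sequence
                    paths.append(UnitigPath(nodes, chosen))
                break
            chosen.append(inst)
            if succ == start:
                paths.append(UnitigPath(nodes, chosen, circular=True))
                break
            nodes.append(succ)
            current = succ
    return paths


def unused_instances(graph: VmusGraph, paths: list[UnitigPath]) -> list[tuple[int, str]]:
    """Edge instances not consumed by any extracted path (audit helper)."""
    used = {id(i) for p in paths for i in p.chosen_instances}
    out = []
    for u, v in graph.edges():
        for inst in graph.instances(u, v):
            if id(inst) not in used:
                out.append((inst.delta, inst.tau))
    return out


# ---------------------------------------------------------------------------
# spelling
# ---------------------------------------------------------------------------


def _expand_instance(inst: EdgeInstance) -> tuple[list[EdgeInstance], list[str]]:
    """Recursively unfold a merged instance into raw instances + interior nodes."""
    if inst.parts is None:
        return [inst], []
    left, mid, right = inst.parts
    li, ln = _expand_instance(left)
    ri, rn = _expand_instance(right)
    return li + ri, ln + [mid] + rn


def _expand_path(nodes: list[str], instances: list[EdgeInstance]) -> tuple[list[str], list[EdgeInstance]]:
    raw_nodes = [nodes[0]]
    raw_insts: list[EdgeInstance] = []
    for hop, inst in enumerate(instances):
        insts, interior = _expand_instance(inst)
        raw_insts.extend(insts)
        raw_nodes.extend(interior)
        raw_nodes.append(nodes[hop + 1] if hop + 1 < len(nodes) else nodes[0])
    return raw_nodes, raw_insts


def _spell_linear(nodes: list[str], insts: list[EdgeInstance], seq) -> str:
    if nodes[0] == USTART:
        if len(nodes) < 2:
            return ""
        out = [insts[0].tau, seq(nodes[1])]
        start = 1
    else:
        out = [seq(nodes[0])]
        start = 0
    for i in range(start, len(insts)):
        u, v, e = nodes[i], nodes[i + 1], insts[i]
        if v == UEND:
            if i != len(insts) - 1:
                raise SpellingError("sink terminal must end the path")
            out.append(e.tau)
            continue
        phi = len(seq(u)) - e.delta
        word = seq(v)
        if phi > len(word):
            raise SpellingError(
                f"impossible overlap at hop {i} ({u} -> {v}): phi={phi} > |{v}|"
            )
        if phi > 0:
            out.append(word[phi:])
        elif phi == 0:
            out.append(word)
        else:
            if len(e.tau) != -phi:
                raise SpellingError(
                    f"gap tag length mismatch at hop {i} ({u} -> {v}): "
                    f"|tau|={len(e.tau)} != {-phi}"
                )
            out.append(e.tau + word)
    return "".join(out)


def spell_path(path: UnitigPath, graph: VmusGraph | None = None) -> str:
    """Spell a path into its nucleotide sequence.

    Missing chosen instances are filled with the best instance of the hop's
    edge when a graph is supplied.  Merged instances are expanded before
    spelling.  For circular paths, the spelled sequence has length equal to
    the sum of raw deltas around the cycle (one full traversal, no repeated
    seam).
    """
    nodes = list(path.nodes)
    insts = list(path.chosen_instances)
    if len(insts) < (len(nodes) if path.circular else len(nodes) - 1):
        if graph is None:
            raise ValueError("path is missing instances and no graph was given")
        hops = [
            (nodes[i], nodes[(i + 1) % len(nodes)])
            for i in range(len(nodes) if path.circular else len(nodes) - 1)
        ]
        insts = [
            insts[i] if i < len(insts) else best_instance(graph, hops[i])
            for i in range(len(hops))
        ]
    seq = VmusGraph.seq
    if not path.circular:
        if len(nodes) == 1:
            return seq(nodes[0])
        raw_nodes, raw_insts = _expand_path(nodes, insts)
        return _spell_linear(raw_nodes, raw_insts, seq)

    raw_nodes, raw_insts = _expand_path(nodes, insts)  # ends back at nodes[0]
    total = sum(e.delta for e in raw_insts)
    extended = _spell_linear(raw_nodes, raw_insts, seq)
    if extended[total:] != extended[: len(extended) - total]:
        raise SpellingError("circular path does not close consistently")
    return extended[:total]


# ---------------------------------------------------------------------------
# final contigs
# ---------------------------------------------------------------------------


def _chain_unitigs(paths: list[UnitigPath]) -> list[UnitigPath]:
    """Join unitigs across junctions whose anchor-level continuation is unique.

    A unitig is an *anchor-entry* at its end node when its last hop is an
    anchor-to-anchor edge, and an *anchor-exit* at its start node likewise.
    When a junction has exactly one of each, the pair is concatenated; a
    chain that returns to its first unitig closes into a circular path.
    """
    linear = [p for p in paths if not p.circular]
    enters: dict[str, list[UnitigPath]] = {}
    exits: dict[str, list[UnitigPath]] = {}
    for p in linear:
        if len(p.nodes) >= 2 and p.nodes[-1] not in TERMINALS and p.nodes[-2] != USTART:
            enters.setdefault(p.nodes[-1], []).append(p)
        if len(p.nodes) >= 2 and p.nodes[0] not in TERMINALS and p.nodes[1] != UEND:
            exits.setdefault(p.nodes[0], []).append(p)

    next_of: dict[UnitigPath, UnitigPath] = {}
    for node, ins in enters.items():
        outs = exits.get(node, [])
        if len(ins) == 1 and len(outs) == 1:
            next_of[ins[0]] = outs[0]
    has_prev = set(next_of.values())

    merged: list[UnitigPath] = []
    consumed: set[int] = set()

    def run_chain(start: UnitigPath) -> None:
        nodes = list(start.nodes)
        chosen = list(start.chosen_instances)
        consumed.add(id(start))
        current = start
        circular = False
        while current in next_of:
            nxt = next_of[current]
            if nxt is start:
                circular = True
                break
            nodes.extend(nxt.nodes[1:])
            chosen.extend(nxt.chosen_instances)
            consumed.add(id(nxt))
            current = nxt
        if circular:
            merged.append(UnitigPath(nodes[:-1], chosen, circular=True))
        else:
            merged.append(UnitigPath(nodes, chosen))

    for p in linear:
        if p not in has_prev and id(p) not in consumed:
            run_chain(p)
    for p in sorted(
        (q for q in linear if id(q) not in consumed), key=lambda q: tuple(q.nodes)
    ):
        if id(p) not in consumed:  # closed chains only reachable from inside
            run_chain(p)
    merged.extend(p for p in paths if p.circular)
    return merged


def assemble_contigs(graph: VmusGraph) -> list[Contig]:
    """Extract unitigs, chain them into final paths, and spell contigs.

    Contigs come back sorted by decreasing length with ids ``contig_<n>``;
    circular contigs are flagged.
    """
    paths = extract_mnbps(graph)
    finals = _chain_unitigs(paths)
    spelled = [(spell_path(p, graph), p) for p in finals]
    spelled = [(s, p) for s, p in spelled if s]
    spelled.sort(key=lambda sp: (-len(sp[0]), sp[0]))
    return [
        Contig(id=f"contig_{i + 1}", seq=s, path=p, circular=p.circular)
        for i, (s, p) in enumerate(spelled)
    ]


def assembly_stats(contigs: list[Contig], reference_length: int | None = None) -> dict:
    """Contig count, total length, largest contig, and N50.

    N50 is the length L such that contigs of length >= L together cover at
    least half of the total assembly length.
    """
    lengths = sorted((c.length for c in contigs), reverse=True)
    total = sum(lengths)
    stats = {
        "contigs": len(lengths),
        "total_length": total,
        "largest": lengths[0] if lengths else 0,
        "n50": 0,
    }
    running = 0
    for length in lengths:
        running += length
        if 2 * running >= total:
            stats["n50"] = length
            break
    if reference_length is not None:
        stats["reference_length"] = reference_length
    return stats
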