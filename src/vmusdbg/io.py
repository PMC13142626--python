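"""File formats: FASTA/FASTQ input, FASTA/FASTQ/TSV/JSON/BED/GFA output.

Reading is gzip-transparent and goes through Biopython's SeqIO.  Reads are
uppercased and split at runs of non-ACGT characters (including N) into
sub-reads, because a single ambiguous base would otherwise manufacture
spurious unique substrings.  The graph JSON dump is lossless, including
merged-instance provenance, so simplify/assemble stages can run from disk.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

from Bio import SeqIO

from .graph_build import EdgeInstance, NodeProps, TERMINALS, VmusGraph
from .mus_core import Anchor, AnchorSet, Read, ReadSet, UniquenessConfig, split_ambiguous
from .simplify import CollapseRecord


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_fastx_format(path) -> str:
    with _open_text(path) as handle:
        for line in handle:
            if line.strip():
                first = line[0]
                break
        else:
            raise ValueError(f"{path}: empty file")
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: not FASTA or FASTQ (first record starts with {first!r})")


def read_fastx(path) -> ReadSet:
    """Parse FASTA or FASTQ (plain or gzipped) into a sanitized ReadSet."""
    fmt = sniff_fastx_format(path)
    reads: list[Read] = []
    with _open_text(path) as handle:
        try:
            for record in SeqIO.parse(handle, fmt):
                parts = split_ambiguous(str(record.seq))
                if len(parts) == 1:
                    reads.append(Read(record.id, parts[0]))
                else:
                    for i, part in enumerate(parts, 1):
                        reads.append(Read(f"{record.id}.{i}", part))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    if not reads:
        raise ValueError(f"{path}: no usable reads")
    return ReadSet(reads)


def write_fasta(records, path, width: int = 80) -> None:
    """Write contigs or (id, seq) pairs as wrapped FASTA."""
    with _open_text(path, "wt") as out:
        for rec in records:
            if hasattr(rec, "seq") and hasattr(rec, "id"):
                header = f"{rec.id} length={len(rec.seq)}"
                if getattr(rec, "circular", False):
                    header += " circular=true"
                seq = rec.seq
            else:
                name, seq = rec
                header = str(name)
            out.write(f">{header}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(reads: ReadSet, path, quality_char: str = "I") -> None:
    with _open_text(path, "wt") as out:
        for read in reads:
            out.write(f"@{read.id}\n{read.seq}\n+\n{quality_char * len(read.seq)}\n")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


def write_anchors_tsv(anchors: AnchorSet, path) -> None:
    cfg = anchors.scope
    with _open_text(path, "wt") as out:
        out.write(
            f"#scope={cfg.scope}\trc={int(cfg.use_reverse_complement)}"
            f"\tcircular={int(cfg.circular)}\tbackend={cfg.backend}\n"
        )
        out.write("anchor_id\tword\tlength\n")
        for i, anchor in enumerate(anchors, 1):
            out.write(f"anchor_{i}\t{anchor.word}\t{anchor.length}\n")


def read_anchors_tsv(path) -> AnchorSet:
    config = UniquenessConfig()
    words: list[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("#"):
                kv = dict(field.split("=", 1) for field in line[1:].split("\t"))
                config = UniquenessConfig(
                    scope=kv.get("scope", "genome"),
                    use_reverse_complement=bool(int(kv.get("rc", "0"))),
                    circular=bool(int(kv.get("circular", "0"))),
                    backend=kv.get("backend", "suffix_array"),
                )
                continue
            if not line or line.startswith("anchor_id\t"):
                continue
            words.append(line.split("\t")[1])
    return AnchorSet([Anchor(w) for w in words], scope=config)


def write_occurrences_tsv(rows, path) -> None:
    """Rows: (read_id, word, start, end), 1-based closed intervals."""
    with _open_text(path, "wt") as out:
        out.write("read_id\tword\tstart\tend\n")
        for read_id, word, start, end in rows:
            out.write(f"{read_id}\t{word}\t{start}\t{end}\n")


def write_collapses_tsv(records: list[CollapseRecord], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("removed_node\tmerged_from\tmerged_to\tmerged_delta\tmerged_tag\n")
        for r in records:
            tag = r.merged_tag if r.merged_tag else "*"
            out.write(
                f"{r.removed_node}\t{r.merged_edge[0]}\t{r.merged_edge[1]}"
                f"\t{r.merged_delta}\t{tag}\n"
            )


def read_collapses_tsv(path) -> list[CollapseRecord]:
    records = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("removed_node\t"):
                continue
            node, u, w, delta, tag = line.split("\t")
            records.append(
                CollapseRecord(node, (u, w), int(delta), "" if tag == "*" else tag)
            )
    return records


def write_bed(intervals, path) -> None:
    """BED3+name; 0-based half-open, the format's native convention."""
    with _open_text(path, "wt") as out:
        for start, end, name in intervals:
            out.write(f"genome\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# graph JSON (lossless)
# ---------------------------------------------------------------------------


def _instance_to_dict(inst: EdgeInstance) -> dict:
    d = {"delta": inst.delta, "tau": inst.tau, "read_id": inst.read_id}
    if inst.parts is not None:
        left, mid, right = inst.parts
        d["parts"] = [_instance_to_dict(left), mid, _instance_to_dict(right)]
    return d


def _instance_from_dict(d: dict) -> EdgeInstance:
    parts = None
    if "parts" in d:
        left, mid, right = d["parts"]
        parts = (_instance_from_dict(left), mid, _instance_from_dict(right))
    return EdgeInstance(d["delta"], d["tau"], d.get("read_id", ""), parts)


def graph_to_dict(graph: VmusGraph) -> dict:
    return {
        "nodes": [
            {
                "id": n,
                "max_prefix": graph.props(n).max_prefix,
                "max_suffix": graph.props(n).max_suffix,
            }
            for n in graph.nodes
        ],
        "edges": [
            {
                "u": u,
                "v": v,
                "instances": [_instance_to_dict(i) for i in graph.instances(u, v)],
            }
            for u, v in graph.edges()
        ],
        "skipped_reads": graph.skipped_reads,
    }


def graph_from_dict(data: dict) -> VmusGraph:
    graph = VmusGraph()
    for node in data["nodes"]:
        if node["id"] not in TERMINALS:
            graph.add_anchor_node(node["id"])
        props = graph.props(node["id"])
        props.max_prefix = node.get("max_prefix", "")
        props.max_suffix = node.get("max_suffix", "")
    for edge in data["edges"]:
        for inst in edge["instances"]:
            graph.add_instance(edge["u"], edge["v"], _instance_from_dict(inst))
    graph.skipped_reads = data.get("skipped_reads", 0)
    return graph


def write_graph_json(graph: VmusGraph, path) -> None:
    with _open_text(path, "wt") as out:
        json.dump(graph_to_dict(graph), out, indent=1, sort_keys=True)
        out.write("\n")


def read_graph_json(path) -> VmusGraph:
    with _open_text(path) as handle:
        return graph_from_dict(json.load(handle))


def write_json(data: dict, path) -> None:
    with _open_text(path, "wt") as out:
        json.dump(data, out, indent=1, sort_keys=True)
        out.write("\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
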