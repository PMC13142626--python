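"""End-to-end driver: extract -> build -> simplify -> assemble -> stats.

Anchor uniqueness is evaluated against a reference genome when one is
supplied (the operating mode for all worked examples); otherwise against
the read set itself.  Every run writes a manifest recording parameters,
input checksums, and per-stage counts, and is byte-reproducible given the
same inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as vio
from .assemble import assemble_contigs, assembly_stats
from .graph_build import build_graph, export_gfa
from .mus_core import UniquenessConfig, extract_mus, locate_occurrences, sanitize_sequence
from .simplify import simplify_graph

log = logging.getLogger("vmusdbg")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str | Path = "vmusdbg_out"
    genome: str | Path | None = None  # reference for genome-scope extraction
    scope: str | None = None  # default: genome if a reference is given
    use_reverse_complement: bool = False
    circular: bool = True
    backend: str = "suffix_array"
    keep_intermediates: bool = True
    seed: int = 0

    def uniqueness(self) -> UniquenessConfig:
        scope = self.scope or ("genome" if self.genome is not None else "reads")
        return UniquenessConfig(
            scope=scope,
            use_reverse_complement=self.use_reverse_complement,
            circular=self.circular and scope == "genome",
            backend=self.backend,
        )


def _load_genome(source) -> str:
    path = Path(source)
    if path.exists():
        reads = vio.read_fastx(path)
        return "".join(r.seq for r in reads)
    return sanitize_sequence(str(source))


def run_pipeline(reads_path, config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dictionary.

    Outputs: contigs.fa, graph.gfa, stats.json, manifest.json, plus
    intermediates (anchors.tsv, occurrences.tsv, graph.json, graph_s.json,
    collapses.tsv) unless keep_intermediates is off.  On failure, files
    created by the failed run are removed and a PipelineError naming the
    stage is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    stage = "load"
    try:
        reads = vio.read_fastx(reads_path)
        log.info("loaded %d reads", len(reads))

        stage = "extract"
        ucfg = config.uniqueness()
        if ucfg.scope == "genome":
            if config.genome is None:
                raise ValueError("genome scope requires a reference genome")
            anchors = extract_mus(_load_genome(config.genome), ucfg)
        else:
            anchors = extract_mus(reads, ucfg)
        log.info("extracted %d anchors", len(anchors))
        if config.keep_intermediates:
            emit("anchors.tsv", lambda p: vio.write_anchors_tsv(anchors, p))
            rows = [
                (read.id, o.word, o.start, o.end)
                for k, read in enumerate(reads)
                for o in locate_occurrences((read.id, read.seq), k, anchors)
            ]
            emit("occurrences.tsv", lambda p: vio.write_occurrences_tsv(rows, p))

        stage = "build"
        graph = build_graph(reads, anchors)
        n_edges = len(graph.edges())
        log.info(
            "graph: %d nodes, %d distinct edges, %d reads without anchors",
            len(graph.nodes), n_edges, graph.skipped_reads,
        )
        emit("graph.gfa", lambda p: Path(p).write_text(export_gfa(graph)))
        if config.keep_intermediates:
            emit("graph.json", lambda p: vio.write_graph_json(graph, p))

        stage = "simplify"
        gs, collapses = simplify_graph(graph)
        log.info("simplified: %d nodes, %d collapses", len(gs.nodes), len(collapses))
        if config.keep_intermediates:
            emit("graph_s.json", lambda p: vio.write_graph_json(gs, p))
            emit("collapses.tsv", lambda p: vio.write_collapses_tsv(collapses, p))

        stage = "assemble"
        contigs = assemble_contigs(gs)
        emit("contigs.fa", lambda p: vio.write_fasta(contigs, p))

        stage = "stats"
        stats = assembly_stats(contigs)
        emit("stats.json", lambda p: vio.write_json(stats, p))

        manifest = {
            "parameters": {
                "reads": str(reads_path),
                "genome": str(config.genome) if config.genome is not None else None,
                "scope": ucfg.scope,
                "use_reverse_complement": ucfg.use_reverse_complement,
                "circular": ucfg.circular,
                "backend": ucfg.backend,
                "seed": config.seed,
            },
            "inputs": {"reads_sha256": vio.sha256_of(reads_path)},
            "counts": {
                "reads": len(reads),
                "anchors": len(anchors),
                "graph_nodes": len(graph.nodes),
                "graph_edges": n_edges,
                "reads_without_anchors": graph.skipped_reads,
                "collapses": len(collapses),
                "contigs": len(contigs),
            },
            "stats": stats,
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
        }
        emit("manifest.json", lambda p: vio.write_json(manifest, p))
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
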