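"""End-to-end orchestration: parse annotated GenBank input, build the
similarity network, report domain architectures and consensus
backbones, infer domain phylogenies, and write a run summary.

Each filtering stage logs records in and out, so the effect of every
threshold (35% identity, >10% coverage, 95% redundancy, trimming) is
auditable from the log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import architecture, io, network, phylo
from .types import ClusterRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gbk_dir: str
    out_dir: str
    reference_dir: str | None = None
    min_identity: float = 0.35
    min_coverage: float = 0.10
    redundancy_threshold: float = 0.95
    trim_max_gap_fraction: float = 0.5
    bootstrap_reps: int = 1000
    seed: int = 0
    phylo_domains: tuple[str, ...] = ("AMP-binding", "KS")
    deterministic: bool = False  # suppress timestamps in outputs

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "redundancy_threshold",
                     "trim_max_gap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def load_cluster_dir(gbk_dir: str | Path) -> list[ClusterRecord]:
    """Parse every .gbk/.gb/.gbff file in a directory; per-file parse
    failures are logged and skipped, the run continues."""
    gbk_dir = Path(gbk_dir)
    records: list[ClusterRecord] = []
    paths = sorted(p for p in gbk_dir.iterdir()
                   if p.suffix.lower() in (".gbk", ".gb", ".gbff", ".genbank"))
    for path in paths:
        try:
            records.extend(io.read_cluster_genbank(path))
        except ValueError as exc:
            logger.error("skipping %s: %s", path, exc)
    records.sort(key=lambda r: r.cluster_id)
    return records


def _domain_sequences(records: list[ClusterRecord], label: str
                      ) -> list[tuple[str, str]]:
    """Extract per-domain amino-acid sequences by slicing each gene's
    translation evenly across its annotated domains (annotation-level
    fixtures carry no per-domain coordinates on the protein)."""
    out = []
    for rec in records:
        for gene in rec.genes:
            doms = rec.domains_for(gene.gene_id)
            if not doms:
                continue
            width = max(len(gene.aa_seq) // len(doms), 1)
            for d in doms:
                if d.label != label:
                    continue
                lo = min(d.order_index * width, len(gene.aa_seq) - 1)
                seq = gene.aa_seq[lo:lo + width]
                if seq:
                    out.append((f"{rec.cluster_id}|{gene.gene_id}|"
                                f"{label}{d.order_index}", seq))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Outputs: genome_stats-free cluster summary (JSON), network GraphML +
    TSV, architecture + backbone TSVs, one Newick per phylogeny domain
    label (when >= 3 domain sequences survive redundancy reduction), and
    ``run_summary.json`` with per-genome class counts.
    """
    out_dir = Path(config.out_dir)
    records = load_cluster_dir(config.gbk_dir)
    if not records:
        raise ValueError(f"no parseable cluster GenBank files in {config.gbk_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("parsed %d clusters", len(records))

    net = network.build_similarity_network(
        records, config.min_identity, config.min_coverage)
    network.export_network(net, out_dir / "network.graphml", "graphml")
    network.export_network(net, out_dir / "network_edges.tsv", "tsv")
    logger.info("network: %d nodes, %d edges after thresholds "
                "(identity >= %.2f, coverage > %.2f)", net.number_of_nodes(),
                net.number_of_edges(), config.min_identity, config.min_coverage)

    if config.reference_dir:
        refs = load_cluster_dir(config.reference_dir)
        if refs:
            ref_net = network.compare_to_reference(records, refs)
            network.export_network(ref_net, out_dir / "reference_network.graphml")

    table = architecture.load_signature_table()
    architecture.write_architecture_tsv(records, out_dir / "architectures.tsv", table)
    architecture.write_backbone_tsv(records, out_dir / "backbones.tsv", table)

    trees_written = {}
    for label in config.phylo_domains:
        entries = _domain_sequences(records, label)
        if len(entries) < 3:
            logger.info("%s: %d sequences, too few for a tree", label, len(entries))
            continue
        seqset = phylo.SequenceSet(entries=entries, alphabet="aa")
        reps, membership = phylo.reduce_redundancy(
            seqset, config.redundancy_threshold)
        logger.info("%s: %d sequences -> %d representatives at %.0f%% identity",
                    label, len(entries), len(reps.entries),
                    100 * config.redundancy_threshold)
        with open(out_dir / f"{label}_clusters.tsv", "w") as fh:
            fh.write("sequence_id\trepresentative_id\n")
            for sid in sorted(membership):
                fh.write(f"{sid}\t{membership[sid]}\n")
        if len(reps.entries) < 3:
            continue
        aln = phylo.progressive_msa(reps)
        trimmed, kept = phylo.trim_columns(aln, config.trim_max_gap_fraction)
        logger.info("%s: alignment %d columns, %d retained after trimming",
                    label, aln.n_columns, len(kept))
        tree = phylo.bootstrap_support(trimmed, model="poisson",
                                       n_reps=config.bootstrap_reps,
                                       seed=config.seed)
        path = out_dir / f"{label}_tree.nwk"
        phylo.write_newick(tree, path)
        trees_written[label] = str(path)

    class_counts: dict[str, dict[str, int]] = {}
    for rec in records:
        cc = class_counts.setdefault(rec.genome_id, {})
        cc[rec.bgc_class] = cc.get(rec.bgc_class, 0) + 1
    summary = {
        "seed": config.seed,
        "config": asdict(config),
        "n_clusters": len(records),
        "n_genomes": len(class_counts),
        "class_counts": class_counts,
        "network": {"nodes": net.number_of_nodes(),
                    "edges": net.number_of_edges()},
        "trees": trees_written,
    }
    if not config.deterministic:
        import datetime
        summary["generated"] = datetime.datetime.now().isoformat(timespec="seconds")
    (out_dir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
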