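"""Identity/coverage-thresholded BGC similarity networks.

Every unordered pair of clusters is aligned once (concatenated
biosynthetic proteins, global alignment); an edge survives iff
identity >= ``min_identity`` (default 0.35) AND coverage >
``min_coverage`` (default 0.10).  Comparison against reference clusters
(MIBiG-style) uses the same alignment with both thresholds disabled, so
every pair yields an annotated edge.

Networks are ``networkx.Graph`` objects with node attributes
``genome_id``/``bgc_class`` and edge attributes ``identity``/``coverage``,
exportable as GraphML or a TSV edge list.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import networkx as nx

from .align import global_align
from .types import ClusterRecord, concatenate_biosynthetic

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.35
DEFAULT_MIN_COVERAGE = 0.10


def _alignable(records: list[ClusterRecord]) -> list[tuple[ClusterRecord, str]]:
    out = []
    for rec in records:
        try:
            out.append((rec, concatenate_biosynthetic(rec)))
        except ValueError:
            logger.warning("cluster %s has no biosynthetic genes; excluded "
                           "from the network", rec.cluster_id)
    return out


def _add_nodes(net: nx.Graph, pairs: list[tuple[ClusterRecord, str]],
               role: str | None = None) -> None:
    for rec, _ in pairs:
        attrs = {"genome_id": rec.genome_id, "bgc_class": rec.bgc_class}
        if role is not None:
            attrs["role"] = role
        net.add_node(rec.cluster_id, **attrs)


def build_similarity_network(records: list[ClusterRecord],
                             min_identity: float = DEFAULT_MIN_IDENTITY,
                             min_coverage: float = DEFAULT_MIN_COVERAGE) -> nx.Graph:
    """All-vs-all similarity network over clusters.

    Edge rule: identity >= min_identity and coverage > min_coverage
    (identity inclusive, coverage strict).  Isolated clusters stay in
    the node set.
    """
    pairs = _alignable(records)
    net = nx.Graph(min_identity=min_identity, min_coverage=min_coverage)
    _add_nodes(net, pairs)
    if len(pairs) < 2:
        logger.warning("fewer than 2 alignable clusters; network has no edges")
        return net
    for (ra, sa), (rb, sb) in itertools.combinations(sorted(
            pairs, key=lambda p: p[0].cluster_id), 2):
        res = global_align(sa, sb, ra.cluster_id, rb.cluster_id)
        if res.identity >= min_identity and res.coverage > min_coverage:
            net.add_edge(ra.cluster_id, rb.cluster_id,
                         identity=res.identity, coverage=res.coverage)
    return net


def compare_to_reference(records: list[ClusterRecord],
                         references: list[ClusterRecord]) -> nx.Graph:
    """Align query clusters against reference clusters (and queries
    among themselves) with no identity or coverage threshold: every
    aligned pair yields an edge annotated with identity and coverage."""
    if not records or not references:
        raise ValueError("both query and reference cluster lists must be non-empty")
    qpairs = _alignable(records)
    rpairs = _alignable(references)
    net = nx.Graph(min_identity=0.0, min_coverage=0.0)
    _add_nodes(net, qpairs, role="query")
    _add_nodes(net, rpairs, role="reference")
    everything = ([(p, "query") for p in qpairs] + [(p, "reference") for p in rpairs])
    for ((ra, sa), role_a), ((rb, sb), role_b) in itertools.combinations(everything, 2):
        if role_a == role_b == "reference":
            continue  # references are context, not compared among themselves
        res = global_align(sa, sb, ra.cluster_id, rb.cluster_id)
        net.add_edge(ra.cluster_id, rb.cluster_id,
                     identity=res.identity, coverage=res.coverage)
    return net


def export_network(net: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or a TSV edge list
    (source, target, identity, coverage)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, str(path))
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tidentity\tcoverage\n")
            for u, v, data in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['identity']:.6f}\t{data['coverage']:.6f}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r} (expected graphml or tsv)")


def import_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt == "tsv":
        net = nx.Graph()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("source\ttarget"):
                raise ValueError(f"{path}: not a network edge-list TSV")
            for line in fh:
                u, v, ident, cov = line.rstrip("\n").split("\t")
                net.add_edge(u, v, identity=float(ident), coverage=float(cov))
        return net
    raise ValueError(f"unknown network format {fmt!r} (expected graphml or tsv)")
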