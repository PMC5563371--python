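"""NRPS/PKS domain architectures, module segmentation, and consensus
amino-acid backbone prediction.

A minimal NRPS module is condensation (C, or heterocyclization) +
adenylation (A, annotated "AMP-binding") + peptidyl carrier protein
(PCP); a minimal type-I PKS module is ketosynthase (KS) +
acyltransferase (AT) + acyl carrier protein (ACP).  Architectures are
read gene by gene in genomic order, N->C within each gene (minus-strand
genes reversed), then segmented greedily: each C/heterocyclization or
KS opens a new module, tailoring domains (KR, DH, ER, epimerization,
...) attach to the open module, and a module lacking its essential
domains is flagged ``incomplete``.

The backbone of the predicted peptide is one monomer token per
adenylation domain, in module order: the strict-majority vote over the
per-predictor substrate calls (plus the native Stachelhaus
signature-code match when a 10-residue binding-pocket signature is
annotated).  Positions without a strict majority render as ``x``,
formatted Table-style as e.g. ``Gly-Thr-Tyr-...-x``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .types import ClusterRecord, DomainAnnotation

logger = logging.getLogger(__name__)

NRPS_OPENERS = {"Condensation", "Heterocyclization"}
PKS_OPENER = "KS"
TAILORING = {"Epimerization", "Heterocyclization", "KR", "DH", "ER", "TE",
             "Aminotransferase", "Docking"}
#: tokens that mean "no usable prediction"
UNKNOWN_TOKENS = {"nrp", "x", "unk", "n/a", "no_call", "none", "hydrophobic"}

STACHELHAUS_PREDICTOR = "stachelhaus-signature"


@dataclass
class Module:
    """One biosynthetic module: its kind, ordered domain labels, and the
    consensus monomer ("x" when unknown; NRPS only)."""

    kind: str  # "NRPS", "PKS" or "incomplete"
    domains: list[str] = field(default_factory=list)
    monomer: str = "x"


@dataclass
class ModuleArchitecture:
    cluster_id: str
    modules: list[Module] = field(default_factory=list)
    tailoring_flags: set[str] = field(default_factory=set)


def extract_architecture(record: ClusterRecord) -> list[tuple[str, list[str]]]:
    """Ordered (gene_id, [domain labels]) per gene.

    Genes are ordered by genomic start; domain labels run N->C along the
    protein (the reader already reverses genomic order on minus-strand
    genes, so ``order_index`` is the protein order).
    """
    out = []
    for gene in record.genes:
        doms = record.domains_for(gene.gene_id)
        if doms:
            out.append((gene.gene_id, [d.label for d in doms]))
    return out


def segment_modules(labels: list[str]) -> list[Module]:
    """Greedy left-to-right segmentation of a domain-label list into
    modules.  A C/heterocyclization opens an NRPS candidate, a KS a PKS
    candidate; completeness requires A+PCP (NRPS) or AT+ACP (PKS).
    Leading domains before the first opener form an implicit incomplete
    module (a standalone adenylation domain still yields a backbone
    position)."""
    if not labels:
        raise ValueError("empty domain list")
    modules: list[Module] = []
    current: list[str] | None = None
    opener: str | None = None

    def close() -> None:
        nonlocal current, opener
        if current is None:
            return
        got = set(current)
        if opener in NRPS_OPENERS and {"AMP-binding", "PCP"} <= got:
            kind = "NRPS"
        elif opener == PKS_OPENER and {"AT", "ACP"} <= got:
            kind = "PKS"
        else:
            kind = "incomplete"
        modules.append(Module(kind=kind, domains=current))
        current, opener = None, None

    for label in labels:
        if label in NRPS_OPENERS or label == PKS_OPENER:
            close()
            current = [label]
            opener = label
        else:
            if current is None:
                current = []
                opener = None
            current.append(label)
    close()
    return modules


def build_architecture(record: ClusterRecord) -> ModuleArchitecture:
    """Segment a cluster's full (gene-ordered) domain list into modules
    and collect cluster-level tailoring flags."""
    labels = [lab for _, labs in extract_architecture(record) for lab in labs]
    arch = ModuleArchitecture(cluster_id=record.cluster_id)
    if labels:
        arch.modules = segment_modules(labels)
        arch.tailoring_flags = {lab for lab in labels if lab in TAILORING}
    return arch


# ---------------------------------------------------------------------------
# Stachelhaus signature matching

def load_signature_table(path: str | Path | None = None) -> dict[str, str]:
    """Load a reference table of 10-residue adenylation binding-pocket
    signatures -> monomer tokens (TSV: signature, monomer).

    The packaged default table is synthetic: a constructed, internally
    consistent stand-in for the curated specificity-code collections,
    sufficient for fixtures and user-extensible via this same TSV
    format.
    """
    if path is None:
        ref = resources.files("bgcnet.data") / "stachelhaus_signatures.synthetic.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for i, line in enumerate(text.splitlines()):
        if not line.strip() or (i == 0 and line.lower().startswith("signature")):
            continue
        sig, monomer = line.split("\t")
        if len(sig) != 10:
            raise ValueError(f"reference signature {sig!r} does not have length 10")
        table[sig] = monomer.strip().lower()
    return table


def stachelhaus_match(signature10: str, table: dict[str, str]) -> tuple[str, int]:
    """Best positional match of a 10-residue signature against a
    reference table.

    Returns (monomer, n_matching_positions) for the reference signature
    with the most positional matches; if two references with *different*
    monomers tie for the best count, returns ("x", count).
    """
    if len(signature10) != 10:
        raise ValueError(f"signature must have length 10, got {len(signature10)}")
    if not table:
        raise ValueError("empty reference signature table")
    best_count = -1
    best_monomers: set[str] = set()
    for ref, monomer in table.items():
        count = sum(a == b for a, b in zip(signature10, ref))
        if count > best_count:
            best_count, best_monomers = count, {monomer}
        elif count == best_count:
            best_monomers.add(monomer)
    if len(best_monomers) == 1:
        return next(iter(best_monomers)), best_count
    return "x", best_count


# ---------------------------------------------------------------------------
# consensus backbone

def _format_token(token: str) -> str:
    return "x" if token in UNKNOWN_TOKENS else token.capitalize()


def format_backbone(tokens: list[str]) -> str:
    """Join per-module monomer tokens into the reported backbone string,
    e.g. ["gly", "thr", "x"] -> "Gly-Thr-x"."""
    return "-".join(_format_token(t) for t in tokens)


def _domain_consensus(domain: DomainAnnotation,
                      table: dict[str, str] | None) -> str:
    calls = {k: v for k, v in domain.predictor_calls.items()
             if v and v not in UNKNOWN_TOKENS}
    if domain.signature10 and table:
        native, _ = stachelhaus_match(domain.signature10, table)
        if native != "x":
            calls[STACHELHAUS_PREDICTOR] = native
    if not calls:
        return "x"
    counts = Counter(calls.values())
    token, n = counts.most_common(1)[0]
    if n * 2 > len(calls):  # strict majority of the non-empty calls
        return token
    return "x"


def consensus_backbone(record: ClusterRecord,
                       table: dict[str, str] | None = None) -> str:
    """Predicted amino-acid backbone of a cluster: one consensus token
    per adenylation domain, in gene/protein order.

    Consensus is a strict-majority vote over the annotated per-predictor
    substrate calls, augmented with the native signature-code match when
    a binding-pocket signature is present.  No strict majority (or no
    informative calls) yields "x"."""
    tokens = []
    for gene in record.genes:
        for dom in record.domains_for(gene.gene_id):
            if dom.label == "AMP-binding":
                tokens.append(_domain_consensus(dom, table))
    return format_backbone(tokens)


def backbone_tokens(record: ClusterRecord,
                    table: dict[str, str] | None = None) -> list[str]:
    """Per-adenylation-domain consensus tokens (lowercase, "x" for
    unknown), before Table-style formatting."""
    out = []
    for gene in record.genes:
        for dom in record.domains_for(gene.gene_id):
            if dom.label == "AMP-binding":
                tok = _domain_consensus(dom, table)
                out.append("x" if tok in UNKNOWN_TOKENS else tok)
    return out


def write_architecture_tsv(records: list[ClusterRecord], path: str | Path,
                           table: dict[str, str] | None = None) -> None:
    """TSV report: cluster_id, module_index, kind, domains, monomer;
    trailing incomplete modules are flagged."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tmodule_index\tkind\tdomains\tmonomer\tflags\n")
        for rec in records:
            arch = build_architecture(rec)
            n = len(arch.modules)
            per_a = iter(backbone_tokens(rec, table))
            for i, mod in enumerate(arch.modules):
                monomer = "."
                if "AMP-binding" in mod.domains:
                    monomer = next(per_a, "x")
                flags = "trailing_incomplete" if (
                    mod.kind == "incomplete" and i == n - 1 and n > 1) else ""
                fh.write(f"{rec.cluster_id}\t{i}\t{mod.kind}\t"
                         f"{';'.join(mod.domains)}\t{monomer}\t{flags}\n")


def write_backbone_tsv(records: list[ClusterRecord], path: str | Path,
                       table: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tbackbone\n")
        for rec in records:
            bb = consensus_backbone(rec, table)
            if bb:
                fh.write(f"{rec.cluster_id}\t{bb}\n")
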