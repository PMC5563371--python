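"""Core domain types for biosynthetic gene cluster (BGC) analysis.

These containers mirror the information an antiSMASH-style GenBank
annotation carries: genome assemblies, biosynthetic CDS, enzymatic domain
annotations (with per-predictor substrate calls for adenylation domains),
and cluster records grouping all of the above.

Coordinates are stored 1-based inclusive, the GenBank convention; any
0-based arithmetic happens at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = set("ACGTN")

#: Controlled vocabulary for enzymatic domain labels.  antiSMASH spells
#: these in several ways ("AMP-binding", "PKS_KS", "Condensation_LCL", ...);
#: the reader normalizes onto these canonical names and keeps anything
#: unrecognized verbatim.
DOMAIN_LABELS = frozenset({
    "Condensation", "AMP-binding", "PCP", "Heterocyclization",
    "Epimerization", "TE", "ACPS", "KS", "AT", "ACP", "KR", "DH", "ER",
    "Aminotransferase", "Docking",
})

#: BGC class labels as antiSMASH v3 product strings.
BGC_CLASSES = frozenset({
    "nrps", "t1pks", "t3pks", "t1t3pks", "nrps-t1pks", "transat-pks-nrps",
    "bacteriocin", "terpene", "siderophore", "hserlactone", "ectoine",
    "arylpolyene", "butyrolactone", "other",
})


@dataclass
class GenomeAssembly:
    """A (draft) genome: ordered contigs plus free-form metadata."""

    genome_id: str
    contigs: list[str]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"{self.genome_id}: assembly has no contigs")
        for i, c in enumerate(self.contigs):
            if not c:
                raise ValueError(f"{self.genome_id}: contig {i} is empty")
            bad = set(c) - NT_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.genome_id}: contig {i} has non-ACGTN characters {sorted(bad)!r}"
                )


@dataclass
class BiosyntheticGene:
    """One CDS of a cluster; ``is_biosynthetic`` marks a sec_met
    biosynthesis classification.  ``aa_seq`` is the translation, stored
    N->C regardless of strand; genomic ``start`` orders genes."""

    gene_id: str
    strand: str  # "+" or "-"
    start: int  # 1-based inclusive
    end: int
    aa_seq: str
    is_biosynthetic: bool = False
    sec_met_raw: tuple[str, ...] = ()  # raw qualifier text, for debugging

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.is_biosynthetic and not self.aa_seq:
            raise ValueError(f"{self.gene_id}: biosynthetic CDS without translation")
        bad = set(self.aa_seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: non-standard residues {sorted(bad)!r}")


@dataclass
class DomainAnnotation:
    """One enzymatic domain inside a gene.

    ``order_index`` is the domain's position within its gene, counted
    N->C along the protein.  ``predictor_calls`` maps predictor name to
    a lowercase monomer token (e.g. ``{"nrpspredictor2": "gly"}``);
    ``signature10`` is the 10-residue adenylation binding-pocket
    signature when annotated.
    """

    gene_id: str
    label: str
    order_index: int
    predictor_calls: dict[str, str] = field(default_factory=dict)
    signature10: str | None = None

    def __post_init__(self) -> None:
        if self.order_index < 0:
            raise ValueError("order_index must be >= 0")
        if self.signature10 is not None and len(self.signature10) != 10:
            raise ValueError(
                f"signature10 must have length 10, got {len(self.signature10)}"
            )


@dataclass
class ClusterRecord:
    """One annotated BGC: class label, genomic span, genes, domains."""

    cluster_id: str
    genome_id: str
    bgc_class: str
    contig_id: str
    start: int  # 1-based inclusive span on contig_id
    end: int
    genes: list[BiosyntheticGene] = field(default_factory=list)
    domains: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        gene_ids = {g.gene_id for g in self.genes}
        for d in self.domains:
            if d.gene_id not in gene_ids:
                raise ValueError(
                    f"{self.cluster_id}: domain references unknown gene {d.gene_id!r}"
                )

    @property
    def biosynthetic_genes(self) -> list[BiosyntheticGene]:
        return [g for g in self.genes if g.is_biosynthetic]

    def domains_for(self, gene_id: str) -> list[DomainAnnotation]:
        return sorted(
            (d for d in self.domains if d.gene_id == gene_id),
            key=lambda d: d.order_index,
        )


def concatenate_biosynthetic(record: ClusterRecord) -> str:
    """Concatenate the translations of the biosynthetic genes of a
    cluster, in genomic start-coordinate order.

    This concatenated protein is the unit compared between clusters in
    the similarity network.

    Raises
    ------
    ValueError
        If the record carries no biosynthetic gene (such clusters are
        excluded from network construction).
    """
    parts = [g.aa_seq for g in record.biosynthetic_genes]
    if not parts:
        raise ValueError(
            f"cluster {record.cluster_id} has no biosynthetic genes; "
            "excluded from similarity analysis"
        )
    return "".join(parts)
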