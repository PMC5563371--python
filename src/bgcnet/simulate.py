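"""Synthetic annotated-genome fixtures with controlled statistical
structure.

The generator emulates what the comparative analysis assumes of its
inputs: several genomes, each carrying clusters of different classes
(NRPS, PKS, hybrids, bacteriocins, terpenes, siderophores...); families
of clusters derived from a common ancestor at a controlled amino-acid
identity; domain annotations with per-predictor substrate calls (an
exact number of predictors agreeing on the configured monomer, or an
engineered tie for "x" positions); genes on both strands.  Family
ancestors are drawn i.i.d. uniform over residues, so inter-family
identity sits near the ~5% random background, far below the 35%
network threshold.

Everything is seeded and bit-for-bit reproducible, and a JSON manifest
records the ground truth (family membership, configured identities,
true backbones) so every downstream stage can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import format_backbone, load_signature_table
from .io import write_cluster_genbank
from .types import BiosyntheticGene, ClusterRecord, DomainAnnotation

RESIDUES = "ARNDCQEGHILKMFPSTWYV"  # 20 standard residues (X excluded)
NUCLEOTIDES = "ACGT"

#: classic three-predictor panel annotated by antiSMASH-style pipelines
PREDICTORS = ("nrpspredictor2", "minowa", "stachelhaus")
_DECOYS = ("ala", "ser", "thr", "gly", "val", "leu", "lys", "orn")


@dataclass
class FamilySpec:
    """One cluster family: members mutated from a shared ancestor."""

    name: str
    bgc_class: str = "nrps"
    n_members: int = 5
    target_identity: float = 0.80
    n_genes: int = 3
    gene_length_range: tuple[int, int] = (200, 400)
    #: flat domain-label template for the whole cluster, distributed over
    #: genes in order; one entry of ``substrates`` per AMP-binding label
    domain_template: tuple[str, ...] = (
        "Condensation", "AMP-binding", "PCP",
        "Condensation", "AMP-binding", "PCP",
        "Condensation", "AMP-binding", "PCP", "TE",
    )
    substrates: tuple[str, ...] = ("gly", "thr", "tyr")
    n_predictors_agreeing: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.target_identity <= 1:
            raise ValueError("target_identity must be in (0, 1]")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        n_a = sum(1 for d in self.domain_template if d == "AMP-binding")
        if len(self.substrates) != n_a:
            raise ValueError(
                f"{self.name}: {n_a} AMP-binding domains in template but "
                f"{len(self.substrates)} substrates configured")
        if not 0 <= self.n_predictors_agreeing <= len(PREDICTORS):
            raise ValueError("n_predictors_agreeing out of range")


@dataclass
class FixtureConfig:
    seed: int
    n_genomes: int = 4
    families: list[FamilySpec] = field(default_factory=list)
    unrelated_clusters: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")


def default_config(seed: int) -> FixtureConfig:
    """The study-shaped default: two unrelated five-member families at
    0.80 within-family identity plus one unrelated random cluster."""
    return FixtureConfig(
        seed=seed,
        n_genomes=5,
        families=[
            FamilySpec(name="famA", bgc_class="nrps"),
            FamilySpec(name="famB", bgc_class="t1pks",
                       domain_template=("KS", "AT", "ACP", "KR", "DH",
                                        "KS", "AT", "ACP", "TE"),
                       substrates=()),
        ],
        unrelated_clusters=1,
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def mutate_protein(seq: str, target_identity: float,
                   seed: int | np.random.Generator,
                   indel_rate: float = 0.0) -> str:
    """Substitute a Binomial(len, 1 - target_identity) set of positions
    with uniformly drawn different residues, so the realized ungapped
    identity has expectation ``target_identity``.  Optional small
    indels (default off) insert/delete single residues at rate
    ``indel_rate`` per site."""
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chars = list(seq)
    n_sub = rng.binomial(len(chars), 1.0 - target_identity)
    for pos in rng.choice(len(chars), size=n_sub, replace=False):
        alternatives = RESIDUES.replace(chars[pos], "")
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    if indel_rate > 0:
        out = []
        for c in chars:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(c)
            if r > 1 - indel_rate / 2:
                out.append(RESIDUES[rng.integers(20)])
        chars = out or chars
    return "".join(chars)


def _predictor_calls(substrate: str, n_agree: int,
                     rng: np.random.Generator) -> dict[str, str]:
    """Calls such that exactly ``n_agree`` predictors vote ``substrate``.
    A substrate of "x" engineers a three-way tie (no strict majority)."""
    if substrate == "x":
        picks = list(rng.choice(_DECOYS, size=len(PREDICTORS), replace=False))
        return dict(zip(PREDICTORS, picks))
    decoys = [d for d in _DECOYS if d != substrate]
    rng.shuffle(decoys)
    calls = {}
    for i, name in enumerate(PREDICTORS):
        calls[name] = substrate if i < n_agree else decoys[i - n_agree]
    return calls


def _split_template(template: tuple[str, ...], n_genes: int) -> list[list[str]]:
    n_genes = min(n_genes, len(template))
    base, extra = divmod(len(template), n_genes)
    chunks, pos = [], 0
    for g in range(n_genes):
        size = base + (1 if g < extra else 0)
        chunks.append(list(template[pos:pos + size]))
        pos += size
    return chunks


def _make_cluster(cluster_id: str, genome_id: str, bgc_class: str,
                  gene_seqs: list[str], template: tuple[str, ...],
                  substrates: tuple[str, ...], n_agree: int,
                  rng: np.random.Generator,
                  signature_table: dict[str, str]) -> ClusterRecord:
    by_monomer = {m: s for s, m in signature_table.items()}
    chunks = _split_template(template, len(gene_seqs)) if template else []
    genes, domains = [], []
    pos = 101
    substrate_iter = iter(substrates)
    for gi, aa in enumerate(gene_seqs):
        gene_id = f"{cluster_id}_orf{gi + 1:02d}"
        nt_len = 3 * len(aa) + 3
        strand = "+" if rng.random() < 0.7 else "-"
        genes.append(BiosyntheticGene(
            gene_id=gene_id, strand=strand, start=pos, end=pos + nt_len - 1,
            aa_seq=aa, is_biosynthetic=True,
            sec_met_raw=(f"Type: {bgc_class}", "Kind: biosynthetic"),
        ))
        labels = chunks[gi] if gi < len(chunks) else []
        for oi, label in enumerate(labels):
            calls, signature = {}, None
            if label == "AMP-binding":
                substrate = next(substrate_iter)
                calls = _predictor_calls(substrate, n_agree, rng)
                if substrate != "x" and substrate in by_monomer:
                    signature = by_monomer[substrate]
            domains.append(DomainAnnotation(
                gene_id=gene_id, label=label, order_index=oi,
                predictor_calls=calls, signature10=signature))
        pos += nt_len + 150
    return ClusterRecord(
        cluster_id=cluster_id, genome_id=genome_id, bgc_class=bgc_class,
        contig_id=f"{cluster_id}_ctg", start=1, end=pos + 100,
        genes=genes, domains=domains)


def generate_cluster_family(spec: FamilySpec, seed: int | np.random.Generator,
                            genome_ids: list[str] | None = None,
                            cluster_numbers: list[int] | None = None
                            ) -> list[ClusterRecord]:
    """One ancestor plus ``n_members - 1`` derived members, each gene
    independently mutated to the family's target identity."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = load_signature_table()
    lo, hi = spec.gene_length_range
    ancestor = [random_protein(rng, int(rng.integers(lo, hi + 1)))
                for _ in range(spec.n_genes)]
    genome_ids = genome_ids or [f"G{i + 1:02d}" for i in range(spec.n_members)]
    cluster_numbers = cluster_numbers or [1] * spec.n_members
    records = []
    for m in range(spec.n_members):
        if m == 0:
            gene_seqs = list(ancestor)
        else:
            gene_seqs = [mutate_protein(g, spec.target_identity, rng)
                         for g in ancestor]
        genome = genome_ids[m % len(genome_ids)]
        cid = f"{genome}.cluster{cluster_numbers[m]:03d}"
        records.append(_make_cluster(
            cid, genome, spec.bgc_class, gene_seqs, spec.domain_template,
            spec.substrates, spec.n_predictors_agreeing, rng, table))
    return records


def generate_fixture_set(config: FixtureConfig
                         ) -> tuple[list[ClusterRecord], dict]:
    """All cluster records of a fixture plus its ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    genome_ids = [f"G{i + 1:02d}" for i in range(config.n_genomes)]
    counters = {g: 0 for g in genome_ids}
    records: list[ClusterRecord] = []
    manifest: dict = {
        "seed": config.seed,
        "genomes": genome_ids,
        "families": {},
        "unrelated": [],
        "class_counts": {g: {} for g in genome_ids},
    }
    gcycle = 0

    def next_slot() -> tuple[str, int]:
        nonlocal gcycle
        g = genome_ids[gcycle % len(genome_ids)]
        gcycle += 1
        counters[g] += 1
        return g, counters[g]

    for spec in config.families:
        slots = [next_slot() for _ in range(spec.n_members)]
        fam = generate_cluster_family(
            spec, rng, genome_ids=[g for g, _ in slots],
            cluster_numbers=[n for _, n in slots])
        records.extend(fam)
        manifest["families"][spec.name] = {
            "bgc_class": spec.bgc_class,
            "target_identity": spec.target_identity,
            "members": [r.cluster_id for r in fam],
            "backbone": format_backbone(list(spec.substrates)),
        }
    for _ in range(config.unrelated_clusters):
        genome, num = next_slot()
        bgc_class = str(rng.choice(["bacteriocin", "terpene", "siderophore"]))
        n_genes = int(rng.integers(1, 4))
        seqs = [random_protein(rng, int(rng.integers(150, 350)))
                for _ in range(n_genes)]
        cid = f"{genome}.cluster{num:03d}"
        records.append(_make_cluster(cid, genome, bgc_class, seqs, (), (),
                                     0, rng, {}))
        manifest["unrelated"].append(cid)
    for rec in records:
        cc = manifest["class_counts"][rec.genome_id]
        cc[rec.bgc_class] = cc.get(rec.bgc_class, 0) + 1
    return records, manifest


def write_fixture_set(config: FixtureConfig, out_dir: str | Path
                      ) -> tuple[list[Path], Path]:
    """Write one GenBank per genome plus ``manifest.json``; returns the
    GenBank paths and the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, manifest = generate_fixture_set(config)
    per_genome: dict[str, list[ClusterRecord]] = {}
    for rec in records:
        per_genome.setdefault(rec.genome_id, []).append(rec)
    paths = []
    for genome in manifest["genomes"]:
        recs = per_genome.get(genome, [])
        if not recs:
            continue
        path = out_dir / f"{genome}.gbk"
        write_cluster_genbank(recs, path)
        paths.append(path)
    manifest["n_clusters"] = len(records)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths, manifest_path


# ---------------------------------------------------------------------------
# sequence evolution along a tree (for phylogeny validation)

def evolve_along_tree(tree, length: int, seed: int,
                      alphabet: str = "nt") -> list[tuple[str, str]]:
    """Evolve a random root sequence down a dendropy tree: on each edge
    of length b, each site substitutes with probability 1 - exp(-b) to a
    uniformly chosen different symbol.  Returns (leaf label, sequence)
    pairs — a simple Jukes–Cantor-like process adequate for testing
    topology recovery."""
    rng = np.random.default_rng(seed)
    symbols = NUCLEOTIDES if alphabet == "nt" else RESIDUES
    root_seq = "".join(rng.choice(list(symbols), size=length))
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        b = node.edge.length or 0.0
        p = 1.0 - np.exp(-b)
        chars = list(parent_seq)
        for i in range(len(chars)):
            if rng.random() < p:
                alts = symbols.replace(chars[i], "")
                chars[i] = alts[rng.integers(len(alts))]
        seq = "".join(chars)
        seqs[id(node)] = seq
        if node.is_leaf():
            out.append((node.taxon.label, seq))
    return out
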