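"""Reading and writing annotated cluster GenBank files, FASTA, and
genome statistics.

The reader understands antiSMASH-v3-style annotations: ``cluster`` (or
``region``) features carrying the BGC class in their ``product``
qualifier, CDS features whose ``sec_met`` qualifier classifies them as
biosynthetic, and ``aSDomain`` features holding enzymatic domain labels
plus per-predictor substrate calls in ``specificity`` qualifiers.  The
writer emits the same dialect, so fixtures round-trip exactly.

GenBank coordinates are 1-based inclusive; Biopython's 0-based half-open
locations are converted here and nowhere else.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .types import BiosyntheticGene, ClusterRecord, DomainAnnotation, GenomeAssembly

logger = logging.getLogger(__name__)

# antiSMASH spells domain names in several dialects; map them onto the
# controlled vocabulary.  Unrecognized labels pass through verbatim.
_LABEL_MAP = {
    "amp-binding": "AMP-binding",
    "a": "AMP-binding",
    "pcp": "PCP",
    "thiolation": "PCP",
    "condensation": "Condensation",
    "condensation_lcl": "Condensation",
    "condensation_dcl": "Condensation",
    "condensation_starter": "Condensation",
    "cglyc": "Condensation",
    "heterocyclization": "Heterocyclization",
    "condensation_cyclization": "Heterocyclization",
    "epimerization": "Epimerization",
    "te": "TE",
    "thioesterase": "TE",
    "acps": "ACPS",
    "ks": "KS",
    "pks_ks": "KS",
    "at": "AT",
    "pks_at": "AT",
    "acp": "ACP",
    "pks_pp": "ACP",
    "pp-binding": "ACP",
    "kr": "KR",
    "pks_kr": "KR",
    "dh": "DH",
    "pks_dh": "DH",
    "pks_dh2": "DH",
    "er": "ER",
    "pks_er": "ER",
    "aminotransferase": "Aminotransferase",
    "aminotran_1_2": "Aminotransferase",
    "aminotran_3": "Aminotransferase",
    "docking": "Docking",
    "pks_docking_nterm": "Docking",
    "pks_docking_cterm": "Docking",
}

_SIGNATURE_RE = re.compile(r"(?:10 aa )?(?:binding.pocket )?signature:\s*([A-Z]{10})")


def normalize_domain_label(raw: str) -> str:
    """Map an annotation-dialect domain name onto the controlled
    vocabulary; unknown names are preserved as-is."""
    return _LABEL_MAP.get(raw.strip().lower(), raw.strip())


def _is_biosynthetic(sec_met: list[str]) -> bool:
    # antiSMASH v3 marks core genes with a "Kind: biosynthetic" line.
    return any("kind" in line.lower() and "biosynthetic" in line.lower()
               for line in sec_met)


def _parse_specificity(values: list[str]) -> dict[str, str]:
    calls: dict[str, str] = {}
    for v in values:
        if ":" not in v:
            continue
        name, _, token = v.partition(":")
        name = name.strip().lower()
        token = token.strip().lower()
        # "Stachelhaus code: gly" / "NRPSpredictor2 SVM: gly" / "Minowa: gly"
        name = re.sub(r"\s+(svm|code)$", "", name)
        if name == "consensus":  # antiSMASH's own vote; not an input predictor
            continue
        if token:
            calls[name] = token
    return calls


def _domain_from_feature(feat: SeqFeature, gene_id: str, order_index: int) -> DomainAnnotation:
    quals = feat.qualifiers
    raw_label = quals.get("domain", quals.get("aSDomain", ["Other"]))[0]
    signature = None
    for note in quals.get("note", []) + quals.get("signature", []):
        m = _SIGNATURE_RE.search(note)
        if m:
            signature = m.group(1)
            break
    return DomainAnnotation(
        gene_id=gene_id,
        label=normalize_domain_label(raw_label),
        order_index=order_index,
        predictor_calls=_parse_specificity(quals.get("specificity", [])),
        signature10=signature,
    )


def _gene_id_of(feat: SeqFeature, fallback: str) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return fallback


def read_cluster_genbank(path: str | Path) -> list[ClusterRecord]:
    """Parse an annotated GenBank file into :class:`ClusterRecord` s.

    One record is produced per ``cluster``/``region`` feature; a GenBank
    record carrying CDS but no such feature becomes a single cluster of
    class ``other`` spanning the whole record.  CDS lacking a
    ``translation`` qualifier are translated from the nucleotide
    sequence when one is present, otherwise rejected with a warning.
    """
    path = Path(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - report file context
        raise ValueError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not seq_records:
        raise ValueError(f"{path}: no GenBank records found")

    clusters: list[ClusterRecord] = []
    for rec in seq_records:
        clusters.extend(_clusters_from_record(rec, path))
    return clusters


def _clusters_from_record(rec: SeqRecord, path: Path) -> list[ClusterRecord]:
    genome_id = rec.name or rec.id
    for feat in rec.features:
        if feat.type == "source":
            for key in ("strain", "organism", "isolate"):
                if key in feat.qualifiers:
                    genome_id = feat.qualifiers[key][0]
                    break
            break

    cluster_feats = [f for f in rec.features if f.type in ("cluster", "region")]
    cds_feats = [f for f in rec.features if f.type == "CDS"]
    dom_feats = [f for f in rec.features if f.type == "aSDomain"]

    if not cluster_feats:
        span = FeatureLocation(0, len(rec.seq) or max(
            (int(f.location.end) for f in cds_feats), default=1))
        cluster_feats = [SeqFeature(span, type="cluster",
                                    qualifiers={"product": ["other"]})]

    out = []
    for idx, cfeat in enumerate(cluster_feats, start=1):
        bgc_class = cfeat.qualifiers.get("product", ["other"])[0].strip().lower()
        num = idx
        for note in cfeat.qualifiers.get("note", []):
            m = re.search(r"cluster number:\s*(\d+)", note, re.IGNORECASE)
            if m:
                num = int(m.group(1))
        cstart, cend = int(cfeat.location.start), int(cfeat.location.end)

        genes, domain_annotations = [], []
        n_bio = 0
        for i, feat in enumerate(c for c in cds_feats
                                 if int(c.location.start) >= cstart
                                 and int(c.location.end) <= cend):
            gene_id = _gene_id_of(feat, f"{rec.id}_cds{i}")
            aa = feat.qualifiers.get("translation", [""])[0]
            if not aa:
                if rec.seq is not None and len(rec.seq) and set(str(rec.seq)) != {"N"}:
                    aa = str(feat.extract(rec.seq).translate(to_stop=True))
                if not aa:
                    logger.warning("%s: CDS %s has no translation and no usable "
                                   "nucleotide sequence; skipped", path, gene_id)
                    continue
            sec_met = list(feat.qualifiers.get("sec_met", []))
            biosynthetic = _is_biosynthetic(sec_met)
            n_bio += biosynthetic
            genes.append(BiosyntheticGene(
                gene_id=gene_id,
                strand="-" if feat.location.strand == -1 else "+",
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                aa_seq=aa,
                is_biosynthetic=biosynthetic,
                sec_met_raw=tuple(sec_met),
            ))
        if n_bio == 0:
            logger.warning("%s: record %s cluster %d has no sec_met biosynthetic CDS",
                           path, rec.id, num)

        gene_lookup = {g.gene_id: g for g in genes}
        per_gene: dict[str, list[SeqFeature]] = {}
        for feat in dom_feats:
            if not (cstart <= int(feat.location.start) and int(feat.location.end) <= cend):
                continue
            gid = _gene_id_of(feat, "")
            if not gid:  # fall back to coordinate containment
                for g in genes:
                    if g.start - 1 <= int(feat.location.start) and int(feat.location.end) <= g.end:
                        gid = g.gene_id
                        break
            if gid not in gene_lookup:
                raise ValueError(
                    f"{path}: aSDomain at {feat.location} references unknown gene {gid!r}")
            per_gene.setdefault(gid, []).append(feat)

        for gid, feats in per_gene.items():
            # order N->C: genomic order on plus strand, reversed on minus
            feats.sort(key=lambda f: int(f.location.start),
                       reverse=(gene_lookup[gid].strand == "-"))
            for order_index, feat in enumerate(feats):
                domain_annotations.append(
                    _domain_from_feature(feat, gid, order_index))

        out.append(ClusterRecord(
            cluster_id=f"{genome_id}.cluster{num:03d}",
            genome_id=genome_id,
            bgc_class=bgc_class,
            contig_id=rec.id,
            start=cstart + 1,
            end=cend,
            genes=genes,
            domains=domain_annotations,
        ))
    return out


def write_cluster_genbank(records: list[ClusterRecord], path: str | Path,
                          contig_seqs: dict[str, str] | None = None) -> None:
    """Write cluster records as an antiSMASH-v3-style GenBank file (one
    GenBank record per cluster).  Without explicit contig sequences an
    all-N placeholder of the span length is emitted — the annotation,
    not the nucleotide sequence, is what downstream stages consume."""
    path = Path(path)
    seq_records = []
    for rec in records:
        length = rec.end
        seq = (contig_seqs or {}).get(rec.contig_id, "N" * length)
        sr = SeqRecord(Seq(seq), id=rec.contig_id, name=rec.genome_id[:16] or "contig",
                       description=f"{rec.genome_id} {rec.bgc_class} cluster")
        sr.annotations["molecule_type"] = "DNA"
        sr.features.append(SeqFeature(
            FeatureLocation(0, length), type="source",
            qualifiers={"organism": [rec.genome_id], "strain": [rec.genome_id]}))
        m = re.search(r"(\d+)$", rec.cluster_id)
        num = int(m.group(1)) if m else 1
        sr.features.append(SeqFeature(
            FeatureLocation(rec.start - 1, rec.end), type="cluster",
            qualifiers={"product": [rec.bgc_class],
                        "note": [f"Cluster number: {num}"]}))
        for g in rec.genes:
            quals = {
                "locus_tag": [g.gene_id],
                "translation": [g.aa_seq],
            }
            if g.sec_met_raw:
                quals["sec_met"] = list(g.sec_met_raw)
            elif g.is_biosynthetic:
                quals["sec_met"] = [f"Type: {rec.bgc_class}", "Kind: biosynthetic"]
            sr.features.append(SeqFeature(
                FeatureLocation(g.start - 1, g.end,
                                strand=-1 if g.strand == "-" else 1),
                type="CDS", qualifiers=quals))
            doms = rec.domains_for(g.gene_id)
            if not doms:
                continue
            width = max((g.end - g.start + 1) // max(len(doms), 1), 3)
            for d in doms:
                # place slots N->C along the gene; reversed genomically on "-"
                if g.strand == "+":
                    dstart = g.start - 1 + d.order_index * width
                else:
                    dstart = g.end - (d.order_index + 1) * width
                quals = {"domain": [d.label], "locus_tag": [g.gene_id]}
                if d.predictor_calls:
                    quals["specificity"] = [
                        f"{name}: {tok}" for name, tok in sorted(d.predictor_calls.items())]
                if d.signature10:
                    quals["note"] = [f"10 aa binding-pocket signature: {d.signature10}"]
                sr.features.append(SeqFeature(
                    FeatureLocation(dstart, dstart + width,
                                    strand=-1 if g.strand == "-" else 1),
                    type="aSDomain", qualifiers=quals))
        seq_records.append(sr)
    SeqIO.write(seq_records, str(path), "genbank")


# ---------------------------------------------------------------------------
# genome statistics

def genome_stats(assembly: GenomeAssembly) -> dict[str, float | int]:
    """Length, G+C percentage and fragment count of an assembly.

    GC is computed over unambiguous bases only: ``100 * (G+C) / (A+C+G+T)``;
    N never enters numerator or denominator.
    """
    length = sum(len(c) for c in assembly.contigs)
    g = sum(c.count("G") for c in assembly.contigs)
    cc = sum(c.count("C") for c in assembly.contigs)
    acgt = sum(len(c) - c.count("N") for c in assembly.contigs)
    if acgt == 0:
        raise ValueError(f"{assembly.genome_id}: all-N assembly, GC undefined")
    return {
        "length_bp": length,
        "gc_percent": 100.0 * (g + cc) / acgt,
        "n_fragments": len(assembly.contigs),
    }


def read_assembly_fasta(path: str | Path, genome_id: str | None = None) -> GenomeAssembly:
    path = Path(path)
    contigs = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    return GenomeAssembly(genome_id=genome_id or path.stem, contigs=contigs)


def write_fasta(entries: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in entries]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(Path(path)), "fasta")]


def load_genome_table():
    """The published genome feature table for the 21 Pseudovibrio
    assemblies (species, strain, length_bp, gc_percent, n_fragments,
    accession) as a pandas DataFrame — the printed per-genome statistics
    used for desk-scale arithmetic checks."""
    import pandas as pd
    from importlib import resources
    ref = resources.files("bgcnet.data") / "pseudovibrio_genome_table.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def write_genome_stats_tsv(stats: dict[str, dict], path: str | Path) -> None:
    """TSV report: genome_id, length_bp, gc_percent, n_fragments."""
    with open(path, "w") as fh:
        fh.write("genome_id\tlength_bp\tgc_percent\tn_fragments\n")
        for gid in sorted(stats):
            s = stats[gid]
            fh.write(f"{gid}\t{s['length_bp']}\t{s['gc_percent']:.2f}\t{s['n_fragments']}\n")
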