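"""Gene-model annotation of editing sites and codon-level recoding effects.

Region precedence follows the usual variant-effect convention:
CDS > 5'UTR > 3'UTR > exon_noncoding > intron > upstream/downstream
(within a configurable flank, strand-aware) > intergenic.  CDS sites get
a codon lookup: the spliced codon is extracted from the genome (reverse
complemented for minus-strand genes), the edited base substituted, and
both codons translated with the standard genetic code.
"""

from __future__ import annotations

import logging
from collections import Counter

import gffutils
from Bio.Seq import Seq

from editkit.models import (
    GeneModel,
    SiteAnnotation,
    Transcript,
    chrom_length,
    comp,
    fetch_seq,
    revcomp,
)

logger = logging.getLogger(__name__)

REGION_PRECEDENCE = {
    "CDS": 0,
    "5'UTR": 1,
    "3'UTR": 2,
    "exon_noncoding": 3,
    "intron": 4,
    "upstream": 5,
    "downstream": 5,
    "intergenic": 6,
}
KNOWN_BIOTYPES = {"protein_coding", "lincRNA", "snoRNA", "snRNA", "miRNA"}


class AnnotationError(ValueError):
    pass


def load_gtf(source: str) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF (path or text) into gene models.

    Transcripts lacking CDS are treated as non-coding; a CDS whose total
    length is not a multiple of 3 is kept but marked non-recodable (with
    a warning).  Files containing only ``exon`` features still yield
    models, with gene/biotype information taken from the attributes.
    """
    from_string = "\t" in source or "\n" in source
    try:
        db = gffutils.create_db(
            source,
            dbfn=":memory:",
            from_string=from_string,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps parse errors
        raise AnnotationError(f"failed to parse GTF: {exc}") from exc

    tx_feats: dict[str, dict] = {}
    gene_meta: dict[str, dict] = {}
    for feat in db.all_features():
        attrs = {k: v[0] for k, v in feat.attributes.items()}
        gid = attrs.get("gene_id", attrs.get("transcript_id", "unknown"))
        biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
        meta = gene_meta.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand, "biotype": ""}
        )
        if biotype and not meta["biotype"]:
            meta["biotype"] = biotype
        if feat.featuretype in ("gene", "transcript"):
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            continue
        rec = tx_feats.setdefault(
            tid,
            {"gene_id": gid, "strand": feat.strand, "exon": [], "CDS": [],
             "five_prime_utr": [], "three_prime_utr": []},
        )
        ftype = feat.featuretype
        if ftype in ("5UTR", "UTR5"):
            ftype = "five_prime_utr"
        if ftype in ("3UTR", "UTR3"):
            ftype = "three_prime_utr"
        if ftype in rec:
            rec[ftype].append((feat.start, feat.end))

    genes: dict[str, GeneModel] = {}
    for tid, rec in tx_feats.items():
        tx = Transcript(
            transcript_id=tid,
            strand=rec["strand"],
            exons=sorted(rec["exon"]),
            cds=sorted(rec["CDS"]),
            utr5=sorted(rec["five_prime_utr"]),
            utr3=sorted(rec["three_prime_utr"]),
        )
        if not tx.exons:
            continue
        if tx.cds and tx.cds_length() % 3 != 0:
            logger.warning(
                "transcript %s: CDS length %d not divisible by 3; marked non-recodable",
                tid, tx.cds_length(),
            )
            tx.recodable = False
        gid = rec["gene_id"]
        meta = gene_meta.get(gid, {})
        biotype = meta.get("biotype") or ("protein_coding" if tx.cds else "other")
        if biotype not in KNOWN_BIOTYPES:
            biotype = biotype if biotype else "other"
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=meta.get("chrom", "?"),
                strand=meta.get("strand", tx.strand),
                gene_biotype=biotype,
                transcripts=[],
            )
        genes[gid].transcripts.append(tx)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def _in_segments(pos: int, segments: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in segments)


def _region_in_transcript(pos: int, tx: Transcript, gene: GeneModel) -> str | None:
    if not (tx.start <= pos <= tx.end):
        return None
    if _in_segments(pos, tx.exons):
        if _in_segments(pos, tx.cds):
            return "CDS"
        if _in_segments(pos, tx.utr5):
            return "5'UTR"
        if _in_segments(pos, tx.utr3):
            return "3'UTR"
        if gene.gene_biotype == "protein_coding" and tx.cds:
            # exon base outside annotated CDS/UTR segments of a coding
            # transcript: fold into the nearest UTR by position
            return "5'UTR" if (
                (gene.strand == "+" and pos < tx.cds[0][0])
                or (gene.strand == "-" and pos > tx.cds[-1][1])
            ) else "3'UTR"
        return "exon_noncoding"
    return "intron"


def _spliced_cds(tx: Transcript, gene: GeneModel, genome) -> tuple[str, list[int]]:
    """Spliced CDS sequence in translation order plus the genomic
    position of each CDS base (same order)."""
    positions: list[int] = []
    for s, e in tx.cds:
        positions.extend(range(s, e + 1))
    seq = "".join(fetch_seq(genome, gene.chrom, s, e) for s, e in tx.cds)
    if gene.strand == "-":
        seq = revcomp(seq)
        positions = positions[::-1]
    return seq, positions


def _codon_effect(site, tx: Transcript, gene: GeneModel, genome) -> dict:
    seq, positions = _spliced_cds(tx, gene, genome)
    idx = positions.index(site.pos)
    ci, cpos = divmod(idx, 3)
    ref_codon = seq[3 * ci : 3 * ci + 3]
    # site alleles are in *site-strand* orientation; convert to the gene's
    alt_fwd = site.alt if site.strand == "+" else comp(site.alt)
    alt_tx = alt_fwd if gene.strand == "+" else comp(alt_fwd)
    alt_codon = ref_codon[:cpos] + alt_tx + ref_codon[cpos + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_codon == ref_codon or ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense_gain"
    else:
        effect = "missense"
    return dict(effect=effect, ref_codon=ref_codon, alt_codon=alt_codon,
                ref_aa=ref_aa, alt_aa=alt_aa)


def _splice_adjacent(pos: int, tx: Transcript) -> bool:
    if len(tx.exons) < 2:
        return False
    internal = []
    for i, (s, e) in enumerate(tx.exons):
        if i > 0:
            internal.append(s)
        if i < len(tx.exons) - 1:
            internal.append(e)
    return any(abs(pos - b) <= 2 for b in internal)


def annotate_site(site, models: list[GeneModel], genome, flank: int = 5000) -> SiteAnnotation:
    """Assign a region class, gene and (for CDS) recoding effect to a site.

    ``site`` needs ``chrom, pos, strand, ref(_base), alt(_base), edit_type``
    attributes (an :class:`~editkit.models.EditingSite` or a namedtuple row).
    """
    chrom = site.chrom
    pos = int(site.pos)
    if chrom not in genome:
        raise AnnotationError(f"unknown chromosome {chrom!r}")
    if not (1 <= pos <= chrom_length(genome, chrom)):
        raise AnnotationError(f"position {chrom}:{pos} beyond chromosome end")

    best = None  # (strand_mismatch, precedence, gene_id, region, gene, tx)
    for gene in models:
        if gene.chrom != chrom:
            continue
        if not (gene.start - flank <= pos <= gene.end + flank):
            continue
        for tx in gene.transcripts:
            region = _region_in_transcript(pos, tx, gene)
            if region is None:
                if pos < gene.start:
                    region = "upstream" if gene.strand == "+" else "downstream"
                elif pos > gene.end:
                    region = "downstream" if gene.strand == "+" else "upstream"
                else:
                    continue
            cand = (
                0 if gene.strand == site.strand else 1,
                REGION_PRECEDENCE[region],
                gene.gene_id,
                region,
                gene,
                tx,
            )
            if best is None or cand[:3] < best[:3]:
                best = cand

    ann = SiteAnnotation(
        chrom=chrom,
        pos=pos,
        strand=site.strand,
        edit_type=site.edit_type,
        region_class="intergenic",
    )
    if best is None:
        return ann
    _, _, _, region, gene, tx = best
    ann.region_class = region
    ann.gene_id = gene.gene_id
    ann.gene_biotype = gene.gene_biotype
    ann.splice_adjacent = _splice_adjacent(pos, tx)
    if region == "CDS" and tx.recodable and gene.gene_biotype == "protein_coding":
        ann.__dict__.update(_codon_effect(site, tx, gene, genome))
    return ann


def summarize_regions(annotations: list[SiteAnnotation]) -> dict:
    """Region / effect count tables plus the per-gene site-count histogram."""
    regions = Counter(a.region_class for a in annotations)
    effects = Counter(a.effect for a in annotations if a.effect != "none")
    biotypes = Counter(a.gene_biotype for a in annotations if a.gene_biotype)
    per_gene = Counter(a.gene_id for a in annotations if a.gene_id)
    hist = Counter()
    for n in per_gene.values():
        hist["1" if n == 1 else "2" if n == 2 else "3" if n == 3 else ">3"] += 1
    total = sum(regions.values())
    fractions = {k: v / total for k, v in regions.items()} if total else {}
    return {
        "regions": dict(regions),
        "region_fractions": fractions,
        "effects": dict(effects),
        "biotypes": dict(biotypes),
        "genes_by_site_count": dict(hist),
        "per_gene": dict(per_gene),
    }
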