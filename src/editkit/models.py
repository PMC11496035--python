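"""Shared domain types and small sequence helpers.

Coordinate convention: 1-based inclusive everywhere in public interfaces
(GTF-style).  Pileup base counts are kept in *forward-genome* base space,
split by the transcript strand the supporting reads were assigned to;
conversion to transcript orientation happens at site-calling time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASES = "ACGT"
RNA_BASES = "ACGU"
_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def comp(base: str) -> str:
    """Complement of a DNA base (or string of bases)."""
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_COMP)[::-1]


@dataclass
class SitePileup:
    """Strand-resolved base counts at one genomic position in one sample.

    ``counts_fwd`` holds bases from reads whose inferred *transcript*
    strand is '+', ``counts_rev`` from '-' reads; both are expressed as
    forward-genome bases (the usual pileup convention).
    """

    chrom: str
    pos: int
    ref_base: str
    counts_fwd: dict[str, int]
    counts_rev: dict[str, int]
    sample_id: str

    @property
    def coverage(self) -> int:
        return sum(self.counts_fwd.values()) + sum(self.counts_rev.values())


@dataclass(frozen=True)
class EditingSite:
    """A called editing event in one sample, in transcript orientation.

    ``ref_base``/``alt_base`` are reported on the transcript strand: a
    forward-genome T>C observation on a minus-strand site is an A>G site.
    """

    chrom: str
    pos: int
    strand: str
    ref_base: str
    alt_base: str
    edit_type: str
    level: float
    ref_count: int
    alt_count: int
    sample_id: str
    no_dna_support: bool = False


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    recodable: bool = True

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneModel:
    """Transcript structures of one gene, used for region and codon-effect
    annotation."""

    gene_id: str
    chrom: str
    strand: str
    gene_biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass
class SiteAnnotation:
    """Feature-class assignment (and recoding effect, if CDS) for one site."""

    chrom: str
    pos: int
    strand: str
    edit_type: str
    region_class: str
    gene_id: str | None = None
    gene_biotype: str | None = None
    effect: str = "none"
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    splice_adjacent: bool = False


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start..end] (1-based inclusive) as an uppercase string.

    Accepts a plain dict of chrom -> sequence string or a pyfaidx.Fasta.
    """
    seq = genome[chrom][start - 1 : end]
    return str(seq).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])
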