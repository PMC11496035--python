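"""Evidence layer: quality-filtered, strand-resolved per-site base counts.

Two entry points produce the same tabular pileup representation:

* :func:`pileup_from_sam` — walks alignments (SAM/BAM via pysam), applying
  mapping-quality, base-quality and read-end trimming filters, and infers
  each read's *transcript* strand from the library protocol.
* :func:`pileup_from_tsv` — reads the documented ``editkit-pileup v1``
  TSV dialect (quality filtering assumed already applied upstream).

The in-memory representation is a pandas DataFrame with columns
``chrom, pos, ref, fA, fC, fG, fT, rA, rC, rG, rT``: forward-genome base
counts split by the transcript strand ('f' = '+', 'r' = '-') assigned to
the supporting reads.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from editkit.models import BASES, SitePileup, fetch_seq

logger = logging.getLogger(__name__)

PILEUP_VERSION_HEADER = "# editkit-pileup v1"
COUNT_COLS = ["fA", "fC", "fG", "fT", "rA", "rC", "rG", "rT"]
PILEUP_COLS = ["chrom", "pos", "ref"] + COUNT_COLS


class PileupError(ValueError):
    """Malformed pileup input or reference mismatch."""


@dataclass
class IngestConfig:
    """Read-level filters applied while building pileups.

    Defaults mirror a REDItools-style run: base quality >= 25, mapping
    quality >= 20, the first 6 sequenced bases of every read trimmed, and
    the dUTP 'second read matches transcript strand' protocol.
    """

    min_base_quality: int = 25
    min_mapping_quality: int = 20
    trim_5prime: int = 6
    trim_3prime: int = 0
    strand_protocol: str = "second_read"
    min_variant_reads_emit: int = 2

    def validate(self) -> None:
        for name in ("min_base_quality", "min_mapping_quality", "trim_5prime",
                     "trim_3prime", "min_variant_reads_emit"):
            if getattr(self, name) < 0:
                raise PileupError(f"{name} must be >= 0")
        if self.strand_protocol not in ("second_read", "first_read", "unstranded"):
            raise PileupError(f"unknown strand_protocol {self.strand_protocol!r}")


def _transcript_strand(read: "pysam.AlignedSegment", protocol: str) -> str:
    mapped = "-" if read.is_reverse else "+"
    flipped = "-" if mapped == "+" else "+"
    if protocol == "unstranded":
        return "+"
    if protocol == "second_read":
        if read.is_paired and read.is_read2:
            return mapped
        return flipped  # read1 and single-end reads are antisense
    # first_read
    if read.is_paired and read.is_read2:
        return flipped
    return mapped


def pileup_from_sam(sam_path: str, genome, cfg: IngestConfig | None = None) -> pd.DataFrame:
    """Build a strand-resolved pileup from an alignment file.

    Each surviving aligned base of each kept read contributes one count;
    deletions/reference skips contribute nothing and insertions are
    ignored (``get_aligned_pairs(matches_only=True)``).  Positions with
    zero surviving coverage are omitted.
    """
    cfg = cfg or IngestConfig()
    cfg.validate()
    base_idx = {b: i for i, b in enumerate(BASES)}
    counts: dict[tuple[str, int], np.ndarray] = defaultdict(lambda: np.zeros(8, dtype=int))
    stats: Counter = Counter()

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        known = set(sam.references)
        for read in sam:
            if read.is_unmapped:
                stats["unmapped"] += 1
                continue
            if read.is_secondary or read.is_supplementary:
                stats["secondary_supplementary"] += 1
                continue
            if read.is_duplicate:
                stats["duplicate"] += 1
                continue
            if read.mapping_quality < cfg.min_mapping_quality:
                stats["low_mapq"] += 1
                continue
            chrom = read.reference_name
            if chrom not in genome:
                raise PileupError(f"reference name {chrom!r} missing from genome FASTA")
            strand = _transcript_strand(read, cfg.strand_protocol)
            off = 0 if strand == "+" else 4
            seq = read.query_sequence
            quals = read.query_qualities
            rlen = len(seq)
            lo, hi = cfg.trim_5prime, rlen - cfg.trim_3prime
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                seq_order = (rlen - 1 - qpos) if read.is_reverse else qpos
                if not (lo <= seq_order < hi):
                    stats["trimmed_bases"] += 1
                    continue
                if quals is not None and quals[qpos] < cfg.min_base_quality:
                    stats["low_base_quality"] += 1
                    continue
                base = seq[qpos].upper()
                if base not in base_idx:
                    continue
                counts[(chrom, rpos + 1)][off + base_idx[base]] += 1
            stats["reads_used"] += 1
    logger.info("pileup_from_sam %s: %s", sam_path, dict(stats))

    keys = sorted(counts)
    rows = {
        "chrom": [k[0] for k in keys],
        "pos": [k[1] for k in keys],
        "ref": [fetch_seq(genome, c, p, p) for c, p in keys],
    }
    arr = np.array([counts[k] for k in keys], dtype=int).reshape(len(keys), 8)
    df = pd.DataFrame(rows)
    for j, col in enumerate(COUNT_COLS):
        df[col] = arr[:, j] if len(keys) else np.array([], dtype=int)
    df.attrs["ingest_stats"] = dict(stats)
    return df


def write_pileup_tsv(df: pd.DataFrame, path_or_buf, sample_id: str = "") -> None:
    """Serialize a pileup DataFrame in the ``editkit-pileup v1`` dialect:
    ``chrom pos ref fwdA,C,G,T revA,C,G,T`` after a version header."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(PILEUP_VERSION_HEADER + "\n")
        if sample_id:
            fh.write(f"# sample={sample_id}\n")
        fwd = df[COUNT_COLS[:4]].to_numpy()
        rev = df[COUNT_COLS[4:]].to_numpy()
        for i, r in enumerate(df.itertuples(index=False)):
            f = ",".join(map(str, fwd[i]))
            v = ",".join(map(str, rev[i]))
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{f}\t{v}\n")
    finally:
        if own:
            fh.close()


def pileup_from_tsv(source, genome, cfg: IngestConfig | None = None) -> pd.DataFrame:
    """Parse an ``editkit-pileup v1`` TSV; cross-checks every reference
    base against the genome and raises :class:`PileupError` (with the
    offending line number) on any malformed row."""
    own = isinstance(source, (str, bytes)) or hasattr(source, "__fspath__")
    fh = open(source) if own else source
    sample_id = ""
    rows = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# sample="):
                    sample_id = line.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise PileupError(f"line {lineno}: expected 5 tab-separated fields")
            chrom, pos_s, ref, fwd_s, rev_s = parts
            try:
                pos = int(pos_s)
                fwd = [int(x) for x in fwd_s.split(",")]
                rev = [int(x) for x in rev_s.split(",")]
                if len(fwd) != 4 or len(rev) != 4 or min(fwd + rev) < 0:
                    raise ValueError
            except ValueError:
                raise PileupError(f"line {lineno}: malformed counts or position") from None
            if chrom not in genome:
                raise PileupError(f"line {lineno}: unknown chromosome {chrom!r}")
            genome_ref = fetch_seq(genome, chrom, pos, pos)
            if ref.upper() != genome_ref:
                raise PileupError(
                    f"line {lineno}: ref base {ref} at {chrom}:{pos} "
                    f"disagrees with genome ({genome_ref})"
                )
            rows.append([chrom, pos, ref.upper()] + fwd + rev)
    finally:
        if own:
            fh.close()
    df = pd.DataFrame(rows, columns=PILEUP_COLS)
    df["pos"] = df["pos"].astype(int) if len(df) else df.get("pos", pd.Series(dtype=int))
    df.attrs["sample_id"] = sample_id
    return df


def iter_sitepileups(df: pd.DataFrame, sample_id: str = ""):
    """Yield :class:`SitePileup` records from the tabular representation."""
    for r in df.itertuples(index=False):
        yield SitePileup(
            chrom=r.chrom,
            pos=int(r.pos),
            ref_base=r.ref,
            counts_fwd={b: int(getattr(r, "f" + b)) for b in BASES},
            counts_rev={b: int(getattr(r, "r" + b)) for b in BASES},
            sample_id=sample_id,
        )
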