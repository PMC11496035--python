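"""Sequence context around editing sites: the +/-10 bp base-frequency
matrix behind the classic A-to-I logo (upstream-G depletion, downstream-G
enrichment), in editing-strand orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from editkit.models import BASES, chrom_length, fetch_seq, revcomp

logger = logging.getLogger(__name__)


class ContextError(ValueError):
    pass


@dataclass
class ContextMatrix:
    """Per-position base frequencies over (2*width + 1) positions centred
    on the edited base (position 0)."""

    counts: pd.DataFrame  # positions x bases, integer counts
    frequencies: pd.DataFrame  # positions x bases, rows sum to 1
    site_count: int
    n_dropped: int
    width: int


def extract_context(sites, genome, width: int = 10) -> ContextMatrix:
    """Count bases at each offset in [-width, +width] around the sites.

    ``sites`` is an iterable (or DataFrame) with chrom/pos/strand; for
    minus-strand sites the window is reverse complemented so that
    position 0 is the edited A in transcript orientation.  Windows
    truncated by a chromosome end are dropped (counted and logged).
    """
    if isinstance(sites, pd.DataFrame):
        if "edit_type" in sites.columns and sites["edit_type"].nunique() > 1:
            raise ContextError("sites must all share one edit_type")
        records = list(sites.itertuples(index=False))
    else:
        records = list(sites)
    if not records:
        raise ContextError("no sites supplied")

    offsets = np.arange(-width, width + 1)
    base_idx = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((2 * width + 1, 4), dtype=int)
    used = dropped = 0
    for r in records:
        pos = int(r.pos)
        lo, hi = pos - width, pos + width
        if lo < 1 or hi > chrom_length(genome, r.chrom):
            dropped += 1
            continue
        seq = fetch_seq(genome, r.chrom, lo, hi)
        if r.strand == "-":
            seq = revcomp(seq)
        for i, b in enumerate(seq):
            if b in base_idx:
                counts[i, base_idx[b]] += 1
        used += 1
    if used == 0:
        raise ContextError(
            f"all {dropped} site window(s) truncated by chromosome ends"
        )
    if dropped:
        logger.info("extract_context: dropped %d truncated window(s)", dropped)
    counts_df = pd.DataFrame(counts, index=offsets, columns=list(BASES))
    with np.errstate(invalid="ignore"):
        freq = counts / counts.sum(axis=1, keepdims=True)
    freq_df = pd.DataFrame(freq, index=offsets, columns=list(BASES))
    return ContextMatrix(counts_df, freq_df, used, dropped, width)


def genome_base_composition(genome) -> dict[str, float]:
    """Genome-wide mononucleotide frequencies (the default enrichment
    background)."""
    totals = {b: 0 for b in BASES}
    for chrom in genome.keys() if hasattr(genome, "keys") else genome:
        seq = fetch_seq(genome, chrom, 1, chrom_length(genome, chrom))
        for b in BASES:
            totals[b] += seq.count(b)
    n = sum(totals.values())
    if n == 0:
        raise ContextError("empty genome")
    return {b: c / n for b, c in totals.items()}


def context_enrichment(
    matrix: ContextMatrix,
    background: dict[str, float],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-position log2(observed/background) base enrichment.

    Position 0 (the invariant edited base) is excluded.  Zero observed
    counts are replaced by ``pseudocount`` before forming frequencies, so
    exact agreement with the background yields exactly 0.
    """
    bg = np.array([background[b] for b in BASES], dtype=float)
    if np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ContextError("background frequencies must be positive and sum to 1")
    counts = matrix.counts.to_numpy(dtype=float)
    counts = np.where(counts == 0, pseudocount, counts)
    freq = counts / matrix.site_count
    ratios = np.log2(freq / bg)
    out = pd.DataFrame(ratios, index=matrix.counts.index, columns=list(BASES))
    return out.drop(index=0)
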