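"""miRanda-style miRNA target scanning and gain/loss under A-to-G editing.

The scorer is a documented surrogate for miRanda's complementarity
scan: a local (Smith-Waterman, affine-gap) alignment of the reversed
miRNA against the target, Watson-Crick matches +5, G:U wobbles +2,
mismatches -3, gap open/extend -8/-2, with seed positions (2-8 from the
miRNA 5' end) weighted x4 and no match credit for miRNA position 1 or
positions beyond 19.  A surrogate duplex energy
``-(3.0*GC + 2.0*AU + 1.0*GU) * 0.5`` (kcal/mol-like) accompanies each
hit.  Default thresholds: score >= 140 and energy <= -10.  Tests rely on
relative behaviour and oracle equivalence, never on matching miRanda's
exact numbers.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

_WC = {("A", "U"), ("T", "A"), ("G", "C"), ("C", "G")}  # (target DNA, miRNA RNA)
_GU = {("G", "U"), ("T", "G")}


class MirnaError(ValueError):
    pass


@dataclass
class ScanConfig:
    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_start: int = 2
    seed_end: int = 8
    seed_weight: float = 4.0
    credit_start: int = 2
    credit_end: int = 19
    score_threshold: float = 140.0
    energy_threshold: float = -10.0
    gc_energy: float = 3.0
    au_energy: float = 2.0
    gu_energy: float = 1.0
    energy_scale: float = 0.5
    window: int = 10
    full_utr: bool = False
    min_mirna_len: int = 18
    max_mirna_len: int = 26


@dataclass
class AlignedPair:
    target_pos: int | None  # 1-based in the scanned sequence
    mirna_pos: int | None  # 1-based from the miRNA 5' end
    kind: str  # WC | GU | mismatch | gap


@dataclass
class DuplexHit:
    mirna_id: str
    target_id: str
    alignment: list[AlignedPair]
    score: float
    energy: float
    target_start: int  # 1-based inclusive window on the target
    target_end: int


@dataclass
class TargetDelta:
    chrom: str
    pos: int
    strand: str
    gene_id: str | None
    lost: set[str] = field(default_factory=set)
    gained: set[str] = field(default_factory=set)
    scores: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)


def normalize_target(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if any(b not in "ACGT" for b in s):
        raise MirnaError(f"invalid target alphabet in {seq[:30]!r}...")
    return s


def normalize_mirna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if any(b not in "ACGU" for b in s):
        raise MirnaError(f"invalid miRNA alphabet in {seq[:30]!r}...")
    return s


def read_mirnas(source: str) -> dict[str, str]:
    """Parse a (miRbase-dialect) miRNA FASTA, path or text, into
    {id: RNA sequence}; the id is the first header token."""
    if "\n" in source or source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    else:
        handle = open(source)
    with handle:
        return {
            rec.id: normalize_mirna(str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")
        }


def _pair_kind(t: str, m: str) -> str:
    if (t, m) in _WC:
        return "WC"
    if (t, m) in _GU:
        return "GU"
    return "mismatch"


def _pair_score(kind: str, p: int, cfg: ScanConfig) -> float:
    w = cfg.seed_weight if cfg.seed_start <= p <= cfg.seed_end else 1.0
    credit = cfg.credit_start <= p <= cfg.credit_end
    if kind == "WC":
        return w * cfg.match if credit else 0.0
    if kind == "GU":
        return w * cfg.wobble if credit else 0.0
    return w * cfg.mismatch


def _best_local(target: str, mirna: str, cfg: ScanConfig):
    """Best local alignment of the reversed miRNA against ``target``.

    Returns (score, alignment, t_start, t_end) with 1-based inclusive
    target coordinates, or None if no positive-scoring alignment exists.
    Ties are resolved toward the leftmost, shortest alignment.
    """
    n, m = len(target), len(mirna)
    r = mirna[::-1]  # r[j-1] is miRNA position m - j + 1
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming miRNA
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming target
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop, 1 diag, 2 E, 3 F
    eptr = [[0] * (m + 1) for _ in range(n + 1)]  # 1 open, 2 extend
    fptr = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ti = target[i - 1]
        for j in range(1, m + 1):
            p = m - j + 1
            kind = _pair_kind(ti, r[j - 1])
            diag = H[i - 1][j - 1] + _pair_score(kind, p, cfg)
            e_open = H[i][j - 1] + cfg.gap_open
            e_ext = E[i][j - 1] + cfg.gap_extend
            if e_open >= e_ext:
                E[i][j], eptr[i][j] = e_open, 1
            else:
                E[i][j], eptr[i][j] = e_ext, 2
            f_open = H[i - 1][j] + cfg.gap_open
            f_ext = F[i - 1][j] + cfg.gap_extend
            if f_open >= f_ext:
                F[i][j], fptr[i][j] = f_open, 1
            else:
                F[i][j], fptr[i][j] = f_ext, 2
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h == 0.0:
                ptr[i][j] = 0
            elif h == diag:
                ptr[i][j] = 1
            elif h == E[i][j]:
                ptr[i][j] = 2
            else:
                ptr[i][j] = 3
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return None
    # traceback
    pairs: list[AlignedPair] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            d = ptr[i][j]
            if d == 0:
                break
            if d == 1:
                kind = _pair_kind(target[i - 1], r[j - 1])
                pairs.append(AlignedPair(i, m - j + 1, kind))
                i, j = i - 1, j - 1
            elif d == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            pairs.append(AlignedPair(None, m - j + 1, "gap"))
            came = eptr[i][j]
            j -= 1
            state = "H" if came == 1 else "E"
        else:
            pairs.append(AlignedPair(i, None, "gap"))
            came = fptr[i][j]
            i -= 1
            state = "H" if came == 1 else "F"
    pairs.reverse()
    tpos = [p.target_pos for p in pairs if p.target_pos is not None]
    return best, pairs, min(tpos), max(tpos)


def _energy(pairs: list[AlignedPair], target: str, mirna: str, cfg: ScanConfig) -> float:
    total = 0.0
    for p in pairs:
        if p.target_pos is None or p.mirna_pos is None:
            continue
        t = target[p.target_pos - 1]
        m = mirna[p.mirna_pos - 1]
        kind = _pair_kind(t, m)
        if kind == "WC":
            total += cfg.gc_energy if {t, m} == {"G", "C"} or {t, m} == {"C", "G"} else cfg.au_energy
        elif kind == "GU":
            total += cfg.gu_energy
    return -cfg.energy_scale * total


def _scan_one(target: str, mirna: str, cfg: ScanConfig):
    """All non-overlapping candidate alignments with score >= threshold."""
    results = []

    def recurse(seg_start: int, seg_end: int):  # 0-based half-open on target
        if seg_end - seg_start < 1:
            return
        sub = target[seg_start:seg_end]
        hit = _best_local(sub, mirna, cfg)
        if hit is None:
            return
        score, pairs, ts, te = hit
        if score < cfg.score_threshold:
            return
        for p in pairs:
            if p.target_pos is not None:
                p.target_pos += seg_start
        results.append((score, pairs, ts + seg_start, te + seg_start))
        recurse(seg_start, seg_start + ts - 1)
        recurse(seg_start + te, seg_end)

    recurse(0, len(target))
    return results


def scan_duplexes(
    mirnas,
    target_seq: str,
    cfg: ScanConfig | None = None,
    target_id: str = "",
) -> list[DuplexHit]:
    """Scan each miRNA against the target; return hits passing both the
    score and energy thresholds, sorted by score descending (ties by
    leftmost target position)."""
    cfg = cfg or ScanConfig()
    if isinstance(mirnas, str):
        mirnas = read_mirnas(mirnas)
    target = normalize_target(target_seq)
    hits: list[DuplexHit] = []
    for mid, mseq in mirnas.items():
        mseq = normalize_mirna(mseq)
        if not (cfg.min_mirna_len <= len(mseq) <= cfg.max_mirna_len):
            raise MirnaError(
                f"miRNA {mid} length {len(mseq)} outside "
                f"[{cfg.min_mirna_len}, {cfg.max_mirna_len}]"
            )
        for score, pairs, ts, te in _scan_one(target, mseq, cfg):
            energy = _energy(pairs, target, mseq, cfg)
            if energy <= cfg.energy_threshold:
                hits.append(DuplexHit(mid, target_id, pairs, score, energy, ts, te))
    hits.sort(key=lambda h: (-h.score, h.target_start, h.mirna_id))
    return hits


def delta_targets(
    site,
    utr_seq: str,
    site_index: int,
    mirnas,
    cfg: ScanConfig | None = None,
    gene_id: str | None = None,
) -> TargetDelta:
    """Lost/gained miRNA targets when the edited base is substituted.

    ``utr_seq`` is the 3' UTR in transcript orientation and
    ``site_index`` the 0-based index of the edited A within it.  Only
    hits whose target window overlaps the edited position count toward
    the delta.  By default scanning is restricted to the +/-``window``
    bp around the site; set ``cfg.full_utr`` to scan the whole UTR.
    """
    cfg = cfg or ScanConfig()
    if isinstance(mirnas, str):
        mirnas = read_mirnas(mirnas)
    seq = normalize_target(utr_seq)
    if not (0 <= site_index < len(seq)):
        raise MirnaError("site_index outside the UTR sequence")
    if seq[site_index] != normalize_target(site.ref_base if hasattr(site, "ref_base") else site.ref):
        raise MirnaError(
            f"UTR base {seq[site_index]} at site_index does not match the site ref"
        )
    alt = normalize_target(site.alt_base if hasattr(site, "alt_base") else site.alt)
    if cfg.full_utr:
        sub, idx = seq, site_index
    else:
        lo = max(0, site_index - cfg.window)
        sub = seq[lo : site_index + cfg.window + 1]
        idx = site_index - lo
    edited = sub[:idx] + alt + sub[idx + 1 :]

    def overlapping(target: str) -> dict[str, DuplexHit]:
        out: dict[str, DuplexHit] = {}
        for h in scan_duplexes(mirnas, target, cfg, target_id=gene_id or ""):
            if h.target_start <= idx + 1 <= h.target_end and h.mirna_id not in out:
                out[h.mirna_id] = h
        return out

    before = overlapping(sub)
    after = overlapping(edited)
    delta = TargetDelta(
        chrom=site.chrom,
        pos=int(site.pos),
        strand=site.strand,
        gene_id=gene_id,
        lost=set(before) - set(after),
        gained=set(after) - set(before),
    )
    for mid in set(before) | set(after):
        b = before.get(mid)
        a = after.get(mid)
        delta.scores[mid] = (b.score if b else None, a.score if a else None)
    return delta


def predict_targets(
    mirnas,
    utr_sequences: dict[str, str],
    cfg: ScanConfig | None = None,
) -> dict[str, list[str]]:
    """Per-miRNA target gene lists: genes whose UTR carries >= 1 passing
    hit anywhere (set semantics, sorted)."""
    cfg = cfg or ScanConfig()
    if isinstance(mirnas, str):
        mirnas = read_mirnas(mirnas)
    out: dict[str, set[str]] = {mid: set() for mid in mirnas}
    for gene, seq in utr_sequences.items():
        for hit in scan_duplexes(mirnas, seq, cfg, target_id=gene):
            out[hit.mirna_id].add(gene)
    return {mid: sorted(genes) for mid, genes in out.items()}


def utr3_sequence(gene, genome) -> tuple[str, dict[int, int]]:
    """Spliced 3' UTR sequence of a gene's first UTR-bearing transcript in
    transcript orientation, plus a genomic-position -> index map."""
    from editkit.models import fetch_seq, revcomp

    for tx in gene.transcripts:
        if tx.utr3:
            positions: list[int] = []
            for s, e in tx.utr3:
                positions.extend(range(s, e + 1))
            seq = "".join(fetch_seq(genome, gene.chrom, s, e) for s, e in tx.utr3)
            if gene.strand == "-":
                seq = revcomp(seq)
                positions = positions[::-1]
            return seq, {p: i for i, p in enumerate(positions)}
    raise MirnaError(f"gene {gene.gene_id} has no annotated 3' UTR")
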