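"""Editing-site calling, SNP masking and cross-sample aggregation.

The per-sample caller applies the classic REDItools-style cascade on
strand-resolved pileups: minimum RNA coverage, a single alternative base
with enough supporting reads, an editing-level window, and (when DNA
evidence exists at the position) adequate DNA coverage with no DNA
variant reads.  Sites are reported in transcript orientation, so a
forward-genome T>C observation on a minus-strand gene is an A>G site.

Aggregation unions site keys across samples, drops keys supported by
fewer than ``min_samples`` calling samples, and encodes each cell of the
resulting sites x samples matrix as: the editing level when called, 0.0
when the sample had adequate coverage but no variant, or missing (NaN)
when coverage was insufficient.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from editkit.models import BASES, comp
from editkit.pileup import COUNT_COLS

logger = logging.getLogger(__name__)

SITE_COLS = [
    "chrom", "pos", "strand", "ref", "alt", "edit_type",
    "ref_count", "alt_count", "level", "no_dna_support", "sample_id",
]
KEY_COLS = ["chrom", "pos", "strand", "edit_type"]


class DetectError(ValueError):
    pass


@dataclass
class DetectConfig:
    """Filter cascade thresholds (RNA coverage >= 10, DNA coverage >= 5,
    >= 2 RNA variant reads, 0 DNA variant reads, level in [0.01, 0.95],
    support in >= 3 samples)."""

    min_rna_coverage: int = 10
    min_dna_coverage: int = 5
    min_variant_reads: int = 2
    max_dna_variant_reads: int = 0
    min_level: float = 0.01
    max_level: float = 0.95
    min_samples: int = 3

    def validate(self) -> None:
        if not (0.0 <= self.min_level <= self.max_level <= 1.0):
            raise DetectError("require 0 <= min_level <= max_level <= 1")
        for name in ("min_rna_coverage", "min_dna_coverage", "min_variant_reads",
                     "max_dna_variant_reads", "min_samples"):
            if getattr(self, name) < 0:
                raise DetectError(f"{name} must be >= 0")


def classify_type(ref_base: str, alt_base: str, strand: str) -> str:
    """Ordered ref>alt substitution code in transcript orientation.

    Enumerating all 4x3 ordered pairs yields the 12 canonical codes;
    (T, C, '-') maps to "AG" via reverse complement.
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref not in BASES or alt not in BASES:
        raise DetectError(f"invalid bases {ref_base!r}->{alt_base!r}")
    if ref == alt:
        raise DetectError("ref and alt bases must differ")
    if strand not in "+-":
        raise DetectError(f"invalid strand {strand!r}")
    if strand == "-":
        ref, alt = comp(ref), comp(alt)
    return ref + alt


def call_sites(
    rna: pd.DataFrame,
    dna: pd.DataFrame | None,
    cfg: DetectConfig | None = None,
    sample_id: str = "",
) -> pd.DataFrame:
    """Call candidate editing sites in one sample.

    Returns a DataFrame with :data:`SITE_COLS`; per-rule rejection counts
    are logged and attached as ``df.attrs['rejections']``.
    """
    cfg = cfg or DetectConfig()
    cfg.validate()
    rej: Counter = Counter()
    if len(rna):
        known = rna["ref"].isin(list(BASES))
        if not known.all():
            rej["ambiguous_ref"] = int((~known).sum())
            rna = rna[known].reset_index(drop=True)
    if rna.empty:
        out = pd.DataFrame(columns=SITE_COLS)
        out.attrs["rejections"] = dict(rej)
        return out

    F = rna[COUNT_COLS[:4]].to_numpy(dtype=int)
    R = rna[COUNT_COLS[4:]].to_numpy(dtype=int)
    minus = R.sum(axis=1) > F.sum(axis=1)  # majority strand; ties go to '+'
    C = np.where(minus[:, None], R, F)
    cov = C.sum(axis=1)

    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_idx = rna["ref"].map(base_idx).to_numpy()
    n = len(rna)
    rows = np.arange(n)
    ref_count = C[rows, ref_idx]
    altC = C.copy()
    altC[rows, ref_idx] = 0
    n_pass = (altC >= cfg.min_variant_reads).sum(axis=1)
    alt_idx = altC.argmax(axis=1)
    alt_count = altC[rows, alt_idx]
    denom = ref_count + alt_count
    level = np.divide(alt_count, denom, out=np.zeros(n, float), where=denom > 0)

    ok_cov = cov >= cfg.min_rna_coverage
    ok_uni = n_pass == 1
    ok_lvl = (level >= cfg.min_level) & (level <= cfg.max_level)

    # DNA evidence: total coverage and reads supporting the RNA alt base
    no_dna = np.ones(n, dtype=bool)
    ok_dna = np.ones(n, dtype=bool)
    if dna is not None and len(dna):
        d = dna.copy()
        dF = d[COUNT_COLS[:4]].to_numpy(dtype=int)
        dR = d[COUNT_COLS[4:]].to_numpy(dtype=int)
        dtot = dF + dR
        d_by_pos = {
            (c, int(p)): dtot[i]
            for i, (c, p) in enumerate(zip(d["chrom"], d["pos"]))
        }
        dcov = np.zeros(n, dtype=int)
        dalt = np.zeros(n, dtype=int)
        for i, (c, p) in enumerate(zip(rna["chrom"], rna["pos"])):
            row = d_by_pos.get((c, int(p)))
            if row is None:
                continue
            no_dna[i] = False
            dcov[i] = row.sum()
            dalt[i] = row[alt_idx[i]]
        ok_dna = no_dna | ((dcov >= cfg.min_dna_coverage) & (dalt <= cfg.max_dna_variant_reads))

    emit = ok_cov & ok_uni & ok_lvl & ok_dna & (alt_count >= cfg.min_variant_reads)

    rej["low_coverage"] = int((~ok_cov).sum())
    rej["no_variant"] = int((ok_cov & (n_pass == 0)).sum())
    rej["multiallelic"] = int((ok_cov & (n_pass > 1)).sum())
    rej["level_out_of_range"] = int((ok_cov & ok_uni & ~ok_lvl).sum())
    rej["dna_filtered"] = int((ok_cov & ok_uni & ok_lvl & ~ok_dna).sum())
    logger.info("call_sites %s: emitted %d, rejections %s", sample_id, int(emit.sum()), dict(rej))

    idx = np.nonzero(emit)[0]
    strands = np.where(minus, "-", "+")
    refs, alts, types = [], [], []
    for i in idx:
        r = BASES[ref_idx[i]]
        a = BASES[alt_idx[i]]
        if minus[i]:
            r, a = comp(r), comp(a)
        refs.append(r)
        alts.append(a)
        types.append(r + a)
    out = pd.DataFrame(
        {
            "chrom": rna["chrom"].to_numpy()[idx],
            "pos": rna["pos"].to_numpy()[idx].astype(int),
            "strand": strands[idx],
            "ref": refs,
            "alt": alts,
            "edit_type": types,
            "ref_count": ref_count[idx],
            "alt_count": alt_count[idx],
            "level": level[idx],
            "no_dna_support": no_dna[idx],
            "sample_id": sample_id,
        }
    )
    out.attrs["rejections"] = dict(rej)
    return out


def _positions_from_vcf(path: str) -> set[tuple[str, int]]:
    out = set()
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            out.add((rec.chrom, rec.pos))
    return out


def _positions_from_bed(path: str) -> set[tuple[str, int]]:
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DetectError(f"malformed BED line in {path}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            for p in range(start + 1, end + 1):  # BED is 0-based half-open
                out.add((chrom, p))
    return out


def mask_snps(sites: pd.DataFrame, snp_sources: list[str]) -> pd.DataFrame:
    """Remove sites whose (chrom, pos) appears in any VCF/BED source.

    Masking is position-based and allele-agnostic (interval intersection
    semantics).  Removal counts per source are logged and attached as
    ``df.attrs['mask_log']``.
    """
    removed_log = {}
    keep = pd.Series(True, index=sites.index)
    for src in snp_sources:
        s = str(src)
        if s.endswith((".bed", ".bed.gz")):
            positions = _positions_from_bed(s)
        else:
            positions = _positions_from_vcf(s)
        hit = sites.apply(lambda r: (r["chrom"], int(r["pos"])) in positions, axis=1) \
            if len(sites) else pd.Series(dtype=bool)
        n = int(hit.sum()) if len(sites) else 0
        removed_log[s] = n
        if len(sites):
            keep &= ~hit
        logger.info("mask_snps: %d sites removed by %s", n, s)
    out = sites[keep].reset_index(drop=True) if len(sites) else sites.copy()
    out.attrs["mask_log"] = removed_log
    return out


class EditingMatrix:
    """Sites x samples editing-level matrix with missingness semantics.

    ``levels``: DataFrame indexed by (chrom, pos, strand, edit_type) with
    one column per sample; cells hold the editing level, 0.0 for
    'covered but no variant', NaN for 'insufficient coverage'.
    ``called``: same shape, True where the site passed per-sample calling.
    """

    def __init__(
        self,
        levels: pd.DataFrame,
        called: pd.DataFrame,
        stages: dict[str, str],
        calls: pd.DataFrame | None = None,
    ):
        self.levels = levels
        self.called = called
        self.stages = dict(stages)
        self.calls = calls if calls is not None else pd.DataFrame(columns=SITE_COLS)

    @property
    def samples(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def site_keys(self) -> pd.MultiIndex:
        return self.levels.index

    def n_sites(self) -> int:
        return len(self.levels)

    def stage_samples(self, stage: str) -> list[str]:
        return [s for s in self.samples if self.stages[s] == stage]

    def subset_type(self, edit_type: str) -> "EditingMatrix":
        mask = self.levels.index.get_level_values("edit_type") == edit_type
        return EditingMatrix(
            self.levels[mask],
            self.called[mask],
            self.stages,
            self.calls[self.calls["edit_type"] == edit_type].reset_index(drop=True)
            if len(self.calls) else self.calls,
        )

    def mean_levels(self) -> pd.Series:
        """Across-sample mean level per site (NaN cells excluded)."""
        return self.levels.mean(axis=1, skipna=True)

    def to_frame(self) -> pd.DataFrame:
        out = self.levels.reset_index()
        out.insert(4, "n_called", self.called.sum(axis=1).to_numpy())
        return out

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        """Serialize levels + called flags + stage map to one TSV."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(line.rstrip("\n") + "\n")
            fh.write("# stages: " + ",".join(f"{s}={st}" for s, st in self.stages.items()) + "\n")
            cols = KEY_COLS + [f"level_{s}" for s in self.samples] + [
                f"called_{s}" for s in self.samples
            ]
            fh.write("\t".join(cols) + "\n")
            for key in self.levels.index:
                lv = [
                    "NA" if pd.isna(v) else f"{v:.6g}"
                    for v in self.levels.loc[key]
                ]
                cl = ["1" if v else "0" for v in self.called.loc[key]]
                fh.write("\t".join(map(str, key)) + "\t" + "\t".join(lv + cl) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "EditingMatrix":
        stages: dict[str, str] = {}
        header: list[str] | None = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# stages:"):
                    for part in line.split(":", 1)[1].strip().split(","):
                        s, st = part.split("=")
                        stages[s] = st
                    continue
                if line.startswith("#") or not line:
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                rows.append(line.split("\t"))
        if header is None:
            raise DetectError(f"no header row in {path}")
        samples = [c[len("level_"):] for c in header if c.startswith("level_")]
        keys, lvl, cld = [], [], []
        for r in rows:
            keys.append((r[0], int(r[1]), r[2], r[3]))
            vals = r[4 : 4 + len(samples)]
            lvl.append([np.nan if v == "NA" else float(v) for v in vals])
            cld.append([v == "1" for v in r[4 + len(samples) :]])
        idx = pd.MultiIndex.from_tuples(keys, names=KEY_COLS)
        return cls(
            pd.DataFrame(lvl, index=idx, columns=samples),
            pd.DataFrame(cld, index=idx, columns=samples),
            stages,
        )


def aggregate(
    sample_calls: dict[str, pd.DataFrame],
    coverage: dict[str, pd.DataFrame],
    stage_map: dict[str, str],
    cfg: DetectConfig | None = None,
) -> EditingMatrix:
    """Union per-sample calls into an :class:`EditingMatrix`.

    ``coverage`` supplies each sample's pileup so that non-called cells
    can be classified as 'covered' (level 0.0) versus 'missing'.
    Conflicting (strand, edit_type) at one position are resolved by most
    supporting samples, then total alt reads, then lexicographic code.
    """
    cfg = cfg or DetectConfig()
    cfg.validate()
    for sample in sample_calls:
        if sample not in stage_map:
            raise DetectError(f"sample {sample!r} missing from stage map")

    frames = []
    for sample, df in sample_calls.items():
        d = df.copy()
        d["sample_id"] = sample
        frames.append(d)
    allcalls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SITE_COLS)
    samples = list(sample_calls)

    if len(allcalls):
        # resolve edit-type conflicts per position
        grp = allcalls.groupby(["chrom", "pos", "strand", "edit_type"]).agg(
            n_samples=("sample_id", "nunique"), total_alt=("alt_count", "sum")
        ).reset_index()
        conflicts = grp.groupby(["chrom", "pos"]).size()
        n_conflict = int((conflicts > 1).sum())
        if n_conflict:
            logger.info("aggregate: %d positions with conflicting edit types", n_conflict)
        winners = (
            grp.sort_values(
                ["chrom", "pos", "n_samples", "total_alt", "edit_type"],
                ascending=[True, True, False, False, True],
            )
            .groupby(["chrom", "pos"], sort=False)
            .head(1)
        )
        allcalls = allcalls.merge(
            winners[["chrom", "pos", "strand", "edit_type"]],
            on=["chrom", "pos", "strand", "edit_type"],
        )
        support = allcalls.groupby(KEY_COLS)["sample_id"].nunique()
        kept_keys = support[support >= cfg.min_samples].index
    else:
        kept_keys = pd.MultiIndex.from_tuples([], names=KEY_COLS)

    kept_keys = pd.MultiIndex.from_tuples(sorted(kept_keys), names=KEY_COLS)
    levels = pd.DataFrame(np.nan, index=kept_keys, columns=samples)
    called = pd.DataFrame(False, index=kept_keys, columns=samples)
    if len(allcalls):
        kept_calls = allcalls.set_index(KEY_COLS).loc[
            allcalls.set_index(KEY_COLS).index.isin(kept_keys)
        ].reset_index()
        for r in kept_calls.itertuples(index=False):
            key = (r.chrom, r.pos, r.strand, r.edit_type)
            levels.at[key, r.sample_id] = r.level
            called.at[key, r.sample_id] = True
    else:
        kept_calls = allcalls

    # fill covered-but-not-called cells with 0.0
    for sample in samples:
        pile = coverage.get(sample)
        if pile is None or not len(pile):
            continue
        tot = pile[COUNT_COLS].sum(axis=1)
        cov_by_pos = {
            (c, int(p)): int(t) for c, p, t in zip(pile["chrom"], pile["pos"], tot)
        }
        col = levels[sample]
        for key in levels.index[col.isna()]:
            c = cov_by_pos.get((key[0], int(key[1])), 0)
            if c >= cfg.min_rna_coverage:
                levels.at[key, sample] = 0.0

    return EditingMatrix(levels, called, stage_map, kept_calls)
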