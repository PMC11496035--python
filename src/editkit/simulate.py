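"""Planted-truth simulator for A-to-I editing analyses.

Generates a self-consistent miniature dataset: a random genome with
multi-exon genes on both strands, a GTF annotation, planted editing
sites of several classes (constitutive, stage-specific, differential),
SNP confounders with DNA support, stranded per-sample RNA pileups,
a DNA control pileup, a VCF of the confounders, engineered miRNAs whose
seed match appears or disappears upon A-to-G substitution, and optional
SAM reads.

Design of the stated world
--------------------------
Three differentiation stages (GM, DM1, DM5) with three stranded RNA-seq
replicates each, plus one DNA-seq control, mirror the experimental
design being emulated.  Read coverage is Poisson around the configured
mean; at a planted site with true level p the alternative-base count is
Binomial(coverage, p); elsewhere a symmetric error floor applies.
RNA coverage is restricted to gene bodies (pre-mRNA, uniform); the DNA
control covers the same positions and shows variant reads only at the
planted SNP confounders.
"""

from __future__ import annotations

import itertools
import logging
from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from editkit.models import BASES, GeneModel, Transcript, comp

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOP_CODONS
)
_WC_PARTNER = {"A": "U", "C": "G", "G": "C", "T": "A"}  # target DNA -> miRNA RNA
# target:miRNA wobble pairs (G:U and U:G, with the target in DNA alphabet)
_WOBBLE = {("G", "U"), ("T", "G")}

MIN_SITE_SPACING = 25  # bp between planted positions; keeps context windows clean
UTR3_MARGIN = 12  # bp kept clear of 3' UTR edges for engineered miRNA windows


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid or infeasible."""


def default_level_profiles(stages: tuple[str, ...]) -> dict[str, dict[str, float]]:
    profiles: dict[str, dict[str, float]] = {
        "constitutive": {s: 0.3 for s in stages},
        "snp_confounder": {s: 0.5 for s in stages},
    }
    for s in stages:
        profiles[f"stage_specific:{s}"] = {t: (0.4 if t == s else 0.0) for t in stages}
    levels = np.linspace(0.1, 0.9, num=len(stages))
    profiles["differential"] = {s: float(v) for s, v in zip(stages, levels)}
    return profiles


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 12
    n_edit_sites: int = 300
    n_snps: int = 100
    stages: tuple[str, ...] = ("GM", "DM1", "DM5")
    replicates_per_stage: int = 3
    rna_coverage_mean: float = 100.0
    dna_coverage_mean: float = 30.0
    error_rate: float = 0.001
    level_profiles: dict[str, dict[str, float]] | None = None
    context_bias: dict[str, float] | None = None  # {"upstream_g": .., "downstream_g": ..}
    n_mirna_gain: int = 8
    n_mirna_lost: int = 8
    n_recoding: int = 60
    n_decoy_mirnas: int = 4
    read_length: int = 75
    mapq: int = 60
    base_quality: int = 40
    strand_protocol: str = "second_read"

    def validate(self) -> None:
        errs = []
        for name in ("n_chroms", "n_genes", "n_edit_sites", "n_snps",
                     "n_mirna_gain", "n_mirna_lost", "n_recoding"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be nonnegative")
        if self.chrom_length < 10_000:
            errs.append("chrom_length must be >= 10000 so genes with introns/UTRs fit")
        if len(set(self.stages)) != len(self.stages):
            errs.append("stage labels must be unique")
        if self.replicates_per_stage < 2:
            errs.append("replicates_per_stage must be >= 2")
        if not (0.0 <= self.error_rate <= 0.05):
            errs.append("error_rate must be in [0, 0.05]")
        if self.rna_coverage_mean <= 0 or self.dna_coverage_mean <= 0:
            errs.append("coverage means must be positive")
        if self.strand_protocol not in ("second_read", "first_read", "unstranded"):
            errs.append(f"unknown strand_protocol {self.strand_protocol!r}")
        profiles = self.level_profiles or default_level_profiles(tuple(self.stages))
        for cls, prof in profiles.items():
            for stage, lv in prof.items():
                if not (0.0 <= lv <= 1.0):
                    errs.append(f"level_profiles[{cls}][{stage}] = {lv} outside [0, 1]")
        if errs:
            raise SimConfigError("; ".join(errs))

    def profiles(self) -> dict[str, dict[str, float]]:
        return self.level_profiles or default_level_profiles(tuple(self.stages))

    def sample_ids(self) -> dict[str, str]:
        """Ordered sample -> stage mapping (GM_1 .. DM5_3 by default)."""
        return {
            f"{stage}_{rep}": stage
            for stage in self.stages
            for rep in range(1, self.replicates_per_stage + 1)
        }


@dataclass
class _SimGene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]]
    u5_len: int
    cds_len: int
    u3_len: int
    txpos: list[int]  # genomic positions in transcript 5'->3' order

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tlen(self) -> int:
        return len(self.txpos)


@dataclass
class SimulatedData:
    rna_pileups: dict[str, pd.DataFrame]
    dna_pileup: pd.DataFrame
    vcf_text: str
    mirna_fasta: str
    samples: dict[str, str]


def _runs_to_segments(positions: list[int]) -> list[tuple[int, int]]:
    """Collapse sorted genomic positions into 1-based inclusive segments."""
    segs: list[tuple[int, int]] = []
    for p in positions:
        if segs and p == segs[-1][1] + 1:
            segs[-1] = (segs[-1][0], p)
        else:
            segs.append((p, p))
    return segs


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


class Simulator:
    """Stateful generator: call :meth:`simulate_reference`,
    :meth:`plant_sites`, then :meth:`simulate_pileups` (and optionally
    :meth:`write_sam`).  Each step is deterministic under ``cfg.seed``."""

    def __init__(self, cfg: SimConfig):
        cfg.validate()
        self.cfg = cfg
        self.genome: dict[str, list[str]] = {}
        self.genes: list[_SimGene] = []
        self.models: list[GeneModel] = []
        self.truth: pd.DataFrame | None = None
        self.mirnas: dict[str, str] = {}
        self.fasta_text: str | None = None
        self.gtf_text: str | None = None

    # ------------------------------------------------------------------
    # reference
    # ------------------------------------------------------------------
    def simulate_reference(self) -> tuple[str, str, list[GeneModel]]:
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, 1])
        for i in range(cfg.n_chroms):
            chars = rng.choice(list(BASES), size=cfg.chrom_length)
            self.genome[f"chr{i + 1}"] = list(chars)

        per_chrom = [
            cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms else 0)
            for i in range(cfg.n_chroms)
        ]
        gi = 0
        for ci, k in enumerate(per_chrom):
            if k == 0:
                continue
            chrom = f"chr{ci + 1}"
            slot = cfg.chrom_length // k
            for j in range(k):
                gene = self._make_gene(gi, chrom, slot, j, rng)
                self.genes.append(gene)
                gi += 1
        genic = sum(g.end - g.start + 1 for g in self.genes)
        if genic > 0.7 * cfg.n_chroms * cfg.chrom_length:
            raise SimConfigError(
                "genes occupy more than 70% of the genome; "
                "increase chrom_length or reduce n_genes"
            )
        self.models = [self._to_model(g) for g in self.genes]
        self.fasta_text = self._render_fasta()
        self.gtf_text = self._render_gtf()
        return self.fasta_text, self.gtf_text, self.models

    def _make_gene(self, gi: int, chrom: str, slot: int, j: int, rng) -> _SimGene:
        cfg = self.cfg
        u5 = int(rng.integers(80, 161))
        n_codons = int(rng.integers(120, 201))
        cds_len = 3 * n_codons
        u3 = int(rng.integers(280, 421))
        intron = int(rng.integers(500, 901))
        tlen = u5 + cds_len + u3
        span = tlen + intron
        if span + 40 > slot:
            raise SimConfigError(
                f"gene {gi} (span {span} bp) does not fit in its {slot} bp slot; "
                "increase chrom_length or reduce n_genes"
            )
        start = j * slot + (slot - span) // 2 + 1
        strand = "+" if gi % 2 == 0 else "-"
        biotype = "lincRNA" if gi % 6 == 5 else "protein_coding"
        split = u5 + int(rng.integers(cds_len // 3, 2 * cds_len // 3))
        e1 = (start, start + split - 1)
        e2 = (start + split + intron, start + span - 1)
        txpos = list(range(e1[0], e1[1] + 1)) + list(range(e2[0], e2[1] + 1))
        if strand == "-":
            txpos = txpos[::-1]
        if biotype != "protein_coding":
            u5 = cds_len = 0
            u3 = tlen
        gene = _SimGene(
            gene_id=f"SIMG{gi:04d}",
            chrom=chrom,
            strand=strand,
            biotype=biotype,
            exons=[e1, e2],
            u5_len=u5,
            cds_len=cds_len,
            u3_len=u3,
            txpos=txpos,
        )
        if biotype == "protein_coding":
            codons = (
                "ATG"
                + "".join(rng.choice(SENSE_CODONS, size=n_codons - 2))
                + str(rng.choice(STOP_CODONS))
            )
            for i, base in enumerate(codons):
                self._set_tx_base(gene, u5 + i, base)
        return gene

    # transcript-orientation base access --------------------------------
    def _tx_base(self, gene: _SimGene, idx: int) -> str:
        b = self.genome[gene.chrom][gene.txpos[idx] - 1]
        return b if gene.strand == "+" else comp(b)

    def _set_tx_base(self, gene: _SimGene, idx: int, base: str) -> None:
        self.genome[gene.chrom][gene.txpos[idx] - 1] = (
            base if gene.strand == "+" else comp(base)
        )

    def _tx_seq(self, gene: _SimGene) -> str:
        return "".join(self._tx_base(gene, i) for i in range(gene.tlen))

    def _to_model(self, g: _SimGene) -> GeneModel:
        def segs(a: int, b: int) -> list[tuple[int, int]]:
            return _runs_to_segments(sorted(g.txpos[a:b]))

        tx = Transcript(
            transcript_id=g.gene_id.replace("SIMG", "SIMT"),
            strand=g.strand,
            exons=sorted(g.exons),
            cds=segs(g.u5_len, g.u5_len + g.cds_len) if g.cds_len else [],
            utr5=segs(0, g.u5_len) if g.u5_len else [],
            utr3=segs(g.u5_len + g.cds_len, g.tlen) if g.biotype == "protein_coding" else [],
        )
        return GeneModel(
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand=g.strand,
            gene_biotype=g.biotype,
            transcripts=[tx],
        )

    def _render_fasta(self) -> str:
        out = []
        for chrom in sorted(self.genome):
            out.append(f">{chrom}")
            out.append(_wrap_fasta("".join(self.genome[chrom])))
        return "\n".join(out) + "\n"

    def _render_gtf(self) -> str:
        lines = []

        def feat(chrom, ftype, s, e, strand, attrs, frame="."):
            attr = " ".join(f'{k} "{v}";' for k, v in attrs)
            lines.append(
                f"{chrom}\teditkit_sim\t{ftype}\t{s}\t{e}\t.\t{strand}\t{frame}\t{attr}"
            )

        for g, model in zip(self.genes, self.models):
            tx = model.transcripts[0]
            base_attrs = [("gene_id", g.gene_id), ("gene_biotype", g.biotype)]
            tx_attrs = base_attrs[:1] + [
                ("transcript_id", tx.transcript_id),
                ("gene_biotype", g.biotype),
            ]
            feat(g.chrom, "gene", g.start, g.end, g.strand, base_attrs)
            feat(g.chrom, "transcript", g.start, g.end, g.strand, tx_attrs)
            for s, e in tx.exons:
                feat(g.chrom, "exon", s, e, g.strand, tx_attrs)
            # dialect choice: CDS includes the stop codon (length stays a
            # multiple of 3 and matches the in-memory model exactly)
            for s, e in tx.cds:
                feat(g.chrom, "CDS", s, e, g.strand, tx_attrs, frame="0")
            for s, e in tx.utr5:
                feat(g.chrom, "five_prime_utr", s, e, g.strand, tx_attrs)
            for s, e in tx.utr3:
                feat(g.chrom, "three_prime_utr", s, e, g.strand, tx_attrs)
        return "\n".join(lines) + "\n"

    # ------------------------------------------------------------------
    # truth planting
    # ------------------------------------------------------------------
    def plant_sites(self) -> pd.DataFrame:
        if not self.genes:
            raise SimConfigError("simulate_reference must be run before plant_sites")
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, 2])
        occupied: dict[str, list[int]] = {c: [] for c in self.genome}

        def try_place(chrom: str, pos: int) -> bool:
            lst = occupied[chrom]
            i = bisect_left(lst, pos)
            for q in lst[max(0, i - 1) : i + 1]:
                if abs(q - pos) < MIN_SITE_SPACING:
                    return False
            insort(lst, pos)
            return True

        pools = self._candidate_pools()

        def draw_from(cands: list, n: int) -> list:
            """Pop up to n placeable candidates (gene, tx_idx_or_pos, region)."""
            rng.shuffle(cands)
            out = []
            while cands and len(out) < n:
                gene, where, region = cands.pop()
                pos = gene.txpos[where] if region != "intron" else where
                # pools predate engineering rewrites; re-verify the base
                b = self.genome[gene.chrom][pos - 1]
                if (b if gene.strand == "+" else comp(b)) != "A":
                    continue
                if try_place(gene.chrom, pos):
                    out.append((gene, where, region, pos))
            if len(out) < n:
                raise SimConfigError(
                    f"not enough eligible A positions (needed {n}, found {len(out)})"
                )
            return out

        # decoy miRNAs first so the engineered sites can be validated
        # against the full miRNA complement
        for k in range(1, cfg.n_decoy_mirnas + 1):
            self.mirnas[f"chi-miR-dec-{k}"] = "".join(
                rng.choice(list("ACGU"), size=22)
            )

        # 1. engineered miRNA gain / loss sites in 3' UTRs.  Each
        # engineered (site, miRNA) pair is verified with the actual
        # scanner under default parameters — including cross-talk against
        # every previously accepted miRNA and window — and re-drawn on
        # any conflict, so the planted truth holds exactly.
        mirna_recs = self._engineer_mirna_sites(pools["utr3_mirna"], try_place,
                                                occupied, rng)
        # 2. recoding sites with predetermined synonymous / missense outcome
        n_syn = cfg.n_recoding // 2
        n_mis = cfg.n_recoding - n_syn
        rec_sites = [
            (g, w, "CDS", p) for g, w, _, p in draw_from(pools["cds_syn"], n_syn)
        ] + [(g, w, "CDS", p) for g, w, _, p in draw_from(pools["cds_mis"], n_mis)]
        # 3. remaining sites across all regions
        n_left = cfg.n_edit_sites - len(mirna_recs) - len(rec_sites)
        if n_left < 0:
            raise SimConfigError(
                "n_edit_sites smaller than the engineered miRNA + recoding sites"
            )
        generic = draw_from(pools["generic"], n_left)

        # context bias is applied before miRNA engineering so engineered
        # windows stay exact; bias therefore excludes the miRNA sites.
        plain_sites = [(g, w, r, p) for g, w, r, p in rec_sites + generic]
        if cfg.context_bias:
            self._apply_context_bias(plain_sites, rng)

        # assemble records
        all_sites: list[dict] = []
        for rec in mirna_recs:
            g = rec["gene"]
            all_sites.append(
                dict(
                    chrom=g.chrom,
                    pos=rec["pos"],
                    strand=g.strand,
                    gene_id=g.gene_id,
                    region_class="3'UTR",
                    tx_idx=rec["tx_idx"],
                    gene=g,
                    mirna_effect=rec["kind"],
                    mirna_id=rec["mirna_id"],
                )
            )
        for g, where, region, pos in rec_sites + generic:
            all_sites.append(
                dict(
                    chrom=g.chrom,
                    pos=pos,
                    strand=g.strand,
                    gene_id=g.gene_id,
                    region_class=region,
                    tx_idx=None if region == "intron" else where,
                    gene=g,
                    mirna_effect="none",
                    mirna_id="",
                )
            )

        # site-class assignment
        n = len(all_sites)
        n_diff = round(0.3 * n)
        n_ss_total = round(0.3 * n)
        per_stage = [
            n_ss_total // len(cfg.stages)
            + (1 if i < n_ss_total % len(cfg.stages) else 0)
            for i in range(len(cfg.stages))
        ]
        classes = ["differential"] * n_diff
        for stage, k in zip(cfg.stages, per_stage):
            classes += [f"stage_specific:{stage}"] * k
        classes += ["constitutive"] * (n - len(classes))
        order = rng.permutation(n)
        for idx, cls in zip(order, classes):
            all_sites[idx]["site_class"] = cls

        # SNP confounders
        snps = draw_from(pools["snp"], cfg.n_snps)
        for g, where, region, pos in snps:
            all_sites.append(
                dict(
                    chrom=g.chrom,
                    pos=pos,
                    strand=g.strand,
                    gene_id=g.gene_id,
                    region_class=region,
                    tx_idx=None if region == "intron" else where,
                    gene=g,
                    mirna_effect="none",
                    mirna_id="",
                    site_class="snp_confounder",
                )
            )

        # recoding effects computed from the final genome
        profiles = cfg.profiles()
        rows = []
        for s in all_sites:
            effect, ref_codon, alt_codon = "none", "", ""
            if s["region_class"] == "CDS":
                effect, ref_codon, alt_codon = self._codon_effect(s["gene"], s["tx_idx"])
            prof = profiles[s["site_class"]]
            row = dict(
                chrom=s["chrom"],
                pos=s["pos"],
                strand=s["strand"],
                site_class=s["site_class"],
                region_class=s["region_class"],
                gene_id=s["gene_id"],
                effect=effect,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                mirna_effect=s["mirna_effect"],
                mirna_id=s["mirna_id"],
            )
            for stage in cfg.stages:
                row[f"level_{stage}"] = prof[stage]
            rows.append(row)
        truth = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
        # every planted site must read A on the transcript strand
        bad = [
            (r.chrom, r.pos)
            for r in truth.itertuples()
            if (self.genome[r.chrom][r.pos - 1] if r.strand == "+"
                else comp(self.genome[r.chrom][r.pos - 1])) != "A"
        ]
        if bad:  # pragma: no cover - construction guarantee
            raise AssertionError(f"non-A planted sites: {bad[:5]}")
        self.truth = truth
        # FASTA must reflect post-planting rewrites (context bias, miRNA windows)
        self.fasta_text = self._render_fasta()
        return truth

    def _candidate_pools(self) -> dict[str, list]:
        """Candidate (gene, tx_index_or_genomic_pos, region) tuples, keyed by
        planting purpose.  All candidates carry an A on the transcript strand."""
        pools: dict[str, list] = {
            "utr3_mirna": [],
            "cds_syn": [],
            "cds_mis": [],
            "generic": [],
            "snp": [],
        }
        for g in self.genes:
            tx = self._tx_seq(g)
            if g.biotype == "protein_coding":
                cds_start = g.u5_len
                n_codons = g.cds_len // 3
                for ci in range(1, n_codons - 1):  # skip start and stop codons
                    codon = tx[cds_start + 3 * ci : cds_start + 3 * ci + 3]
                    if codon[2] == "A" and codon != "ATA":
                        pools["cds_syn"].append((g, cds_start + 3 * ci + 2, "CDS"))
                    if codon[0] == "A":
                        pools["cds_mis"].append((g, cds_start + 3 * ci, "CDS"))
                    elif codon[1] == "A":
                        pools["cds_mis"].append((g, cds_start + 3 * ci + 1, "CDS"))
                u3_start = g.u5_len + g.cds_len
                for i in range(u3_start, g.tlen):
                    if tx[i] != "A":
                        continue
                    entry = (g, i, "3'UTR")
                    pools["generic"].append(entry)
                    pools["snp"].append(entry)
                    if i - UTR3_MARGIN >= u3_start and i + UTR3_MARGIN < g.tlen:
                        pools["utr3_mirna"].append(entry)
                for i in range(0, g.u5_len):
                    if tx[i] == "A":
                        pools["generic"].append((g, i, "5'UTR"))
                        pools["snp"].append((g, i, "5'UTR"))
            else:
                for i in range(g.tlen):
                    if tx[i] == "A":
                        pools["generic"].append((g, i, "exon_noncoding"))
                        pools["snp"].append((g, i, "exon_noncoding"))
            # intron positions (genomic coords; transcript-strand A)
            (e1, e2) = sorted(g.exons)
            want = "A" if g.strand == "+" else "T"
            for pos in range(e1[1] + 1, e2[0]):
                if self.genome[g.chrom][pos - 1] == want:
                    pools["generic"].append((g, pos, "intron"))
                    pools["snp"].append((g, pos, "intron"))
        return pools

    def _apply_context_bias(self, sites: list, rng) -> None:
        """Rewrite the immediate neighbours of planted sites so that the
        -1 / +1 G frequency matches the configured bias (transcript
        orientation; genomic neighbours, since editing context is
        pre-mRNA)."""
        bias = self.cfg.context_bias or {}
        g_up = bias.get("upstream_g")
        g_down = bias.get("downstream_g")

        def sample_base(g_frac: float) -> str:
            if rng.random() < g_frac:
                return "G"
            return str(rng.choice(["A", "C", "T"]))

        for gene, where, region, pos in sites:
            for offset, frac in ((-1, g_up), (+1, g_down)):
                if frac is None:
                    continue
                gpos = pos + offset if gene.strand == "+" else pos - offset
                if not (1 <= gpos <= len(self.genome[gene.chrom])):
                    continue
                b = sample_base(frac)
                self.genome[gene.chrom][gpos - 1] = b if gene.strand == "+" else comp(b)

    def _tx_window(self, gene: _SimGene, pos: int, lo: int, hi: int) -> str:
        """Transcript-orientation genomic window [pos+lo, pos+hi] (offsets
        measured along the transcript direction)."""
        out = []
        for d in range(lo, hi + 1):
            p = pos + d if gene.strand == "+" else pos - d
            b = self.genome[gene.chrom][p - 1]
            out.append(b if gene.strand == "+" else comp(b))
        return "".join(out)

    def _engineer_mirna_sites(self, pool: list, try_place, occupied, rng) -> list[dict]:
        """Place gain/lost miRNA sites, validating each engineered pair
        with the real duplex scanner (default parameters) before
        acceptance: the planted miRNA must flip pass-status across the
        substitution at its own site, and no miRNA may flip status at any
        *other* engineered site.  Conflicting draws are rejected."""
        from editkit.mirna import ScanConfig, scan_duplexes

        cfg = self.cfg
        scan_cfg = ScanConfig()

        def status(mid: str, seq: str, window: str) -> bool:
            hits = scan_duplexes({mid: seq}, window, scan_cfg)
            return any(h.target_start <= 11 <= h.target_end for h in hits)

        accepted: list[dict] = []
        windows: list[tuple[str, str]] = []
        rng.shuffle(pool)
        k = 0
        for kind, n in (("gain", cfg.n_mirna_gain), ("lost", cfg.n_mirna_lost)):
            placed = 0
            while placed < n:
                cand = None
                while pool:
                    gene, where, _region = pool.pop()
                    pos = gene.txpos[where]
                    if try_place(gene.chrom, pos):
                        cand = (gene, where, pos)
                        break
                if cand is None:
                    raise SimConfigError(
                        "not enough eligible 3' UTR positions for engineered "
                        f"miRNA sites (placed {len(accepted)})"
                    )
                gene, where, pos = cand
                seq = self._engineer_mirna(gene, pos, kind, rng)
                wb = self._tx_window(gene, pos, -10, 10)
                wa = wb[:10] + "G" + wb[11:]
                mid = f"chi-miR-sim-{k + 1}"
                if kind == "gain":
                    ok = status(mid, seq, wa) and not status(mid, seq, wb)
                else:
                    ok = status(mid, seq, wb) and not status(mid, seq, wa)
                if ok:
                    for oid, oseq in self.mirnas.items():
                        if status(oid, oseq, wb) != status(oid, oseq, wa):
                            ok = False
                            break
                if ok:
                    for owb, owa in windows:
                        if status(mid, seq, owb) != status(mid, seq, owa):
                            ok = False
                            break
                if not ok:
                    occupied[gene.chrom].remove(pos)
                    continue
                k += 1
                self.mirnas[mid] = seq
                windows.append((wb, wa))
                accepted.append(
                    dict(gene=gene, tx_idx=where, region="3'UTR", pos=pos,
                         kind=kind, mirna_id=mid)
                )
                placed += 1
        return accepted

    def _engineer_mirna(self, gene: _SimGene, pos: int, kind: str, rng) -> str:
        """Build a 22-nt miRNA whose seed (positions 2-8) pairs the 3' UTR
        window around the planted site perfectly only after (gain) or only
        before (lost) the A-to-G substitution.

        Layout: miRNA position p pairs transcript-window offset d = 6 - p
        (so p in 2..16 pairs d in +4..-10); the edited A sits at d = 0 and
        pairs seed position 6.  Positions 9-12 bridge with engineered
        mismatches, 13-16 add G/C supplementary pairs, the rest dangle.
        """

        def gpos(d: int) -> int:
            return pos + d if gene.strand == "+" else pos - d

        def get_t(d: int) -> str:
            p = gpos(d)
            if not (1 <= p <= len(self.genome[gene.chrom])):
                return "A"
            b = self.genome[gene.chrom][p - 1]
            return b if gene.strand == "+" else comp(b)

        def set_t(d: int, base: str) -> None:
            p = gpos(d)
            self.genome[gene.chrom][p - 1] = base if gene.strand == "+" else comp(base)

        def nonpairing(t: str) -> str:
            cands = [
                m for m in "ACGU"
                if _WC_PARTNER.get(t) != m and (t, m) not in _WOBBLE
            ]
            return str(rng.choice(cands))

        for d in (-10, -9, -8, -7):  # GC-rich supplementary target bases
            set_t(d, str(rng.choice(["G", "C"])))
        window = [get_t(d) for d in range(-10, 6)]  # T'[k] = offset k-10
        edited = list(window)
        edited[10] = "G"
        pairing_target = edited if kind == "gain" else window
        m = [""] * 22
        for p in range(2, 9):  # seed, pairs T'[16-p]
            m[p - 1] = _WC_PARTNER[pairing_target[16 - p]]
        for p in range(9, 13):  # bridge mismatches
            m[p - 1] = nonpairing(window[16 - p])
        for p in range(13, 17):  # supplementary WC (G/C)
            m[p - 1] = _WC_PARTNER[window[16 - p]]
        m[0] = nonpairing(window[15])
        for p in range(17, 23):  # dangling 3' tail, kept non-pairing
            m[p - 1] = nonpairing(get_t(6 - p))
        return "".join(m)

    def _codon_effect(self, gene: _SimGene, tx_idx: int) -> tuple[str, str, str]:
        from Bio.Seq import Seq

        ci = (tx_idx - gene.u5_len) // 3
        cpos = (tx_idx - gene.u5_len) % 3
        start = gene.u5_len + 3 * ci
        ref_codon = "".join(self._tx_base(gene, start + i) for i in range(3))
        alt_codon = ref_codon[:cpos] + "G" + ref_codon[cpos + 1 :]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            effect = "synonymous"
        elif alt_aa == "*":
            effect = "nonsense_gain"
        else:
            effect = "missense"
        return effect, ref_codon, alt_codon

    # ------------------------------------------------------------------
    # pileups, VCF, miRNA FASTA
    # ------------------------------------------------------------------
    def simulate_pileups(self) -> SimulatedData:
        if self.truth is None:
            raise SimConfigError("plant_sites must be run before simulate_pileups")
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, 3])
        base_idx = {b: i for i, b in enumerate(BASES)}

        chroms, positions, strands, refs = [], [], [], []
        for g in self.genes:
            span = np.arange(g.start, g.end + 1)
            positions.append(span)
            chroms += [g.chrom] * len(span)
            strands += [g.strand] * len(span)
            refs += self.genome[g.chrom][g.start - 1 : g.end]
        pos_arr = np.concatenate(positions)
        chrom_arr = np.array(chroms)
        strand_arr = np.array(strands)
        ref_arr = np.array(refs)
        N = len(pos_arr)
        ref_idx = np.array([base_idx[b] for b in ref_arr])
        row_of = {(c, int(p)): i for i, (c, p) in enumerate(zip(chrom_arr, pos_arr))}

        # per-stage true level and forward-genome alt base per position
        levels = {stage: np.zeros(N) for stage in cfg.stages}
        alt_idx = np.full(N, -1)
        is_snp = np.zeros(N, dtype=bool)
        for r in self.truth.itertuples():
            i = row_of[(r.chrom, r.pos)]
            alt_fwd = "G" if r.strand == "+" else "C"
            alt_idx[i] = base_idx[alt_fwd]
            if r.site_class == "snp_confounder":
                is_snp[i] = True
            for stage in cfg.stages:
                levels[stage][i] = getattr(r, f"level_{stage}")
        is_truth = alt_idx >= 0

        samples = cfg.sample_ids()
        keep = is_truth.copy()
        counts_per_sample: dict[str, np.ndarray] = {}
        for sample, stage in samples.items():
            cov = rng.poisson(cfg.rna_coverage_mean, N)
            p = levels[stage]
            alt = rng.binomial(cov, p)
            err = np.zeros(N, dtype=int)
            if cfg.error_rate > 0:
                err = np.where(p == 0, rng.binomial(cov, cfg.error_rate), 0)
            counts = np.zeros((N, 8), dtype=int)
            off = np.where(strand_arr == "+", 0, 4)
            rows = np.arange(N)
            counts[rows, off + ref_idx] = cov - alt - err
            safe_alt = np.where(alt_idx >= 0, alt_idx, 0)
            counts[rows, off + safe_alt] += np.where(alt_idx >= 0, alt, 0)
            for i in np.nonzero(err)[0]:
                others = [b for b in range(4) if b != ref_idx[i]]
                split = rng.multinomial(err[i], [1 / 3] * 3)
                for b, c in zip(others, split):
                    counts[i, off[i] + b] += c
            counts_per_sample[sample] = counts
            keep |= (alt > 0) | (err > 0)

        dna_cov = rng.poisson(cfg.dna_coverage_mean, N)
        dna_alt = np.where(is_snp, rng.binomial(dna_cov, 0.5), 0)
        dna_counts = np.zeros((N, 8), dtype=int)
        rows = np.arange(N)
        dna_counts[rows, ref_idx] = dna_cov - dna_alt
        safe_alt = np.where(alt_idx >= 0, alt_idx, 0)
        dna_counts[rows, safe_alt] += np.where(is_snp, dna_alt, 0)

        kept = np.nonzero(keep)[0]
        cols = ["fA", "fC", "fG", "fT", "rA", "rC", "rG", "rT"]

        def to_df(counts: np.ndarray) -> pd.DataFrame:
            df = pd.DataFrame(
                {"chrom": chrom_arr[kept], "pos": pos_arr[kept], "ref": ref_arr[kept]}
            )
            for j, c in enumerate(cols):
                df[c] = counts[kept, j]
            return df.reset_index(drop=True)

        rna = {s: to_df(c) for s, c in counts_per_sample.items()}
        dna = to_df(dna_counts)
        vcf_text = self._render_vcf()
        mirna_fasta = self._render_mirna_fasta()
        return SimulatedData(rna, dna, vcf_text, mirna_fasta, samples)

    def _render_vcf(self) -> str:
        lines = [
            "##fileformat=VCFv4.2",
            '##source=editkit_sim',
        ]
        for chrom in sorted(self.genome):
            lines.append(f"##contig=<ID={chrom},length={len(self.genome[chrom])}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        snps = self.truth[self.truth.site_class == "snp_confounder"]
        for r in snps.itertuples():
            ref = "A" if r.strand == "+" else "T"
            alt = "G" if r.strand == "+" else "C"
            lines.append(f"{r.chrom}\t{r.pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
        return "\n".join(lines) + "\n"

    def _render_mirna_fasta(self) -> str:
        out = []
        for i, (mid, seq) in enumerate(self.mirnas.items(), start=1):
            out.append(f">{mid} MIMAT{i:07d} Capra hircus {mid}")
            out.append(seq)
        return "\n".join(out) + "\n"

    # ------------------------------------------------------------------
    # SAM
    # ------------------------------------------------------------------
    def write_sam(
        self,
        samples: list[str] | None = None,
        artifact_sites: set[tuple[str, int]] | None = None,
    ) -> dict[str, str]:
        """Emit simple single-end reads per sample as SAM text.

        ``artifact_sites`` are positions where alternative bases occur only
        within the first 6 *sequenced* positions of a read, so that 5'-end
        trimming removes all of their evidence.
        """
        if self.truth is None:
            raise SimConfigError("plant_sites must be run before write_sam")
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, 4])
        artifact_sites = artifact_sites or set()
        L = cfg.read_length
        qual = chr(cfg.base_quality + 33) * L
        truth_by_chrom: dict[str, dict[int, tuple[str, dict[str, float]]]] = {}
        for r in self.truth.itertuples():
            alt_fwd = "G" if r.strand == "+" else "C"
            lv = {s: getattr(r, f"level_{s}") for s in cfg.stages}
            truth_by_chrom.setdefault(r.chrom, {})[r.pos] = (alt_fwd, lv)

        ids = samples or list(cfg.sample_ids())
        stage_of = cfg.sample_ids()
        out: dict[str, str] = {}
        header = ["@HD\tVN:1.6\tSO:coordinate"] + [
            f"@SQ\tSN:{c}\tLN:{len(self.genome[c])}" for c in sorted(self.genome)
        ]
        for sample in ids:
            stage = stage_of[sample]
            lines = list(header)
            for g in self.genes:
                span = g.end - g.start + 1
                if span < L:
                    continue
                n_reads = rng.poisson(cfg.rna_coverage_mean * span / L)
                starts = np.sort(rng.integers(g.start, g.end - L + 2, size=n_reads))
                # under the dUTP-style 'second_read' protocol a single-end
                # read maps antisense to its transcript
                if cfg.strand_protocol == "second_read":
                    flag = 16 if g.strand == "+" else 0
                elif cfg.strand_protocol == "first_read":
                    flag = 16 if g.strand == "-" else 0
                else:
                    flag = 0
                reverse_read = bool(flag & 16)
                chrom_seq = self.genome[g.chrom]
                tmap = truth_by_chrom.get(g.chrom, {})
                for ri, s in enumerate(starts):
                    s = int(s)
                    seq = chrom_seq[s - 1 : s - 1 + L]
                    seq = list(seq)
                    for p in range(s, s + L):
                        hit = tmap.get(p)
                        is_artifact = (g.chrom, p) in artifact_sites
                        if hit is None and not is_artifact:
                            continue
                        i = p - s
                        seq_order = (L - 1 - i) if reverse_read else i
                        if is_artifact:
                            if seq_order < 6:
                                seq[i] = "G" if g.strand == "+" else "C"
                            continue
                        alt_fwd, lv = hit
                        if rng.random() < lv[stage]:
                            seq[i] = alt_fwd
                    if cfg.error_rate > 0:
                        k = rng.binomial(L, cfg.error_rate)
                        for i in rng.integers(0, L, size=k):
                            cur = seq[int(i)]
                            seq[int(i)] = str(
                                rng.choice([b for b in BASES if b != cur])
                            )
                    lines.append(
                        "\t".join(
                            [
                                f"r_{sample}_{g.gene_id}_{ri}",
                                str(flag),
                                g.chrom,
                                str(s),
                                str(cfg.mapq),
                                f"{L}M",
                                "*",
                                "0",
                                "0",
                                "".join(seq),
                                qual,
                            ]
                        )
                    )
            out[sample] = "\n".join(lines) + "\n"
        return out

    # ------------------------------------------------------------------
    def genome_strings(self) -> dict[str, str]:
        return {c: "".join(s) for c, s in self.genome.items()}


def simulate_all(cfg: SimConfig) -> tuple[Simulator, SimulatedData]:
    """Run the full generator: reference, truth, pileups/VCF/miRNAs."""
    sim = Simulator(cfg)
    sim.simulate_reference()
    sim.plant_sites()
    data = sim.simulate_pileups()
    return sim, data
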