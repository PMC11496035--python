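"""Simulator contracts: determinism, gene-model well-formedness, planted
truth consistency, binomial level recovery, and SAM emission."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest
from Bio.Seq import Seq

from editkit.models import revcomp
from editkit.pileup import IngestConfig, pileup_from_sam
from editkit.simulate import SimConfig, SimConfigError, Simulator


def _parse_gtf(text):
    """Independent minimal GTF reader used as an oracle."""
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(
            kv.strip().split(" ", 1) for kv in f[8].split(";") if kv.strip()
        )
        rows.append(
            dict(chrom=f[0], type=f[2], start=int(f[3]), end=int(f[4]), strand=f[6],
                 **{k: v.strip('"') for k, v in attrs.items()})
        )
    return pd.DataFrame(rows)


class TestReference:
    def test_deterministic_outputs(self, small_cfg):
        a = Simulator(small_cfg)
        b = Simulator(small_cfg)
        fa_a, gtf_a, _ = a.simulate_reference()
        fa_b, gtf_b, _ = b.simulate_reference()
        assert fa_a == fa_b and gtf_a == gtf_b
        ta, tb = a.plant_sites(), b.plant_sites()
        assert ta.equals(tb)
        assert a.fasta_text == b.fasta_text  # post-planting rewrites included

    def test_gene_records_on_both_strands(self, small_cfg):
        sim = Simulator(small_cfg)
        _, gtf, _ = sim.simulate_reference()
        genes = _parse_gtf(gtf).query("type == 'gene'")
        assert len(genes) == 2
        assert set(genes.strand) == {"+", "-"}

    def test_cds_translates_cleanly(self, small_sim):
        """Every CDS extracted from the emitted FASTA via the emitted GTF
        translates without internal stop codons (genetic-code oracle)."""
        gtf = _parse_gtf(small_sim.gtf_text)
        fasta = {}
        name = None
        for line in small_sim.fasta_text.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                fasta[name] = []
            else:
                fasta[name].append(line)
        fasta = {k: "".join(v) for k, v in fasta.items()}
        cds = gtf.query("type == 'CDS'")
        assert len(cds)
        for tid, seg in cds.groupby("transcript_id"):
            seg = seg.sort_values("start")
            seq = "".join(
                fasta[r.chrom][r.start - 1 : r.end] for r in seg.itertuples()
            )
            if seg.iloc[0].strand == "-":
                seq = revcomp(seq)
            assert len(seq) % 3 == 0
            protein = str(Seq(seq).translate())
            assert "*" not in protein[:-1]
            assert protein.startswith("M") and protein.endswith("*")

    def test_intergenic_space_retained(self, default_sim):
        genic = sum(g.end - g.start + 1 for g in default_sim.genes)
        total = sum(len(s) for s in default_sim.genome.values())
        assert genic / total <= 0.7

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(chrom_length=5000), "chrom_length"),
            (dict(stages=("GM", "GM", "DM5")), "unique"),
            (dict(replicates_per_stage=1), "replicates"),
            (dict(error_rate=0.2), "error_rate"),
            (dict(level_profiles={"constitutive": {"GM": 1.5, "DM1": 0, "DM5": 0}}),
             "outside"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs, msg):
        with pytest.raises(SimConfigError, match=msg):
            Simulator(SimConfig(**kwargs))

    def test_infeasible_gene_layout(self):
        with pytest.raises(SimConfigError, match="fit|slot"):
            sim = Simulator(SimConfig(chrom_length=10_000, n_chroms=1, n_genes=6))
            sim.simulate_reference()


class TestTruth:
    def test_positions_unique_and_ref_is_A(self, default_sim, default_genome):
        truth = default_sim.truth
        assert not truth.duplicated(["chrom", "pos"]).any()
        for r in truth.itertuples():
            base = default_genome[r.chrom][r.pos - 1]
            tx = base if r.strand == "+" else revcomp(base)
            assert tx == "A"

    def test_stage_specific_levels_by_definition(self, default_sim):
        truth = default_sim.truth
        ss = truth[truth.site_class == "stage_specific:DM5"]
        assert len(ss)
        assert (ss.level_GM == 0).all() and (ss.level_DM1 == 0).all()
        assert (ss.level_DM5 > 0).all()

    def test_planted_recoding_classes_present(self, default_sim):
        effects = default_sim.truth.effect.value_counts()
        assert effects.get("synonymous", 0) >= 10
        assert effects.get("missense", 0) >= 10
        assert effects.get("nonsense_gain", 0) == 0

    def test_vcf_matches_snp_confounders_exactly(self, default_sim, default_data):
        truth = default_sim.truth
        snps = truth[truth.site_class == "snp_confounder"]
        vcf_rows = [
            line.split("\t")
            for line in default_data.vcf_text.splitlines()
            if line and not line.startswith("#")
        ]
        assert {(c, int(p)) for c, p, *_ in vcf_rows} == set(
            zip(snps.chrom, snps.pos)
        )
        assert len(vcf_rows) == len(snps)


class TestPileups:
    def test_no_alt_without_noise_at_nonsites(self, small_sim):
        data = small_sim.simulate_pileups()
        truth_pos = set(zip(small_sim.truth.chrom, small_sim.truth.pos))
        for df in data.rna_pileups.values():
            for r in df.itertuples():
                if (r.chrom, r.pos) in truth_pos:
                    continue
                counts = {b: getattr(r, "f" + b) + getattr(r, "r" + b) for b in "ACGT"}
                assert sum(v for b, v in counts.items() if b != r.ref) == 0

    def test_binomial_level_recovery(self, default_sim, default_data):
        """Mean recovered level over constitutive sites at coverage 100 is
        within 3 standard errors of the planted 0.30."""
        truth = default_sim.truth
        const = truth[truth.site_class == "constitutive"]
        assert len(const) >= 100
        df = default_data.rna_pileups["GM_1"]
        by_pos = df.set_index(["chrom", "pos"])
        obs = []
        for r in const.itertuples():
            row = by_pos.loc[(r.chrom, r.pos)]
            alt_col = ("f" if r.strand == "+" else "r") + ("G" if r.strand == "+" else "C")
            ref_col = ("f" if r.strand == "+" else "r") + ("A" if r.strand == "+" else "T")
            alt, ref = row[alt_col], row[ref_col]
            if alt + ref > 0:
                obs.append(alt / (alt + ref))
        se = np.sqrt(0.3 * 0.7 / 100 / len(obs))
        assert abs(np.mean(obs) - 0.3) < 3 * se

    def test_dna_variants_only_at_snps(self, default_sim, default_data):
        truth = default_sim.truth
        snp_pos = set(
            zip(truth[truth.site_class == "snp_confounder"].chrom,
                truth[truth.site_class == "snp_confounder"].pos)
        )
        dna = default_data.dna_pileup
        for r in dna.itertuples():
            nonref = sum(
                getattr(r, "f" + b) + getattr(r, "r" + b) for b in "ACGT" if b != r.ref
            )
            if (r.chrom, r.pos) not in snp_pos:
                assert nonref == 0
            else:
                assert nonref > 0


class TestSam:
    def _pileup(self, sim, sample, **ingest_kw):
        import tempfile, os

        sams = sim.write_sam(samples=[sample], **{
            k: v for k, v in ingest_kw.items() if k == "artifact_sites"
        })
        kw = {k: v for k, v in ingest_kw.items() if k != "artifact_sites"}
        path = tempfile.mktemp(suffix=".sam")
        with open(path, "w") as fh:
            fh.write(sams[sample])
        try:
            return pileup_from_sam(path, sim.genome_strings(), IngestConfig(**kw))
        finally:
            os.unlink(path)

    def test_read_counts_reconcile_with_coverage(self, small_sim):
        """With error_rate 0 and no filtering, per-position pileup coverage
        equals the number of overlapping reads (independent SAM recount)."""
        import tempfile, os

        sams = small_sim.write_sam(samples=["GM_1"])
        path = tempfile.mktemp(suffix=".sam")
        with open(path, "w") as fh:
            fh.write(sams["GM_1"])
        try:
            df = pileup_from_sam(
                path, small_sim.genome_strings(),
                IngestConfig(min_base_quality=0, min_mapping_quality=0, trim_5prime=0),
            )
            from collections import Counter

            overlap = Counter()
            for line in sams["GM_1"].splitlines():
                if line.startswith("@"):
                    continue
                f = line.split("\t")
                start, length = int(f[3]), len(f[9])
                for p in range(start, start + length):
                    overlap[(f[2], p)] += 1
            got = {
                (r.chrom, r.pos): sum(
                    getattr(r, s + b) for s in "fr" for b in "ACGT"
                )
                for r in df.itertuples()
            }
            assert got == dict(overlap)
        finally:
            os.unlink(path)

    def test_artifact_site_removed_by_end_trimming(self, small_sim):
        g = small_sim.genes[0]
        pos = g.txpos[200]  # deep inside the gene so reads cover it both ways
        art = {(g.chrom, pos)}
        trimmed = self._pileup(
            small_sim, "GM_1", artifact_sites=art,
            min_base_quality=0, min_mapping_quality=0, trim_5prime=6,
        )
        untrimmed = self._pileup(
            small_sim, "GM_1", artifact_sites=art,
            min_base_quality=0, min_mapping_quality=0, trim_5prime=0,
        )

        def alt_at(df):
            row = df[(df.chrom == g.chrom) & (df.pos == pos)]
            if not len(row):
                return 0
            r = row.iloc[0]
            return sum(r["f" + b] + r["r" + b] for b in "ACGT" if b != r["ref"])

        assert alt_at(untrimmed) > 0
        assert alt_at(trimmed) == 0

    def test_sam_parses_with_pysam(self, small_sim, tmp_path):
        sams = small_sim.write_sam(samples=["GM_1"])
        p = tmp_path / "gm1.sam"
        p.write_text(sams["GM_1"])
        with pysam.AlignmentFile(str(p), "r") as fh:
            n = sum(1 for _ in fh)
        assert n > 100
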