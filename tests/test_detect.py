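"""Site calling, substitution typing, SNP masking and aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from editkit.detect import (
    DetectConfig,
    DetectError,
    aggregate,
    call_sites,
    classify_type,
    mask_snps,
)
from editkit.pileup import COUNT_COLS, PILEUP_COLS


def pile(rows):
    """rows: (chrom, pos, ref, fA,fC,fG,fT, rA,rC,rG,rT)"""
    return pd.DataFrame(rows, columns=PILEUP_COLS)


def row(chrom, pos, ref, **counts):
    base = dict.fromkeys(COUNT_COLS, 0)
    base.update(counts)
    return [chrom, pos, ref] + [base[c] for c in COUNT_COLS]


class TestCallSites:
    def test_low_coverage_not_emitted(self):
        rna = pile([row("chr1", 10, "A", fA=8, fG=1)])
        assert call_sites(rna, None).empty  # coverage 9 < 10

    def test_basic_ag_call_with_clean_dna(self):
        rna = pile([row("chr1", 10, "A", fA=7, fG=3)])
        dna = pile([row("chr1", 10, "A", fA=20)])
        out = call_sites(rna, dna)
        assert len(out) == 1
        s = out.iloc[0]
        assert (s.strand, s.ref, s.alt, s.edit_type) == ("+", "A", "G", "AG")
        assert s.level == pytest.approx(0.3)
        assert not s.no_dna_support

    def test_high_level_rejected(self):
        rna = pile([row("chr1", 10, "A", fA=1, fG=99)])
        assert call_sites(rna, None).empty  # level 0.99 > 0.95

    def test_low_level_rejected(self):
        rna = pile([row("chr1", 10, "A", fA=499, fG=2)])
        out = call_sites(rna, None)
        assert out.empty  # level 0.004 < 0.01

    def test_dna_variant_reads_reject(self):
        rna = pile([row("chr1", 10, "A", fA=7, fG=3)])
        dna = pile([row("chr1", 10, "A", fA=19, fG=1)])
        assert call_sites(rna, dna).empty

    def test_dna_low_coverage_rejects(self):
        rna = pile([row("chr1", 10, "A", fA=7, fG=3)])
        dna = pile([row("chr1", 10, "A", fA=3)])
        assert call_sites(rna, dna).empty  # DNA coverage 3 < 5

    def test_dna_absent_flags_no_support(self):
        rna = pile([row("chr1", 10, "A", fA=7, fG=3)])
        dna = pile([row("chr1", 99, "A", fA=20)])
        out = call_sites(rna, dna)
        assert len(out) == 1 and out.iloc[0].no_dna_support

    def test_multiallelic_rejected(self):
        rna = pile([row("chr1", 10, "A", fA=10, fG=3, fC=3)])
        out = call_sites(rna, None)
        assert out.empty
        assert out.attrs["rejections"]["multiallelic"] == 1

    def test_minus_strand_reported_in_transcript_orientation(self):
        # forward-genome T>C evidence on '-' reads is an A>G site
        rna = pile([row("chr1", 10, "T", rT=7, rC=3)])
        out = call_sites(rna, None)
        s = out.iloc[0]
        assert (s.strand, s.ref, s.alt, s.edit_type) == ("-", "A", "G", "AG")

    def test_strand_majority_selects_evidence(self):
        rna = pile([row("chr1", 10, "A", fA=2, rA=14, rG=6)])
        s = call_sites(rna, None).iloc[0]
        assert s.strand == "-" and s.level == pytest.approx(0.3)

    @pytest.mark.parametrize("knob,tight", [
        ("min_rna_coverage", 25), ("min_variant_reads", 6),
        ("min_level", 0.2), ("min_samples", 1),
    ])
    def test_threshold_monotonicity(self, rng, knob, tight):
        """Tightening any threshold never adds a site."""
        rows = []
        for i in range(300):
            counts = dict.fromkeys(COUNT_COLS, 0)
            strand = "f" if rng.random() < 0.5 else "r"
            counts[strand + "A"] = int(rng.poisson(15))
            counts[strand + "G"] = int(rng.poisson(3))
            rows.append(["chr1", i + 1, "A"] + [counts[c] for c in COUNT_COLS])
        rna = pile(rows)
        base = DetectConfig()
        loose = set(map(tuple, call_sites(rna, None, base)[["chrom", "pos"]].values))
        kw = {knob: tight} if knob != "min_samples" else {}
        tight_cfg = DetectConfig(**kw)
        tighter = set(map(tuple, call_sites(rna, None, tight_cfg)[["chrom", "pos"]].values))
        assert tighter <= loose


class TestClassifyType:
    def test_twelve_distinct_codes(self):
        codes = {
            classify_type(r, a, "+")
            for r in "ACGT" for a in "ACGT" if r != a
        }
        assert len(codes) == 12

    @pytest.mark.parametrize("ref,alt,strand,expected", [
        ("A", "G", "+", "AG"),
        ("T", "C", "-", "AG"),
        ("C", "T", "-", "GA"),
        ("G", "C", "+", "GC"),
    ])
    def test_examples(self, ref, alt, strand, expected):
        assert classify_type(ref, alt, strand) == expected

    def test_strand_pairing_is_involution(self):
        for r in "ACGT":
            for a in "ACGT":
                if r == a:
                    continue
                plus = classify_type(r, a, "+")
                minus = classify_type(r, a, "-")
                # complementing both bases twice returns the original code
                assert classify_type(minus[0], minus[1], "-") == plus

    def test_invalid_inputs(self):
        with pytest.raises(DetectError):
            classify_type("A", "A", "+")
        with pytest.raises(DetectError):
            classify_type("N", "G", "+")


class TestMaskSnps:
    def _vcf(self, tmp_path, positions):
        lines = ["##fileformat=VCFv4.2",
                 "##contig=<ID=chr1,length=100000>",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        for c, p in positions:
            lines.append(f"{c}\t{p}\t.\tA\tG\t.\tPASS\t.")
        f = tmp_path / "s.vcf"
        f.write_text("\n".join(lines) + "\n")
        return str(f)

    def _sites(self, positions):
        return pd.DataFrame(
            [dict(chrom=c, pos=p, strand="+", ref="A", alt="G", edit_type="AG",
                  ref_count=7, alt_count=3, level=0.3, no_dna_support=False,
                  sample_id="s") for c, p in positions]
        )

    def test_listed_position_removed(self, tmp_path):
        vcf = self._vcf(tmp_path, [("chr1", 100)])
        out = mask_snps(self._sites([("chr1", 100), ("chr1", 200)]), [vcf])
        assert list(out.pos) == [200]
        assert out.attrs["mask_log"][vcf] == 1

    def test_empty_vcf_changes_nothing(self, tmp_path):
        vcf = self._vcf(tmp_path, [])
        sites = self._sites([("chr1", 1), ("chr1", 2)])
        out = mask_snps(sites, [vcf])
        assert len(out) == 2

    def test_bed_source(self, tmp_path):
        bed = tmp_path / "s.bed"
        bed.write_text("chr1\t99\t100\n")  # 0-based half-open = position 100
        out = mask_snps(self._sites([("chr1", 100), ("chr1", 101)]), [str(bed)])
        assert list(out.pos) == [101]

    def test_simulated_confounders_all_masked(self, default_sim, default_data, tmp_path):
        """Truth-table oracle: every SNP confounder is removed and no
        planted editing site is."""
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(default_data.vcf_text)
        sample = "GM_1"
        raw = call_sites(default_data.rna_pileups[sample],
                         default_data.dna_pileup, sample_id=sample)
        masked = mask_snps(raw, [str(vcf)])
        truth = default_sim.truth
        snp_keys = set(zip(truth[truth.site_class == "snp_confounder"].chrom,
                           truth[truth.site_class == "snp_confounder"].pos))
        edit_keys = set(zip(truth[truth.site_class != "snp_confounder"].chrom,
                            truth[truth.site_class != "snp_confounder"].pos))
        masked_keys = set(zip(masked.chrom, masked.pos))
        raw_keys = set(zip(raw.chrom, raw.pos))
        assert masked_keys & snp_keys == set()
        assert (raw_keys & edit_keys) <= masked_keys


class TestAggregate:
    def _calls(self, spec_map):
        """spec_map: sample -> list of (chrom,pos,strand,etype,level,alt)."""
        out = {}
        for sample, entries in spec_map.items():
            out[sample] = pd.DataFrame(
                [dict(chrom=c, pos=p, strand=s, ref=t[0], alt=t[1], edit_type=t,
                      ref_count=10, alt_count=a, level=lv, no_dna_support=False,
                      sample_id=sample)
                 for c, p, s, t, lv, a in entries]
            )
        return out

    STAGES = {f"{st}_{i}": st for st in ("GM", "DM1", "DM5") for i in (1, 2, 3)}

    def _coverage(self, positions, cov=50):
        return {
            s: pile([row("chr1", p, "A", fA=cov) for p in positions])
            for s in self.STAGES
        }

    def test_low_support_dropped(self):
        entry = [("chr1", 5, "+", "AG", 0.3, 5)]
        calls = self._calls({s: (entry if s in ("GM_1", "GM_2") else [])
                             for s in self.STAGES})
        m = aggregate(calls, self._coverage([5]), self.STAGES)
        assert m.n_sites() == 0

    def test_full_support_retained_with_nine_cells(self):
        entry = [("chr1", 5, "+", "AG", 0.3, 5)]
        calls = self._calls({s: entry for s in self.STAGES})
        m = aggregate(calls, self._coverage([5]), self.STAGES)
        assert m.n_sites() == 1
        assert m.levels.notna().to_numpy().sum() == 9
        assert (m.levels.iloc[0] == 0.3).all()

    def test_covered_but_uncalled_cells_are_zero(self):
        entry = [("chr1", 5, "+", "AG", 0.3, 5)]
        callers = ["GM_1", "GM_2", "DM1_1"]
        calls = self._calls({s: (entry if s in callers else [])
                             for s in self.STAGES})
        m = aggregate(calls, self._coverage([5]), self.STAGES)
        assert m.n_sites() == 1
        vals = m.levels.iloc[0]
        assert (vals[callers] == 0.3).all()
        others = [s for s in self.STAGES if s not in callers]
        assert (vals[others] == 0.0).all()  # covered at 50x, no variant

    def test_uncovered_cells_are_missing(self):
        entry = [("chr1", 5, "+", "AG", 0.3, 5)]
        callers = ["GM_1", "GM_2", "DM1_1"]
        calls = self._calls({s: (entry if s in callers else [])
                             for s in self.STAGES})
        coverage = self._coverage([5])
        coverage["DM5_3"] = pile([])  # no pileup rows at all
        m = aggregate(calls, coverage, self.STAGES)
        assert np.isnan(m.levels.iloc[0]["DM5_3"])

    def test_type_conflict_resolution(self):
        ag = [("chr1", 5, "+", "AG", 0.3, 5)]
        ac = [("chr1", 5, "+", "AC", 0.3, 9)]
        spec = {s: ag for s in ("GM_1", "GM_2", "GM_3", "DM1_1")}
        spec.update({s: ac for s in ("DM1_2", "DM1_3", "DM5_1")})
        spec.update({s: [] for s in self.STAGES if s not in spec})
        m = aggregate(self._calls(spec), self._coverage([5]), self.STAGES)
        # AG wins on samples (4 > 3) despite AC's higher alt reads
        assert list(m.levels.index.get_level_values("edit_type")) == ["AG"]

    def test_unknown_sample_in_stage_map_errors(self):
        calls = self._calls({"mystery": [("chr1", 5, "+", "AG", 0.3, 5)]})
        with pytest.raises(DetectError, match="mystery"):
            aggregate(calls, {}, self.STAGES)

    def test_union_oracle_on_fixture(self, rng):
        """Brute-force recount of retained keys equals aggregate output."""
        samples = list(self.STAGES)
        positions = list(range(1, 51))
        spec = {}
        for s in samples:
            entries = []
            for p in positions:
                if rng.random() < 0.4:
                    entries.append(("chr1", p, "+", "AG", round(float(rng.uniform(0.05, 0.9)), 3), 5))
            spec[s] = entries
        calls = self._calls(spec)
        m = aggregate(calls, self._coverage(positions), self.STAGES)
        # oracle: independent set union + support count
        support = {}
        for s, entries in spec.items():
            for c, p, st, t, lv, a in entries:
                support.setdefault((c, p, st, t), set()).add(s)
        expected = {k for k, v in support.items() if len(v) >= 3}
        got = set(m.levels.index)
        assert got == expected
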