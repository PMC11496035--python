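"""End-to-end pipeline: simulate (or load) -> ingest -> detect -> mask ->
aggregate -> annotate -> context -> miRNA rewiring -> stage statistics.

Every output TSV starts with a provenance header (tool version, config
hash, seed); a machine-readable ``manifest.json`` lists all outputs.
A stage failure halts the run with the stage name and cause and leaves a
``<stage>.partial`` marker in the output directory.
"""

from __future__ import annotations

import json
import logging
from collections import namedtuple
from pathlib import Path

import pandas as pd

import editkit
from editkit import annotate as ann_mod
from editkit import context as ctx_mod
from editkit import detect as det_mod
from editkit import mirna as mir_mod
from editkit import stats as stats_mod
from editkit.config import PipelineConfig
from editkit.pileup import pileup_from_tsv, write_pileup_tsv
from editkit.simulate import Simulator

logger = logging.getLogger(__name__)

_SiteKey = namedtuple("_SiteKey", "chrom pos strand edit_type ref_base alt_base ref alt")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _site_from_key(key) -> _SiteKey:
    chrom, pos, strand, etype = key
    ref, alt = etype[0], etype[1]
    return _SiteKey(chrom, int(pos), strand, etype, ref, alt, ref, alt)


def _write_tsv(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_pipeline(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    header = [f"# editkit v{editkit.__version__} seed={cfg.seed} config_hash={h}"]
    manifest: dict = {
        "tool": "editkit",
        "version": editkit.__version__,
        "seed": cfg.seed,
        "config_hash": h,
        "outputs": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(outdir)))

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    (outdir / f"{name}.partial").write_text(f"{exc}\n")
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done", name)

        return _Stage()

    # ------------------------------------------------------------------
    with stage("inputs"):
        if cfg.simulate:
            sim = Simulator(cfg.sim)
            sim.simulate_reference()
            sim.plant_sites()
            data = sim.simulate_pileups()
            indir = outdir / "inputs"
            indir.mkdir(exist_ok=True)
            (indir / "genome.fa").write_text(sim.fasta_text)
            (indir / "annotation.gtf").write_text(sim.gtf_text)
            (indir / "snps.vcf").write_text(data.vcf_text)
            (indir / "mirnas.fa").write_text(data.mirna_fasta)
            _write_tsv(sim.truth, indir / "truth.tsv", header)
            pileup_paths = {}
            for sample, df in data.rna_pileups.items():
                p = indir / f"pileup_{sample}.tsv"
                write_pileup_tsv(df, p, sample_id=sample)
                pileup_paths[sample] = str(p)
            write_pileup_tsv(data.dna_pileup, indir / "pileup_DNA.tsv", sample_id="DNA")
            for rel in ("genome.fa", "annotation.gtf", "snps.vcf", "mirnas.fa", "truth.tsv"):
                record(indir / rel)
            genome = sim.genome_strings()
            models = sim.models
            stage_map = data.samples
            snp_sources = [str(indir / "snps.vcf")]
            mirnas = mir_mod.read_mirnas(data.mirna_fasta)
            dna_path = str(indir / "pileup_DNA.tsv")
        else:
            import pyfaidx

            genome = pyfaidx.Fasta(cfg.inputs["genome"], as_raw=True, sequence_always_upper=True)
            models = ann_mod.load_gtf(cfg.inputs["gtf"])
            stage_map = dict(cfg.inputs["stage_map"])
            pileup_paths = dict(cfg.inputs["pileups"])
            dna_path = cfg.inputs.get("dna_pileup")
            snp_sources = list(cfg.inputs.get("snp_vcfs", [])) + list(
                cfg.inputs.get("snp_beds", [])
            )
            mirnas = (
                mir_mod.read_mirnas(cfg.inputs["mirna_fasta"])
                if "mirna_fasta" in cfg.inputs
                else {}
            )

    with stage("ingest"):
        pileups = {
            sample: pileup_from_tsv(path, genome, cfg.ingest)
            for sample, path in pileup_paths.items()
        }
        dna = pileup_from_tsv(dna_path, genome, cfg.ingest) if dna_path else None

    with stage("detect"):
        calls = {}
        for sample, pile in pileups.items():
            raw = det_mod.call_sites(pile, dna, cfg.detect, sample_id=sample)
            calls[sample] = det_mod.mask_snps(raw, snp_sources) if snp_sources else raw
        matrix = det_mod.aggregate(calls, pileups, stage_map, cfg.detect)
        matrix.to_tsv(outdir / "matrix.tsv", header)
        record(outdir / "matrix.tsv")
        _write_tsv(matrix.calls, outdir / "sites.tsv", header)
        record(outdir / "sites.tsv")

    with stage("annotate"):
        sites = [_site_from_key(k) for k in matrix.site_keys]
        annotations = [
            ann_mod.annotate_site(s, models, genome, flank=cfg.annotation_flank)
            for s in sites
        ]
        ann_df = pd.DataFrame([a.__dict__ for a in annotations])
        _write_tsv(ann_df, outdir / "annotation.tsv", header)
        record(outdir / "annotation.tsv")
        summary = ann_mod.summarize_regions(annotations)
        rows = [
            {"table": t, "key": k, "count": v}
            for t in ("regions", "effects", "biotypes", "genes_by_site_count")
            for k, v in sorted(summary[t].items())
        ]
        _write_tsv(pd.DataFrame(rows), outdir / "region_summary.tsv", header)
        record(outdir / "region_summary.tsv")

    with stage("context"):
        ag = matrix.subset_type("AG")
        if ag.n_sites():
            keys = ag.levels.index.to_frame(index=False)
            cm = ctx_mod.extract_context(keys, genome, width=cfg.context_width)
            bg = ctx_mod.genome_base_composition(genome)
            enr = ctx_mod.context_enrichment(cm, bg)
            _write_tsv(
                cm.frequencies.rename_axis("offset").reset_index(),
                outdir / "context_matrix.tsv", header,
            )
            _write_tsv(
                enr.rename_axis("offset").reset_index(),
                outdir / "context_enrichment.tsv", header,
            )
            record(outdir / "context_matrix.tsv")
            record(outdir / "context_enrichment.tsv")

    with stage("mirna"):
        rows = []
        if mirnas:
            model_by_id = {g.gene_id: g for g in models}
            for site, a in zip(sites, annotations):
                if a.region_class != "3'UTR" or a.edit_type != "AG" or not a.gene_id:
                    continue
                gene = model_by_id[a.gene_id]
                try:
                    utr, posmap = mir_mod.utr3_sequence(gene, genome)
                except mir_mod.MirnaError:
                    continue
                if site.pos not in posmap:
                    continue
                delta = mir_mod.delta_targets(
                    site, utr, posmap[site.pos], mirnas, cfg.mirna, gene_id=a.gene_id
                )
                rows.append(
                    dict(
                        chrom=site.chrom, pos=site.pos, strand=site.strand,
                        gene_id=a.gene_id,
                        lost=",".join(sorted(delta.lost)),
                        gained=",".join(sorted(delta.gained)),
                    )
                )
        _write_tsv(
            pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id", "lost", "gained"]),
            outdir / "mirna_delta.tsv", header,
        )
        record(outdir / "mirna_delta.tsv")

    with stage("stats"):
        diff = stats_mod.differential_sites(matrix, alpha=cfg.alpha)
        _write_tsv(diff, outdir / "differential.tsv", header)
        record(outdir / "differential.tsv")
        spec = stats_mod.stage_specific_sites(matrix, min_support=cfg.min_stage_support)
        _write_tsv(spec, outdir / "stage_specific.tsv", header)
        record(outdir / "stage_specific.tsv")

        site_table = pd.DataFrame(
            {
                "chrom": matrix.levels.index.get_level_values("chrom"),
                "mean_level": matrix.mean_levels().to_numpy(),
            }
        )
        gene_ids = {(a.chrom, a.pos): a.gene_id for a in annotations}
        site_table["gene_id"] = [
            gene_ids.get((c, p))
            for c, p in zip(
                matrix.levels.index.get_level_values("chrom"),
                matrix.levels.index.get_level_values("pos"),
            )
        ]
        chrom_lengths = {c: len(genome[c]) for c in (genome.keys() if hasattr(genome, "keys") else genome)}
        expr = None
        if "expression" in cfg.inputs:
            expr = pd.read_csv(cfg.inputs["expression"], sep="\t", comment="#")
        corr = stats_mod.spearman_correlations(site_table, chrom_lengths, expr)
        corr_df = pd.DataFrame(
            [
                dict(analysis=k, rho=v.rho, p_value=v.p_value, n=v.n, note=v.note)
                for k, v in corr.items()
            ]
        )
        _write_tsv(corr_df, outdir / "correlations.tsv", header)
        record(outdir / "correlations.tsv")

        if "gmt" in cfg.inputs:
            query = sorted({g for g in site_table["gene_id"] if g})
            universe = sorted({g.gene_id for g in models})
            enr_df = stats_mod.enrich(query, cfg.inputs["gmt"], universe)
            _write_tsv(enr_df, outdir / "enrichment.tsv", header)
            record(outdir / "enrichment.tsv")
        if "edges" in cfg.inputs:
            hubs = stats_mod.hub_genes(cfg.inputs["edges"])
            _write_tsv(hubs, outdir / "hubs.tsv", header)
            record(outdir / "hubs.tsv")

    with stage("manifest"):
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    logger.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), outdir)
    return outdir
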