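"""Stage-wise statistics: differential editing (one-way ANOVA), stage-
specific site calling, Spearman correlations, Fisher gene-set
enrichment, and degree-based hub summarisation.

Conventions: undetected-but-covered matrix cells enter the ANOVA as
level 0 (absence of editing at adequate coverage is evidence of a level
near 0); insufficient-coverage cells are excluded.  The differential
call uses an uncorrected p < alpha threshold, with a Benjamini-Hochberg
column always emitted alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from editkit.detect import EditingMatrix

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


def differential_sites(
    matrix: EditingMatrix,
    alpha: float = 0.05,
    method: str = "anova",
) -> pd.DataFrame:
    """Per-site one-way test of editing level across stages.

    Returns one row per testable site with per-stage means, the F (or
    Kruskal-Wallis H) statistic, p, BH-adjusted p and a ``significant``
    flag (p < alpha, uncorrected).  Sites where fewer than two stages
    have >= 2 usable values are skipped with a reason.
    """
    stages = sorted(set(matrix.stages.values()), key=list(matrix.stages.values()).index)
    if len(stages) < 2:
        raise StatsError("need >= 2 stages for differential testing")
    rows, skipped = [], []
    for key, level_row in matrix.levels.iterrows():
        groups = []
        means = {}
        ns = {}
        for stage in stages:
            vals = level_row[matrix.stage_samples(stage)].dropna().to_numpy(float)
            means[stage] = float(vals.mean()) if len(vals) else np.nan
            ns[stage] = len(vals)
            if len(vals) >= 2:
                groups.append(vals)
        if len(groups) < 2:
            skipped.append((key, "fewer than 2 stages with >= 2 usable values"))
            continue
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            stat, p = 0.0, 1.0
        elif method == "kruskal":
            stat, p = sps.kruskal(*groups)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.f_oneway(*groups)
            if not np.isfinite(p):
                p = 0.0
        row = {"chrom": key[0], "pos": key[1], "strand": key[2], "edit_type": key[3]}
        row.update({f"mean_{s}": means[s] for s in stages})
        row.update({f"n_{s}": ns[s] for s in stages})
        row["F_statistic"] = float(stat)
        row["p_value"] = float(p)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_value"] < alpha
    else:
        out["p_bh"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["skipped"] = skipped
    logger.info(
        "differential_sites: %d tested, %d significant, %d skipped",
        len(out), int(out["significant"].sum()) if len(out) else 0, len(skipped),
    )
    return out


def pairwise_welch(matrix: EditingMatrix) -> pd.DataFrame:
    """Optional pairwise Welch t-tests between stages (two-sided)."""
    stages = sorted(set(matrix.stages.values()), key=list(matrix.stages.values()).index)
    rows = []
    for key, level_row in matrix.levels.iterrows():
        for i, a in enumerate(stages):
            for b in stages[i + 1 :]:
                va = level_row[matrix.stage_samples(a)].dropna().to_numpy(float)
                vb = level_row[matrix.stage_samples(b)].dropna().to_numpy(float)
                if len(va) < 2 or len(vb) < 2:
                    continue
                both = np.concatenate([va, vb])
                if np.all(both == both[0]):
                    t, p = 0.0, 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        t, p = sps.ttest_ind(va, vb, equal_var=False)
                    if not np.isfinite(p):
                        p = 1.0 if np.allclose(va.mean(), vb.mean()) else 0.0
                rows.append(
                    dict(chrom=key[0], pos=key[1], strand=key[2], edit_type=key[3],
                         stage_a=a, stage_b=b, t=float(t), p_value=float(p))
                )
    return pd.DataFrame(rows)


def stage_specific_sites(matrix: EditingMatrix, min_support: int = 1) -> pd.DataFrame:
    """Sites called in >= ``min_support`` samples of exactly one stage and
    in zero samples of every other stage."""
    stages = sorted(set(matrix.stages.values()), key=list(matrix.stages.values()).index)
    support = pd.DataFrame(
        {s: matrix.called[matrix.stage_samples(s)].sum(axis=1) for s in stages}
    )
    rows = []
    for key, counts in support.iterrows():
        nonzero = [s for s in stages if counts[s] > 0]
        if len(nonzero) == 1 and counts[nonzero[0]] >= min_support:
            row = {"chrom": key[0], "pos": key[1], "strand": key[2],
                   "edit_type": key[3], "stage": nonzero[0]}
            row.update({f"support_{s}": int(counts[s]) for s in stages})
            rows.append(row)
    out = pd.DataFrame(rows)
    logger.info("stage_specific_sites: %d calls", len(out))
    return out


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    note: str = ""


def _spearman(x, y) -> CorrelationResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        return CorrelationResult(np.nan, np.nan, len(x), "fewer than 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, np.nan, len(x), "constant input; rho undefined")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), len(x))


def spearman_correlations(
    site_table: pd.DataFrame,
    chrom_lengths: dict[str, int],
    expression: pd.DataFrame | None = None,
) -> dict[str, CorrelationResult]:
    """Spearman correlations of (a) per-chromosome site count vs length,
    (b) per-chromosome mean editing level vs length, and optionally
    (c) per-gene mean level vs expression.

    ``site_table`` needs ``chrom`` and ``mean_level`` columns (and
    ``gene_id`` for the expression analysis); ``expression`` is a
    DataFrame with ``gene_id`` and ``expression`` columns.
    """
    out: dict[str, CorrelationResult] = {}
    per_chrom = site_table.groupby("chrom").agg(
        n_sites=("chrom", "size"), mean_level=("mean_level", "mean")
    )
    chroms = [c for c in per_chrom.index if c in chrom_lengths]
    lengths = [chrom_lengths[c] for c in chroms]
    out["count_vs_length"] = _spearman(per_chrom.loc[chroms, "n_sites"], lengths)
    out["level_vs_length"] = _spearman(per_chrom.loc[chroms, "mean_level"], lengths)
    if expression is not None and "gene_id" in site_table.columns:
        per_gene = (
            site_table.dropna(subset=["gene_id"])
            .groupby("gene_id")["mean_level"]
            .mean()
            .reset_index()
            .merge(expression, on="gene_id")
        )
        out["level_vs_expression"] = _spearman(
            per_gene["mean_level"], per_gene["expression"]
        )
    return out


def read_gmt(source: str) -> dict[str, set[str]]:
    """Parse GMT gene sets (name, description, genes...).  Hand-rolled
    because no pre-installed library reads GMT."""
    if "\n" in source or "\t" in source:
        lines = source.splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    sets: dict[str, set[str]] = {}
    for line in lines:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise StatsError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrich(
    query_genes,
    gene_sets: dict[str, set[str]] | str,
    universe,
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact enrichment of ``query_genes`` in
    each gene set, BH-adjusted across all tested sets, sorted by p."""
    if isinstance(gene_sets, str):
        gene_sets = read_gmt(gene_sets)
    query = set(query_genes)
    uni = set(universe)
    if not query:
        raise StatsError("empty query gene list")
    if not gene_sets:
        raise StatsError("empty gene-set collection")
    if not query <= uni:
        raise StatsError("query genes must be a subset of the universe")
    N, n = len(uni), len(query)
    rows = []
    for name, genes in gene_sets.items():
        genes = genes & uni
        K = len(genes)
        k = len(genes & query)
        table = [[k, n - k], [K - k, N - K - n + k]]
        _, p = sps.fisher_exact(table, alternative="greater")
        rows.append(dict(set_name=name, k=k, K=K, n=n, N=N, p_value=float(p)))
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def hub_genes(edges, top_n: int = 14) -> pd.DataFrame:
    """Rank genes by degree on the undirected simple graph built from an
    edge list (DataFrame with two columns, or a TSV path).  Duplicate
    edges collapse; self-loops are dropped with a warning."""
    if isinstance(edges, str):
        edges = pd.read_csv(edges, sep="\t", header=None, comment="#").iloc[:, :2]
    if len(edges) == 0:
        raise StatsError("empty edge list")
    g = nx.Graph()
    n_self = 0
    for a, b in edges.itertuples(index=False):
        if a == b:
            n_self += 1
            continue
        g.add_edge(str(a), str(b))
    if n_self:
        logger.warning("hub_genes: dropped %d self-loop(s)", n_self)
    ranked = sorted(g.degree, key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(ranked, columns=["gene", "degree"])
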