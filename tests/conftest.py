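"""Shared fixtures: one session-scoped default simulation plus small
helpers for building genomes and matrices by hand."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from editkit.detect import EditingMatrix
from editkit.simulate import SimConfig, Simulator


@pytest.fixture(scope="session")
def default_sim():
    """The default stated world: 2 chromosomes x 100 kb, 12 genes, 300
    planted editing sites, 100 SNP confounders, 3 stages x 3 replicates
    at mean coverage 100."""
    sim = Simulator(SimConfig(seed=1))
    sim.simulate_reference()
    sim.plant_sites()
    return sim


@pytest.fixture(scope="session")
def default_data(default_sim):
    return default_sim.simulate_pileups()


@pytest.fixture(scope="session")
def default_genome(default_sim):
    return default_sim.genome_strings()


@pytest.fixture()
def small_cfg():
    return SimConfig(
        seed=7,
        n_chroms=1,
        chrom_length=12_000,
        n_genes=2,
        n_edit_sites=10,
        n_snps=2,
        n_mirna_gain=1,
        n_mirna_lost=1,
        n_recoding=4,
        rna_coverage_mean=60.0,
        error_rate=0.0,
    )


@pytest.fixture()
def small_sim(small_cfg):
    sim = Simulator(small_cfg)
    sim.simulate_reference()
    sim.plant_sites()
    return sim


def make_matrix(levels_rows, samples, stages, called=None):
    """Build an EditingMatrix from a dict {site_key: [levels...]}."""
    idx = pd.MultiIndex.from_tuples(
        list(levels_rows), names=["chrom", "pos", "strand", "edit_type"]
    )
    lv = pd.DataFrame(
        [levels_rows[k] for k in levels_rows], index=idx, columns=samples, dtype=float
    )
    if called is None:
        cl = lv.notna() & (lv > 0)
    else:
        cl = pd.DataFrame(
            [called[k] for k in called], index=idx, columns=samples, dtype=bool
        )
    return EditingMatrix(lv, cl, stages)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
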