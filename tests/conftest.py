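import numpy as np
import pandas as pd
import pytest

from strandmod.genome import GenomeLayout, GenomicInterval, GeneModel, StrandedReadSet
from strandmod.simulate import SimulationConfig, simulate_experiment

ACCEPTANCE_SEED = 20240901


def make_reads(intervals, sample_id="s1", cell_type="D1", assay="5mC", replicate=1):
    """Read set from (chrom, start, end, strand) tuples."""
    ivs = [GenomicInterval(c, s, e, st) for c, s, e, st in intervals]
    return StrandedReadSet.from_intervals(sample_id, cell_type, assay, replicate, ivs)


@pytest.fixture(scope="session")
def tiny_layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured experiment, shared by integration tests."""
    return SimulationConfig(
        seed=424242,
        chrom_sizes={"chr1": 2_000_000, "chr2": 2_000_000},
        n_genes=80,
        gene_length_range=(4_000, 15_000),
        n_repeats=80,
        rna_reads_per_sample=300_000,
        reads_per_sample={"5mC": 120_000, "5hmC": 120_000, "input": 30_000},
        n_clusters=4,
        cluster_span_range=(4_000, 40_000),
        cluster_min_gap=100_000,
        n_tfs=12,
        n_enriched_tfs=2,
        sites_per_tf=60,
    )


@pytest.fixture(scope="session")
def small_exp(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def planted_config():
    """The planted-cluster recovery scale: 2 x 10 Mb, 3+3 reps, 0.5 M reads."""
    return SimulationConfig(seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def planted_exp(planted_config):
    return simulate_experiment(planted_config)


@pytest.fixture(scope="session")
def null_config():
    return SimulationConfig(seed=ACCEPTANCE_SEED + 1, n_clusters=0, n_enriched_tfs=0)


@pytest.fixture(scope="session")
def null_exp(null_config):
    return simulate_experiment(null_config)


def mod_groups(exp, assay):
    """(ordered read sets, group_a ids, group_b ids) for one assay."""
    samples = [s for s in exp.samples.values() if s.assay == assay]
    ga = sorted(s.sample_id for s in samples if s.cell_type == "D1")
    gb = sorted(s.sample_id for s in samples if s.cell_type == "D2")
    ordered = [exp.samples[sid] for sid in ga + gb]
    return ordered, ga, gb


@pytest.fixture(scope="session")
def diff_5mc_planted(planted_exp):
    from strandmod.genome import tile_genome, count_reads_in_windows
    from strandmod.differential import differential_windows

    layout = planted_exp.genome.layout
    ordered, ga, gb = mod_groups(planted_exp, "5mC")
    wc = count_reads_in_windows(ordered, tile_genome(layout, 1000), layout, 1000)
    return differential_windows(wc, ga, gb)


@pytest.fixture(scope="session")
def diff_5mc_null(null_exp):
    from strandmod.genome import tile_genome, count_reads_in_windows
    from strandmod.differential import differential_windows

    layout = null_exp.genome.layout
    ordered, ga, gb = mod_groups(null_exp, "5mC")
    wc = count_reads_in_windows(ordered, tile_genome(layout, 1000), layout, 1000)
    return differential_windows(wc, ga, gb)
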