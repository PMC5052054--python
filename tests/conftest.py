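"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from wormcycle.stages import stage_grid
from wormcycle.synthetic_data import (
    GenomeConfig,
    SeriesSpec,
    SimulationConfig,
    simulate_genome,
    simulate_junctions,
    simulate_series,
)


@pytest.fixture(scope="session")
def small_sim():
    """Three mixed-stage series, 80 genes, 20 stages, moderate noise."""
    cfg = SimulationConfig(n_genes=80, n_stages=20, seed=11, lognormal_sd=0.2)
    series, truth = simulate_series(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def noiseless_identity_sim():
    """One series whose samples are point masses on each stage in turn."""
    spec = SeriesSpec(
        t0=0.0, growth_rate=1.0, sigma0=0.0, variance_rate=0.0,
        sample_times=tuple(30.0 * np.arange(20)),
    )
    cfg = SimulationConfig(n_genes=40, n_stages=20, series_specs=(spec,),
                           lognormal_sd=0.0, seed=7)
    series, truth = simulate_series(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def junction_data():
    return simulate_junctions(n_pairs=40, n_constitutive=30, n_samples=24, seed=5)


@pytest.fixture(scope="session")
def genome():
    return simulate_genome(GenomeConfig(seed=4))


@pytest.fixture(scope="session")
def grid20():
    return stage_grid(20)


def random_junction_table(rng: np.random.Generator, n_junctions=40, n_samples=6, n_genes=8):
    """Unstructured junction table for oracle-equivalence tests."""
    rows = []
    samples = [f"s{j}" for j in range(n_samples)]
    for i in range(n_junctions):
        start = int(rng.integers(0, 500)) * 10
        end = start + int(rng.integers(5, 40)) * 10
        gene = f"g{rng.integers(0, n_genes)}" if rng.random() < 0.8 else ""
        counts = rng.poisson(rng.uniform(0, 30), size=n_samples)
        rows.append(
            ["chrT", start, end, rng.choice(["+", "-"]), gene,
             rng.choice(["known", "novel"]), *counts]
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id", "status", *samples]
    )
    table.insert(
        0, "junction_id",
        [f"{r.chrom}:{r.start}-{r.end}:{r.strand}:{i}" for i, r in enumerate(table.itertuples())],
    )
    return table
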