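"""Shared fixtures: small deterministic datasets and the default synthetic
benchmark (10 kb genome, 5 poly(A/T) loci, 30x coverage, 100 bp reads)."""

import numpy as np
import pytest

from polycor.pipeline import PipelineConfig, correct_pairs
from polycor.simulate import simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def benchmark_readset():
    genome = simulate_genome(length=10_000, n_loci=5, run_len_range=(15, 25), seed=1)
    return simulate_reads(
        genome,
        coverage=30,
        read_len=100,
        insert_mean=300,
        insert_sd=30,
        error_rate=0.001,
        hotspot_multiplier=10,
        seed=1,
    )


@pytest.fixture(scope="session")
def benchmark_run(benchmark_readset):
    """One full pipeline pass over the default benchmark."""
    cfg = PipelineConfig(seed=1)
    merged, report, debug = correct_pairs(cfg, benchmark_readset.pairs)
    return merged, report, debug


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
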