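"""Shared fixtures: seeded synthetic capture experiments at two scales."""

from __future__ import annotations

import numpy as np
import pytest

from capqc import alignments
from capqc.panels import comparable_partition
from capqc.simulate import SimConfig, make_genome, make_panels, run_simulation


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but fully featured experiment: endogenous fraction 30%,
    deamination, duplicates, a mitochondrial compartment, 8x enrichment."""
    cfg = SimConfig(
        seed=11,
        genome_length=120_000,
        gc_blocks=[(120_000, 0.42)],
        n_snps_a=40,
        n_snps_b=80,
        n_reads=20_000,
        endogenous_fraction=0.3,
        mito_fraction=0.02,
        duplication_rate=0.15,
        deamination_d0=0.3,
        deamination_lambda=0.3,
        enrichment_factor={"a": 8.0, "b": 8.0},
    )
    out = tmp_path_factory.mktemp("small_sim")
    genome, panels, reads = run_simulation(cfg, out, captured_panels=("a", None))
    return {
        "cfg": cfg, "dir": out, "genome": genome, "panels": panels,
        "reads": reads, "partition": comparable_partition(*panels),
    }


@pytest.fixture(scope="session")
def small_sam_reads(small_sim):
    return list(alignments.read_sam(small_sim["dir"] / "reads_a.sam"))


@pytest.fixture(scope="session")
def toy_genome_panels():
    cfg = SimConfig(seed=3, genome_length=60_000, n_snps_a=10, n_snps_b=20,
                    n_reads=10)
    genome = make_genome(cfg)
    panels = make_panels(cfg, genome)
    return cfg, genome, panels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
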