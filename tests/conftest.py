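import numpy as np
import pytest

from ripcall import (
    Feature,
    FeatureKind,
    GenomeAnnotation,
    PipelineConfig,
    ReadSet,
    SimulationConfig,
    TssRecord,
)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_sim():
    """A scaled-down simulation for fast unit tests."""
    return SimulationConfig(
        genome_length=60_000,
        n_cds=8,
        n_trna=4,
        n_rrna=1,
        n_srna=4,
        n_leaders=3,
        ip_library_size=30_000,
        ctrl_library_size=5_000,
        seed=42,
    )


@pytest.fixture
def toy_annotation():
    """A hand-built annotation exercising every feature kind."""
    return GenomeAnnotation(
        genome_id="toy",
        genome_length=10_000,
        features=[
            Feature("trnaA", FeatureKind.TRNA, 500, 575, "+"),
            Feature("cdsA", FeatureKind.CDS, 2001, 2600, "+"),
            Feature("srnaA", FeatureKind.SRNA, 4000, 4150, "-"),
            Feature("cdsB", FeatureKind.CDS, 6001, 6300, "-"),
            Feature("rrnaA", FeatureKind.RRNA, 8000, 9200, "+"),
        ],
    )


@pytest.fixture
def toy_tss():
    return [TssRecord(1801, "+"), TssRecord(4150, "-"), TssRecord(6550, "-")]


def random_reads(rng, n, genome_length, read_length=35):
    starts = rng.integers(1, genome_length - read_length + 1, size=n)
    ends = starts + read_length - 1
    return ReadSet("random", starts, ends, n)
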