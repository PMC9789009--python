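import numpy as np
import pytest
from hypothesis import settings

from cnvdosage.core import GenomicInterval, TranscriptModel
from cnvdosage.synthetic import SimulationConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("suite")


# the worked transcript used across annotation tests: two exons with one
# intron, plus-strand, body (10000, 12000)
@pytest.fixture
def two_exon_transcript():
    return TranscriptModel(
        transcript_id="tx1",
        chrom="1",
        strand="+",
        exons=(
            GenomicInterval("1", 10_000, 10_500),
            GenomicInterval("1", 11_500, 12_000),
        ),
    )


def small_sim_config(**overrides) -> SimulationConfig:
    """A compact cohort used throughout the suite: same structure as the
    default study conditions, smaller genome and call counts."""
    base = dict(
        chrom_lengths={"1": 8_000_000, "2": 6_000_000},
        n_transcripts=400,
        expected_deletions_per_animal=120,
        expected_duplications_per_animal=120,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated cohort shared by read-only tests (default effect sizes)."""
    return simulate_dataset(small_sim_config(), seed=11)


@pytest.fixture(scope="session")
def null_dataset():
    """A cohort with no dosage effects (delta = gamma = 1)."""
    return simulate_dataset(
        small_sim_config(deletion_multiplier=1.0, duplication_multiplier=1.0), seed=7
    )
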