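"""Shared fixtures: hand-built records and small simulated cohorts."""

import numpy as np
import pytest

from sizenipt import CohortSimConfig, FetalFraction, SampleRecord, simulate_cohort
from sizenipt.chromosomes import AUTOSOMES, CHROMOSOMES


@pytest.fixture
def tiny_record():
    """One sample, chr1: 3 fragments, chr2: 1 fragment."""
    return SampleRecord(
        "s1",
        "euploid",
        {("chr1", 100): 2, ("chr1", 150): 1, ("chr2", 150): 1},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """18-sample cohort at shallow depth; fixed fetal fraction 0.10."""
    config = CohortSimConfig(
        n_per_class={"T13": 2, "T18": 2, "T21": 2, "euploid": 12},
        depth=30_000,
        fetal_fraction=FetalFraction.fixed(0.10),
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_config():
    return CohortSimConfig(
        n_per_class={"T13": 2, "T18": 2, "T21": 2, "euploid": 12},
        depth=30_000,
        fetal_fraction=FetalFraction.fixed(0.10),
        seed=42,
    )


def random_record(rng: np.random.Generator, sample_id="r", label="euploid",
                  n_keys=80, chroms=CHROMOSOMES, lengths=(60, 250)):
    """A random valid SampleRecord for property tests."""
    counts = {}
    for _ in range(n_keys):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        counts[(chrom, length)] = counts.get((chrom, length), 0) + int(
            rng.integers(1, 50)
        )
    # guarantee a positive reference-autosome count in any mid window
    for c in AUTOSOMES:
        counts[(c, 120)] = counts.get((c, 120), 0) + 5
    return SampleRecord(sample_id, label, counts)
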