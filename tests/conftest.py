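import numpy as np
import pytest

from svscape.catalog_io import GenomeModel, ReferenceGenome
from svscape.synthetic_data import (ChromothripsisSpec, CohortConfig,
                                    FoldbackSpec, HotspotLocus,
                                    simulate_cohort)


@pytest.fixture(scope="session")
def tiny_genome():
    return GenomeModel(names=("chrA", "chrB"),
                       lengths={"chrA": 1_000_000, "chrB": 500_000})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_cohort_config(n_samples=6, seed=3) -> CohortConfig:
    """A reduced cohort (8 Mb genome) for fast end-to-end tests."""
    return CohortConfig(
        n_samples=n_samples, seed=seed,
        chrom_lengths={"chr1": 3_000_000, "chr2": 2_500_000,
                       "chr3": 2_000_000, "chr4": 1_500_000},
        sv_count_range=(19, 300), tdp_sv_count_range=(150, 300),
        hotspots=[HotspotLocus("chr1", 1_000_000, 1_060_000, "short",
                               span_range=(8e3, 5e4))],
        chromothripsis=ChromothripsisSpec("chr3", 200_000, 400_000, 30,
                                          (2, 3), 0.3),
        foldback=FoldbackSpec("chr2", 2_000_000, 5_000,
                              (1_700_000, 2_000_000), 8, True, 1, 0.3),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    _, _, _, seqs, _ = small_cohort
    return ReferenceGenome(seqs)
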