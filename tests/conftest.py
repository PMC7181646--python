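"""Shared fixtures: a toy genome and a small synthetic bundle."""

import logging

import pytest

from peaklink import GenomeTable, GenomicInterval, PeakSet, SyntheticConfig

logging.disable(logging.WARNING)


@pytest.fixture
def genome() -> GenomeTable:
    return GenomeTable([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    """A scaled-down synthetic configuration for fast unit tests."""
    return SyntheticConfig(
        seed=42,
        chroms=[("chr1", 2_000_000), ("chr2", 1_000_000)],
        n_genes=200,
        n_peaks_A=300,
        n_peaks_B=300,
        n_peaks_igg=300,
        n_tags=5_000,
        motif_density_per_mb=20.0,
        de_truth=(20, 5),
    )


def make_peaks(intervals, label="peaks", genome=None) -> PeakSet:
    ivs = [GenomicInterval(*args) if isinstance(args, tuple) else args for args in intervals]
    return PeakSet(label=label, intervals=ivs, genome=genome)
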