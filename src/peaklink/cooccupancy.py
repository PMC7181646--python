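"""Cross-factor peak comparison.

Two factors co-occupy a site when their peaks, each expanded to a
fixed-width window centered on the peak midpoint (100 bp by default),
overlap by at least one base.  Peak-peak distances are measured between
the original peak midpoints of overlapping window pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from peaklink.genomic import (
    GenomeTable,
    GenomicInterval,
    PeakSet,
    expand_to_window,
    merge_intervals,
    midpoint,
    overlap_pairs,
)


@dataclass
class CooccupancyResult:
    """Counts and fractions of co-occurring peaks between two sets.

    ``n_common_A``/``n_common_B`` count peaks of each set with at least
    one partner; because the printed overlap percentage in this kind of
    analysis rarely names its denominator, fractions are reported for
    A, B and the union of both sets.
    """

    n_A: int
    n_B: int
    n_common_A: int
    n_common_B: int
    n_pairs: int
    frac_A: float
    frac_B: float
    frac_union: float
    common_regions: list[GenomicInterval] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_A": self.n_A,
            "n_B": self.n_B,
            "n_common_A": self.n_common_A,
            "n_common_B": self.n_common_B,
            "n_pairs": self.n_pairs,
            "frac_A": self.frac_A,
            "frac_B": self.frac_B,
            "frac_union": self.frac_union,
            "n_common_regions": len(self.common_regions),
        }


@dataclass
class DistanceStats:
    """Midpoint-to-midpoint distances of co-occurring peak pairs.

    ``median_bp`` is the exact sample median; it is None (undefined,
    never 0) when no pair overlaps.
    """

    distances: list[int]
    median_bp: float | None
    n_pairs: int

    def to_dict(self) -> dict:
        return {"median_bp": self.median_bp, "n_pairs": self.n_pairs}


def _check_same_genome(A: PeakSet, B: PeakSet) -> None:
    if A.genome is not None and B.genome is not None and A.genome != B.genome:
        raise ValueError("peak sets bound to different genomes")


def cooccurring_peaks(A: PeakSet, B: PeakSet, window: int = 100) -> CooccupancyResult:
    """Co-occupancy of two peak sets through midpoint-centered windows.

    Both sets are expanded to ``window``-bp windows; pairs of windows
    sharing >= 1 bp count as co-occurring.  ``common_regions`` is the
    merged union of every overlapping window pair.
    """
    _check_same_genome(A, B)
    genome = A.genome or B.genome
    wA = [expand_to_window(iv, window, genome) for iv in A]
    wB = [expand_to_window(iv, window, genome) for iv in B]
    setA = PeakSet(label=A.label, intervals=wA)
    setB = PeakSet(label=B.label, intervals=wB)
    pairs = overlap_pairs(setA, setB)
    common_a = {i for i, _ in pairs}
    common_b = {j for _, j in pairs}
    n_A, n_B = len(A), len(B)
    regions = merge_intervals(
        [w for k, w in enumerate(wA) if k in common_a]
        + [w for k, w in enumerate(wB) if k in common_b]
    )
    return CooccupancyResult(
        n_A=n_A,
        n_B=n_B,
        n_common_A=len(common_a),
        n_common_B=len(common_b),
        n_pairs=len(pairs),
        frac_A=len(common_a) / n_A if n_A else 0.0,
        frac_B=len(common_b) / n_B if n_B else 0.0,
        frac_union=(len(common_a) + len(common_b)) / (n_A + n_B) if n_A + n_B else 0.0,
        common_regions=regions,
    )


def median_peak_distance(
    A: PeakSet, B: PeakSet, window: int = 100, pairing: str = "nearest"
) -> DistanceStats:
    """Median |midpoint(a) - midpoint(b)| over co-occurring window pairs.

    pairing="nearest" keeps, for each A peak with at least one
    overlapping B window, the distance to its nearest such partner;
    pairing="all_pairs" keeps every overlapping pair (and is exactly
    symmetric in A and B).
    """
    if pairing not in ("nearest", "all_pairs"):
        raise ValueError(f"unknown pairing {pairing!r}")
    _check_same_genome(A, B)
    genome = A.genome or B.genome
    wA = PeakSet(label=A.label, intervals=[expand_to_window(iv, window, genome) for iv in A])
    wB = PeakSet(label=B.label, intervals=[expand_to_window(iv, window, genome) for iv in B])
    pairs = overlap_pairs(wA, wB)
    mids_a = [midpoint(iv) for iv in A]
    mids_b = [midpoint(iv) for iv in B]
    if pairing == "nearest":
        best: dict[int, int] = {}
        for i, j in pairs:
            d = abs(mids_a[i] - mids_b[j])
            if i not in best or d < best[i]:
                best[i] = d
        distances = sorted(best.values())
    else:
        distances = sorted(abs(mids_a[i] - mids_b[j]) for i, j in pairs)
    if not distances:
        return DistanceStats(distances=[], median_bp=None, n_pairs=0)
    return DistanceStats(
        distances=distances,
        median_bp=float(np.median(distances)),
        n_pairs=len(distances),
    )


def pairwise_distance_matrix(
    sets: list[PeakSet], window: int = 100, pairing: str = "nearest"
) -> np.ndarray:
    """Matrix of median peak-peak distances between every pair of sets.

    Entry (i, j) is ``median_peak_distance(sets[i], sets[j])``; the
    diagonal is 0 and undefined entries (no overlap) are NaN.  With
    pairing="all_pairs" the matrix is exactly symmetric.
    """
    if len(sets) < 2:
        raise ValueError("pairwise_distance_matrix requires >= 2 peak sets")
    n = len(sets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                mat[i, j] = 0.0
                continue
            stats = median_peak_distance(sets[i], sets[j], window=window, pairing=pairing)
            mat[i, j] = math.nan if stats.median_bp is None else stats.median_bp
    return mat
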