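"""Chromatin-state enrichment, motif co-localization and tag pileups.

A chromatin-state segmentation (ChromHMM-style) is a labeled partition
of the genome.  Peaks are assigned the state at their midpoint, and
per-state peak frequencies of a sample are compared against an IgG
(non-specific antibody) background as log2 fold-changes.  Tag pileups
accumulate 5' read ends around anchors (TSS or motif midpoints) with
strand-aware offsets.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from peaklink.genomic import (
    GenomeTable,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    midpoint,
    overlap_pairs,
)

UNANNOTATED = "Unannotated"

DEFAULT_PSEUDOCOUNT = 1e-4


class Segmentation:
    """A labeled partition of the genome into chromatin states.

    Segments must not overlap within a chromosome; gaps are permitted
    and positions falling in a gap are reported as ``Unannotated``.
    """

    def __init__(
        self,
        per_chrom: dict[str, tuple[list[int], list[int], list[str]]],
        state_catalog: list[str],
        genome: GenomeTable | None = None,
    ):
        self.per_chrom = per_chrom
        self.state_catalog = list(state_catalog)
        self.genome = genome
        for chrom, (starts, ends, states) in per_chrom.items():
            for k in range(1, len(starts)):
                if starts[k] < ends[k - 1]:
                    raise ValueError(
                        f"segmentation overlap on {chrom} at {starts[k]} < {ends[k - 1]}"
                    )
            for st in states:
                if st not in self.state_catalog:
                    raise ValueError(f"state {st!r} missing from catalog")

    @classmethod
    def from_intervals(
        cls,
        intervals: list[GenomicInterval],
        state_catalog: list[str] | None = None,
        genome: GenomeTable | None = None,
    ) -> "Segmentation":
        ivs = sorted(intervals, key=GenomicInterval.sort_key)
        per_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
        for iv in ivs:
            starts, ends, states = per_chrom.setdefault(iv.chrom, ([], [], []))
            starts.append(iv.start)
            ends.append(iv.end)
            states.append(iv.name)
        if state_catalog is None:
            state_catalog = sorted({iv.name for iv in ivs})
        return cls(per_chrom, state_catalog, genome=genome)

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.per_chrom):
            starts, ends, states = self.per_chrom[chrom]
            out.extend(
                GenomicInterval(chrom, s, e, name=st)
                for s, e, st in zip(starts, ends, states)
            )
        return out

    def state_at(self, chrom: str, pos: int) -> str:
        """State covering position ``pos`` (half-open segments)."""
        if chrom not in self.per_chrom:
            return UNANNOTATED
        starts, ends, states = self.per_chrom[chrom]
        k = bisect_right(starts, pos) - 1
        if k >= 0 and pos < ends[k]:
            return states[k]
        return UNANNOTATED

    def max_overlap_state(self, chrom: str, start: int, end: int) -> str:
        """State with the largest bp overlap with [start, end).

        Ties break toward the left-most segment; no overlap at all
        reports ``Unannotated``.
        """
        if chrom not in self.per_chrom:
            return UNANNOTATED
        starts, ends, states = self.per_chrom[chrom]
        k = max(0, bisect_right(starts, start) - 1)
        overlap_by_state: dict[str, int] = {}
        best_state, best_bp = UNANNOTATED, 0
        while k < len(starts) and starts[k] < end:
            ov = min(end, ends[k]) - max(start, starts[k])
            if ov > 0:
                total = overlap_by_state.get(states[k], 0) + ov
                overlap_by_state[states[k]] = total
                if total > best_bp:
                    best_state, best_bp = states[k], total
            k += 1
        covered = sum(overlap_by_state.values())
        if end - start - covered > best_bp:  # mostly uncovered
            return UNANNOTATED
        return best_state

    def state_bp(self) -> dict[str, int]:
        """Total bp per state."""
        bp = {st: 0 for st in self.state_catalog}
        for starts, ends, states in self.per_chrom.values():
            for s, e, st in zip(starts, ends, states):
                bp[st] += e - s
        return bp

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Segmentation)
            and self.state_catalog == other.state_catalog
            and self.per_chrom == other.per_chrom
        )


@dataclass
class StateEnrichment:
    """Per-state peak frequencies of a sample vs a control background.

    log2fc = log2((freq_sample + eps) / (freq_control + eps)) with the
    pseudocount eps recorded; frequencies sum to 1 over the catalog plus
    Unannotated.
    """

    states: list[str]
    count_sample: dict[str, int]
    count_control: dict[str, int]
    freq_sample: dict[str, float]
    freq_control: dict[str, float]
    log2fc: dict[str, float]
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.states,
                "count_sample": [self.count_sample[s] for s in self.states],
                "count_control": [self.count_control[s] for s in self.states],
                "freq_sample": [self.freq_sample[s] for s in self.states],
                "freq_control": [self.freq_control[s] for s in self.states],
                "log2fc": [self.log2fc[s] for s in self.states],
            }
        )


@dataclass
class PileupMatrix:
    """Tag counts per (row, offset) around a set of anchors.

    Offsets run from -half_width to half_width - 1; rows are expression
    bins (highest expression first) or a single composite row.
    """

    offsets: np.ndarray
    counts: np.ndarray  # shape (n_rows, len(offsets)), non-negative ints
    row_labels: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=self.row_labels or list(range(self.counts.shape[0])),
            columns=self.offsets,
        )


def state_frequencies(
    peaks: PeakSet, seg: Segmentation, assign: str = "midpoint"
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-state peak counts and fractions.

    assign="midpoint" (default) takes the state at the peak midpoint;
    assign="max_overlap" takes the state with the largest bp overlap.
    Returns (counts, fractions) keyed by every catalog state plus
    ``Unannotated``; fractions sum to 1.
    """
    if len(peaks) == 0:
        raise ValueError("state_frequencies: empty peak set")
    if assign not in ("midpoint", "max_overlap"):
        raise ValueError(f"unknown assignment rule {assign!r}")
    states = list(seg.state_catalog) + [UNANNOTATED]
    counts = {st: 0 for st in states}
    for iv in peaks:
        if assign == "midpoint":
            st = seg.state_at(iv.chrom, midpoint(iv))
        else:
            st = seg.max_overlap_state(iv.chrom, iv.start, iv.end)
        counts[st] += 1
    total = len(peaks)
    freqs = {st: counts[st] / total for st in states}
    return counts, freqs


def state_enrichment(
    sample: PeakSet,
    control: PeakSet,
    seg: Segmentation,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> StateEnrichment:
    """log2 fold-change of per-state peak frequencies, sample over control.

    The control is typically an IgG peak set defining the background
    occupancy of each state; it must be non-empty.
    """
    if len(control) == 0:
        raise ValueError("state_enrichment: a non-empty control (background) is required")
    cs, fs = state_frequencies(sample, seg)
    cc, fc = state_frequencies(control, seg)
    states = list(seg.state_catalog) + [UNANNOTATED]
    log2fc = {
        st: math.log2((fs[st] + pseudocount) / (fc[st] + pseudocount)) for st in states
    }
    return StateEnrichment(
        states=states,
        count_sample=cs,
        count_control=cc,
        freq_sample=fs,
        freq_control=fc,
        log2fc=log2fc,
        pseudocount=pseudocount,
    )


def filter_motifs_near_peaks(motifs: PeakSet, peaks: PeakSet, window: int = 100) -> PeakSet:
    """Motif occurrences within ``window`` bp of (or overlapping) a peak.

    The gap between half-open intervals is the number of uncovered bases
    separating them (0 when they overlap or are bookended); a motif is
    retained when its gap to the nearest peak is <= window.  Retained
    motifs carry that nearest-peak distance in their score field.
    """
    if len(peaks) == 0 or len(motifs) == 0:
        return PeakSet(label=motifs.label or "motifs", intervals=[], genome=motifs.genome)
    # expand by window + 1 so a gap of exactly `window` bp still yields an
    # overlap candidate (half-open intervals); the exact gap filter below
    # enforces the <= window threshold
    expanded = PeakSet(
        label="_expanded",
        intervals=[
            replace(iv, start=max(0, iv.start - window - 1), end=iv.end + window + 1)
            for iv in motifs
        ],
    )
    pairs = overlap_pairs(expanded, peaks)
    best: dict[int, int] = {}
    for i, j in pairs:
        m, p = motifs[i], peaks[j]
        gap = max(0, max(m.start, p.start) - min(m.end, p.end))
        if i not in best or gap < best[i]:
            best[i] = gap
    retained = [
        replace(motifs[k], score=float(best[k])) for k in sorted(best) if best[k] <= window
    ]
    return PeakSet(label=motifs.label, intervals=retained, genome=motifs.genome)


def _anchor_pileup(
    tags: PeakSet,
    anchors: list[tuple[str, int, str, int]],
    half_width: int,
    n_rows: int,
    row_labels: list[str],
) -> PileupMatrix:
    """Pile tag 5' positions around anchors (chrom, pos, strand, row).

    Each tag is assigned to its nearest anchor (ties to the left-most);
    it is counted when the strand-oriented offset lies in
    [-half_width, half_width - 1].
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    offsets = np.arange(-half_width, half_width)
    counts = np.zeros((n_rows, 2 * half_width), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, str, int]]] = {}
    for chrom, pos, strand, row in anchors:
        by_chrom.setdefault(chrom, []).append((pos, strand, row))
    tag_pos: dict[str, list[int]] = {}
    for tag in tags:
        tag_pos.setdefault(tag.chrom, []).append(tag.start)  # 1-bp 5' ends
    for chrom, alist in by_chrom.items():
        if chrom not in tag_pos:
            continue
        alist.sort()
        apos = np.array([a[0] for a in alist])
        aflip = np.array([a[1] == "-" for a in alist])
        arow = np.array([a[2] for a in alist])
        pos = np.array(tag_pos[chrom])
        k = np.searchsorted(apos, pos, side="right")
        left = np.clip(k - 1, 0, len(apos) - 1)
        right = np.clip(k, 0, len(apos) - 1)
        d_left = np.abs(pos - apos[left])
        d_right = np.abs(pos - apos[right])
        # nearest anchor; ties go to the left-most anchor
        use_left = (d_left <= d_right) | (apos[left] == apos[right])
        nearest = np.where(use_left, left, right)
        raw = pos - apos[nearest]
        off = np.where(aflip[nearest], -raw, raw)
        keep = (off >= -half_width) & (off <= half_width - 1)
        np.add.at(counts, (arow[nearest[keep]], off[keep] + half_width), 1)
    return PileupMatrix(offsets=offsets, counts=counts, row_labels=row_labels)


def motif_composite_profile(tags: PeakSet, anchors: PeakSet, half_width: int) -> PileupMatrix:
    """Single composite profile of tag 5' ends around anchor midpoints.

    Anchors on the minus strand flip the offset sign so that positive
    offsets always point downstream of the anchor.
    """
    if len(anchors) == 0:
        raise ValueError("motif_composite_profile: no anchors")
    anchor_list = [(iv.chrom, midpoint(iv), iv.strand, 0) for iv in anchors]
    return _anchor_pileup(tags, anchor_list, half_width, 1, ["composite"])


def tss_pileup(
    tags: PeakSet,
    genes: list[GeneAnnotation],
    expression: dict[str, float],
    n_bins: int = 4,
    half_width: int = 2000,
) -> PileupMatrix:
    """Tag pileup around TSSs, one row per expression bin.

    Genes are ranked by expression (highest first, ties broken by
    gene_id) and split into ``n_bins`` equal-count bins; row 0 holds the
    most highly expressed genes.  Offsets are strand-oriented: positive
    means downstream of the TSS.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    missing = [g.gene_id for g in genes if g.gene_id not in expression]
    if missing:
        raise ValueError(f"missing expression values for genes: {', '.join(sorted(missing))}")
    order = sorted(genes, key=lambda g: (-expression[g.gene_id], g.gene_id))
    bins = np.array_split(np.arange(len(order)), n_bins)
    row_of: dict[str, int] = {}
    for row, idxs in enumerate(bins):
        for k in idxs:
            row_of[order[k].gene_id] = row
    anchors = [(g.chrom, g.tss, g.strand, row_of[g.gene_id]) for g in genes]
    labels = [f"expr_bin_{r + 1}" for r in range(n_bins)]
    return _anchor_pileup(tags, anchors, half_width, n_bins, labels)
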