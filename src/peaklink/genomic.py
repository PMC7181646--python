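"""Coordinate conventions, interval algebra and BED/TSV readers and writers.

All coordinates are 0-based, half-open ``[start, end)`` (BED-native).
The midpoint of an interval is ``floor((start + end) / 2)``; an
even-width window therefore places ``width // 2`` bp to the left of the
midpoint.  These two conventions fix every downstream offset
computation.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


class GenomeTable:
    """Chromosome name -> length (bp) lookup.

    Names must be unique and lengths positive.
    """

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for chrom, length in items:
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        self._sizes: dict[str, int] = {c: int(n) for c, n in items}

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeTable) and self._sizes == other._sizes

    def items(self) -> Iterable[tuple[str, int]]:
        return self._sizes.items()

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self._sizes.items():
                fh.write(f"{chrom}\t{length}\n")

    def __repr__(self) -> str:
        return f"GenomeTable({len(self)} chromosomes, {self.total_bp} bp)"


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a two-column chrom.sizes TSV."""
    items: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                items.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad chromosome length {fields[1]!r}") from exc
    return GenomeTable(items)


@dataclass(slots=True)
class GenomicInterval:
    """A labeled, strand-aware half-open interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """An ordered collection of intervals for one factor/antibody.

    ``provenance`` records replicate identifiers that contributed to a
    consensus set.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    genome: GenomeTable | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("PeakSet label must be non-empty")
        if self.genome is not None:
            self.validate()

    def validate(self) -> None:
        if self.genome is None:
            return
        for iv in self.intervals:
            if iv.chrom not in self.genome:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > self.genome[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:[{iv.start},{iv.end}) extends past "
                    f"chromosome end {self.genome[iv.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def is_sorted(self) -> bool:
        keys = [iv.sort_key() for iv in self.intervals]
        return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))

    def sorted(self) -> "PeakSet":
        return PeakSet(
            label=self.label,
            intervals=sorted(self.intervals, key=GenomicInterval.sort_key),
            provenance=list(self.provenance),
            genome=self.genome,
        )


@dataclass(slots=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site (0-based position)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS")


# ---------------------------------------------------------------------------
# Readers / writers


_SKIP_PREFIXES = ("#", "track", "browser")


def _parse_bed_line(
    line: str, lineno: int, path: str, genome: GenomeTable | None
) -> GenomicInterval:
    fields = line.split("\t")
    if not 3 <= len(fields) <= 6:
        raise ValueError(f"{path}:{lineno}: expected 3-6 tab-separated columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if not (0 <= start < end):
        raise ValueError(f"{path}:{lineno}: invalid interval [{start},{end}) (start >= end)")
    name = fields[3] if len(fields) > 3 else ""
    score: float | None = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in VALID_STRANDS:
        raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
    if genome is not None:
        if chrom not in genome:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end > genome[chrom]:
            raise ValueError(
                f"{path}:{lineno}: interval {chrom}:[{start},{end}) outside chromosome "
                f"(length {genome[chrom]})"
            )
    return GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)


def read_bed(path: str | Path, genome: GenomeTable | None = None, kind: str = "peaks"):
    """Read a BED file as a :class:`PeakSet` or (kind="segmentation") a
    :class:`~peaklink.annotation.Segmentation`.

    Accepts BED3-BED6; ``track``/``browser``/``#`` lines are skipped.
    Intervals are validated against ``genome`` when given and returned
    sorted by (chrom, start, end).  For segmentations column 4 carries
    the chromatin-state label.
    """
    if kind not in ("peaks", "motifs", "tags", "segmentation"):
        raise ValueError(f"unknown BED kind {kind!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            intervals.append(_parse_bed_line(line, lineno, str(path), genome))
    intervals.sort(key=GenomicInterval.sort_key)
    if kind == "segmentation":
        from peaklink.annotation import Segmentation

        for iv in intervals:
            if not iv.name:
                raise ValueError(f"{path}: segmentation interval {iv.chrom}:{iv.start} lacks a state label")
        return Segmentation.from_intervals(intervals, genome=genome)
    return PeakSet(label=path.stem, intervals=intervals, genome=genome)


def write_bed(collection, path: str | Path) -> None:
    """Write a PeakSet or Segmentation as BED (header-free).

    Round-trips with :func:`read_bed`: intervals with default
    strand/name/score emit as BED3, otherwise BED6 (or BED4 for
    segmentations).
    """
    from peaklink.annotation import Segmentation

    if isinstance(collection, Segmentation):
        rows = [
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n" for iv in collection.intervals()
        ]
    else:
        rows = []
        for iv in collection:
            if iv.name == "" and iv.strand == "." and iv.score is None:
                rows.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if iv.score is None else f"{iv.score:g}"
                rows.append(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
    with open(path, "w") as fh:
        fh.writelines(rows)


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from a TSV (gene_id, chrom, strand, tss) or BED6.

    A header line ``gene_id<TAB>chrom<TAB>strand<TAB>tss`` marks the TSV
    form.  In the BED6 form the TSS is ``start`` for + strand genes and
    ``end - 1`` for - strand genes, with the name column as gene id.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()

    def _add(gene: GeneAnnotation, lineno: int) -> None:
        if gene.gene_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        genes.append(gene)

    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    start_at = 0
    header_tsv = lines and lines[0].split("\t")[:4] == ["gene_id", "chrom", "strand", "tss"]
    if header_tsv:
        start_at = 1
    for lineno, line in enumerate(lines[start_at:], start_at + 1):
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        fields = line.split("\t")
        if header_tsv or len(fields) == 4:
            gid, chrom, strand, tss = fields[0], fields[1], fields[2], fields[3]
            _add(GeneAnnotation(gid, chrom, strand, int(tss)), lineno)
        elif len(fields) == 6:
            chrom, start, end, gid, _score, strand = fields
            tss = int(start) if strand == "+" else int(end) - 1
            _add(GeneAnnotation(gid, chrom, strand, tss), lineno)
        else:
            raise ValueError(f"{path}:{lineno}: expected 4-column TSV or BED6, got {len(fields)} columns")
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def midpoint(iv: GenomicInterval) -> int:
    """Midpoint of an interval: ``floor((start + end) / 2)``."""
    return (iv.start + iv.end) // 2


def expand_to_window(
    iv: GenomicInterval, width: int = 100, genome: GenomeTable | None = None
) -> GenomicInterval:
    """Fixed-width window centered on the interval midpoint.

    Returns ``[m - width//2, m - width//2 + width)`` clipped to the
    chromosome; clipped windows are shortened, not shifted, so the
    midpoint stays where the peak was.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    m = midpoint(iv)
    start = m - width // 2
    end = start + width
    start = max(0, start)
    if genome is not None:
        end = min(end, genome[iv.chrom])
    return replace(iv, start=start, end=end)


def overlap_pairs(A: PeakSet, B: PeakSet) -> list[tuple[int, int]]:
    """All index pairs (i, j) where A[i] and B[j] share >= 1 bp.

    Sweep-line over start-sorted intervals with end-keyed heaps of
    active intervals; O((n + k) log n) for k overlaps.  Indices refer to
    the original ordering of each set.  Unsorted inputs are handled by
    an internal sort (logged).
    """
    for s in (A, B):
        if not s.is_sorted():
            logger.warning("PeakSet %r not sorted; sorting internally for overlap_pairs", s.label)

    by_chrom: dict[str, tuple[list, list]] = {}
    for which, peaks in ((0, A), (1, B)):
        for idx, iv in enumerate(peaks):
            by_chrom.setdefault(iv.chrom, ([], []))[which].append((iv.start, iv.end, idx))

    pairs: list[tuple[int, int]] = []
    for chrom in by_chrom:
        a_list, b_list = by_chrom[chrom]
        a_list.sort()
        b_list.sort()
        events = []  # (start, end, which, idx) merged by start
        i = j = 0
        active_a: list[tuple[int, int]] = []  # heap of (end, idx)
        active_b: list[tuple[int, int]] = []
        while i < len(a_list) or j < len(b_list):
            take_a = j >= len(b_list) or (i < len(a_list) and a_list[i][0] <= b_list[j][0])
            if take_a:
                start, end, idx = a_list[i]
                i += 1
                while active_b and active_b[0][0] <= start:
                    heapq.heappop(active_b)
                for b_end, b_idx in active_b:
                    pairs.append((idx, b_idx))
                heapq.heappush(active_a, (end, idx))
            else:
                start, end, idx = b_list[j]
                j += 1
                while active_a and active_a[0][0] <= start:
                    heapq.heappop(active_a)
                for a_end, a_idx in active_a:
                    pairs.append((a_idx, idx))
                heapq.heappush(active_b, (end, idx))
    pairs.sort()
    return pairs


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merge all overlapping or bookended intervals."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def consensus_merge(replicates: Sequence[PeakSet], min_support: int) -> PeakSet:
    """Interval-level consensus across replicate peak sets.

    A genomic base is retained when it is covered by peaks from at least
    ``min_support`` distinct replicates; maximal runs of retained bases
    become the consensus intervals.  This is an interval-level stand-in
    for re-calling peaks on merged replicate alignments.
    """
    if not replicates:
        raise ValueError("consensus_merge requires at least one replicate")
    if not 1 <= min_support <= len(replicates):
        raise ValueError(
            f"min_support must be in [1, {len(replicates)}], got {min_support}"
        )
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicates:
        # merge within a replicate first so support counts distinct replicates
        for iv in merge_intervals(rep.intervals):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))

    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        support = 0
        run_start: int | None = None
        k = 0
        while k < len(evs):
            pos = evs[k][0]
            while k < len(evs) and evs[k][0] == pos:
                support += evs[k][1]
                k += 1
            if support >= min_support and run_start is None:
                run_start = pos
            elif support < min_support and run_start is not None:
                out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    label = replicates[0].label
    return PeakSet(
        label=label,
        intervals=out,
        provenance=[r.label for r in replicates],
        genome=replicates[0].genome,
    )
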