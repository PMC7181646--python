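"""Seeded generator of synthetic pipeline inputs with planted truth.

Emulates the inputs of a two-factor ChIP-exo / RNA-seq integration
study on a scaled-down genome: two factor peak sets with a planted
co-occupancy fraction and planted midpoint-offset distribution, a
uniform IgG control, a chromatin-state segmentation with planted
enhancer/promoter placement enrichment, TSS-concentrated 5' tags scaled
by expression, motif occurrences, and differential-expression tables
with a planted number of enhancer-linked DE genes per condition.  Every
planted parameter is recoverable by the analysis modules, which closes
the loop for end-to-end validation.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` child streams (genome, peaks, expression,
tags, de), so each stage is individually reproducible.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from peaklink.genomic import (
    GenomeTable,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    write_bed,
    write_gene_table,
)
from peaklink.annotation import Segmentation
from peaklink.quantstats import DE_COLUMNS

# SeedSequence spawn-key positions for the per-stage streams
_STREAMS = {"genome": 0, "peaks": 1, "expression": 2, "tags": 3, "de": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults plant the quantities the analysis is designed to recover:
    a 0.22 co-occupancy fraction, a 94-bp median midpoint offset, a 4x
    enhancer / 2x promoter placement multiplier over a uniform IgG
    background (log2 enrichments of exactly 2.0 and 1.0, since the
    weighted state proportions sum to 1), and 541 / 49 enhancer-linked
    DE genes in the two conditions.
    """

    seed: int = 0
    chroms: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 20_000_000),
            ("chr2", 15_000_000),
            ("chr3", 10_000_000),
            ("chr4", 5_000_000),
        ]
    )
    n_genes: int = 4_000
    state_catalog: list[str] = field(
        default_factory=lambda: [
            "Promoter",
            "Enhancer",
            "Transcribed",
            "Heterochromatin",
            "Repressed",
        ]
    )
    state_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "Promoter": 0.05,
            "Enhancer": 0.12,
            "Transcribed": 0.23,
            "Heterochromatin": 0.40,
            "Repressed": 0.20,
        }
    )
    # placement multipliers for factor peaks; IgG is always uniform.
    # sum_s proportion_s * weight_s == 1, so log2 enrichment vs IgG is
    # exactly log2(weight).
    state_weights: dict[str, float] = field(
        default_factory=lambda: {
            "Promoter": 2.0,
            "Enhancer": 4.0,
            "Transcribed": 0.6,
            "Heterochromatin": 0.5,
            "Repressed": 0.41,
        }
    )
    mean_segment_length: int = 2_000
    n_peaks_A: int = 5_000
    n_peaks_B: int = 5_000
    n_peaks_igg: int = 5_000
    overlap_fraction: float = 0.22
    offset_dist: str = "discrete_laplace"  # or "constant"
    offset_median: int = 94
    offset_scale: float = 3.0
    window: int = 100
    peak_width_range: tuple[int, int] = (20, 60)
    motif_density_per_mb: float = 10.0
    motif_width: int = 12
    n_tags: int = 100_000
    tag_background_frac: float = 0.2
    tag_spread: float = 50.0
    expression_effect: float = 2.0
    de_truth: tuple[int, int] = (541, 49)
    de_effect: float = 2.0
    de_noise: float = 0.5
    de_background_rate: float = 0.1

    def __post_init__(self) -> None:
        total = sum(self.state_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state proportions must sum to 1, got {total}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        for name in ("n_genes", "n_peaks_A", "n_peaks_B", "n_peaks_igg", "n_tags"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.state_proportions) != set(self.state_catalog):
            raise ValueError("state_proportions keys must match state_catalog")
        if set(self.state_weights) != set(self.state_catalog):
            raise ValueError("state_weights keys must match state_catalog")


@dataclass
class SyntheticTruth:
    """The planted parameters and their realizations.

    ``matched_pairs`` holds (index in sorted A, index in sorted B) for
    each planted partner pair; ``offsets`` the signed midpoint offsets
    B - A of those pairs.
    """

    realized_pi: float = 0.0
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)
    offsets: list[int] = field(default_factory=list)
    state_counts_A: dict[str, int] = field(default_factory=dict)
    state_counts_B: dict[str, int] = field(default_factory=dict)
    planted_log2_enrichment: dict[str, float] = field(default_factory=dict)
    n_linked_available: int = 0
    de_linked_cond1: list[str] = field(default_factory=list)
    de_linked_cond2: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Stage 1: genome, genes, segmentation, motifs


def simulate_genome_annotation(
    cfg: SyntheticConfig,
) -> tuple[GenomeTable, list[GeneAnnotation], Segmentation, PeakSet]:
    """Genome table, gene TSSs, chromatin-state segmentation and motifs.

    The segmentation partitions each chromosome; per-state bp match the
    configured proportions up to segment-length rounding (a quota
    scheme draws the next state proportionally to its remaining bp
    budget).  Gene TSSs are spread with a minimum 2 kb separation.
    """
    genome = GenomeTable(cfg.chroms)
    rng = _rng(cfg.seed, "genome")

    # segmentation: quota sampling keeps realized proportions within
    # rounding of the configured ones
    seg_intervals: list[GenomicInterval] = []
    for chrom, length in cfg.chroms:
        remaining = {
            st: int(round(cfg.state_proportions[st] * length)) for st in cfg.state_catalog
        }
        # rounding may leave a few bp unassigned; give them to the largest state
        deficit = length - sum(remaining.values())
        remaining[max(remaining, key=remaining.get)] += deficit
        pos = 0
        states = [st for st in cfg.state_catalog]
        while pos < length:
            budgets = np.array([remaining[st] for st in states], dtype=float)
            probs = budgets / budgets.sum()
            st = states[rng.choice(len(states), p=probs)]
            seg_len = int(min(rng.geometric(1.0 / cfg.mean_segment_length), remaining[st]))
            seg_len = max(1, min(seg_len, length - pos))
            seg_intervals.append(GenomicInterval(chrom, pos, pos + seg_len, name=st))
            remaining[st] -= seg_len
            pos += seg_len
    segmentation = Segmentation.from_intervals(
        seg_intervals, state_catalog=cfg.state_catalog, genome=genome
    )

    # genes: per-chrom counts proportional to length; min 2 kb TSS gap
    total_bp = genome.total_bp
    genes: list[GeneAnnotation] = []
    min_gap = 2_000
    counts = _allocate(cfg.n_genes, [l for _, l in cfg.chroms])
    gid = 0
    for (chrom, length), n_c in zip(cfg.chroms, counts):
        if n_c == 0:
            continue
        usable = length - (n_c - 1) * min_gap - 2 * min_gap
        if usable <= 0:
            raise ValueError(f"chromosome {chrom} too small for {n_c} genes")
        raw = np.sort(rng.integers(0, usable, size=n_c))
        tss = raw + min_gap + np.arange(n_c) * min_gap
        strands = rng.choice(["+", "-"], size=n_c)
        for p, s in zip(tss, strands):
            gid += 1
            genes.append(GeneAnnotation(f"gene_{gid:05d}", chrom, str(s), int(p)))

    # motif occurrences: uniform over the genome
    n_motifs = int(round(cfg.motif_density_per_mb * total_bp / 1e6))
    motif_ivs: list[GenomicInterval] = []
    chrom_probs = np.array([l for _, l in cfg.chroms], dtype=float) / total_bp
    chosen = rng.choice(len(cfg.chroms), size=n_motifs, p=chrom_probs)
    for k, ci in enumerate(chosen):
        chrom, length = cfg.chroms[ci]
        start = int(rng.integers(0, length - cfg.motif_width))
        strand = "+" if rng.random() < 0.5 else "-"
        motif_ivs.append(
            GenomicInterval(chrom, start, start + cfg.motif_width, strand=strand, name=f"motif_{k + 1:05d}")
        )
    motif_ivs.sort(key=GenomicInterval.sort_key)
    motifs = PeakSet(label="motifs", intervals=motif_ivs, genome=genome)
    return genome, genes, segmentation, motifs


def _allocate(n: int, lengths: list[int]) -> list[int]:
    """Split n items across chromosomes proportionally to length."""
    total = sum(lengths)
    counts = [int(n * l / total) for l in lengths]
    k = 0
    while sum(counts) < n:
        counts[k % len(counts)] += 1
        k += 1
    return counts


# ---------------------------------------------------------------------------
# Stage 2: peak sets


class _SpacedSampler:
    """Rejection sampler for midpoints with a minimum pairwise distance."""

    def __init__(self, min_dist: int):
        self.min_dist = min_dist
        self.accepted: dict[str, list[int]] = {}

    def ok(self, chrom: str, pos: int) -> bool:
        lst = self.accepted.get(chrom, [])
        k = bisect_left(lst, pos)
        if k > 0 and pos - lst[k - 1] < self.min_dist:
            return False
        if k < len(lst) and lst[k] - pos < self.min_dist:
            return False
        return True

    def add(self, chrom: str, pos: int) -> None:
        insort(self.accepted.setdefault(chrom, []), pos)


def _draw_offsets(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Signed midpoint offsets for matched partner peaks.

    "constant": every offset is +-offset_median.  "discrete_laplace":
    magnitudes follow a discrete Laplace centred on offset_median
    (scale offset_scale), truncated to [0, window - 1] by resampling so
    every planted partner stays recoverable through window overlap; the
    magnitude median is exactly offset_median.  Signs are equiprobable.
    """
    signs = rng.choice([-1, 1], size=n)
    if cfg.offset_dist == "constant":
        return signs * cfg.offset_median
    if cfg.offset_dist != "discrete_laplace":
        raise ValueError(f"unknown offset_dist {cfg.offset_dist!r}")
    mags = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(
            rng.laplace(cfg.offset_median, cfg.offset_scale, size=2 * (n - filled))
        ).astype(np.int64)
        good = draw[(draw >= 0) & (draw <= cfg.window - 1)]
        take = min(len(good), n - filled)
        mags[filled : filled + take] = good[:take]
        filled += take
    return signs * mags


def simulate_peaksets(
    cfg: SyntheticConfig,
    annotation: tuple[GenomeTable, list[GeneAnnotation], Segmentation, PeakSet],
) -> tuple[PeakSet, PeakSet, PeakSet, SyntheticTruth]:
    """Factor A and B peak sets with planted co-occupancy, plus uniform IgG.

    floor(overlap_fraction * n_A) A-peaks receive a B partner at a
    signed offset drawn from the configured offset distribution; all
    other peak midpoints (A and unmatched B) keep a minimum separation
    of 3 * window so no accidental window overlaps dilute the planted
    fraction.  A/B midpoints land in chromatin states proportionally to
    state_weights; IgG is uniform.
    """
    genome, _genes, segmentation, _motifs = annotation
    rng = _rng(cfg.seed, "peaks")
    margin = 3 * cfg.window
    sampler = _SpacedSampler(min_dist=3 * cfg.window)

    # per-state segment tables; state counts are drawn as an exact
    # multinomial over weighted proportions, then positions are sampled
    # within the chosen state (conflicts resample within the same
    # state) so min-separation never biases the state frequencies
    chrom_len = {c: l for c, l in cfg.chroms}
    per_state: dict[str, tuple[list[str], np.ndarray, np.ndarray, np.ndarray]] = {}
    for st in cfg.state_catalog:
        chroms_l: list[str] = []
        starts_l: list[int] = []
        lens_l: list[int] = []
        for chrom in segmentation.per_chrom:
            c_starts, c_ends, c_states = segmentation.per_chrom[chrom]
            for s, e, s_st in zip(c_starts, c_ends, c_states):
                if s_st == st:
                    chroms_l.append(chrom)
                    starts_l.append(s)
                    lens_l.append(e - s)
        lens_a = np.array(lens_l, dtype=float)
        cum = np.cumsum(lens_a / lens_a.sum()) if len(lens_l) else np.array([])
        per_state[st] = (chroms_l, np.array(starts_l), np.array(lens_l), cum)

    state_probs = np.array(
        [cfg.state_proportions[st] * cfg.state_weights[st] for st in cfg.state_catalog]
    )
    state_probs = state_probs / state_probs.sum()

    def draw_in_state(st: str) -> tuple[str, int]:
        chroms_l, starts_a, lens_a, cum = per_state[st]
        while True:
            k = int(np.searchsorted(cum, rng.random(), side="right"))
            k = min(k, len(lens_a) - 1)
            pos = int(starts_a[k] + rng.integers(0, lens_a[k]))
            chrom = chroms_l[k]
            if margin <= pos <= chrom_len[chrom] - margin and sampler.ok(chrom, pos):
                sampler.add(chrom, pos)
                return chrom, pos

    def draw_weighted_batch(n: int) -> list[tuple[str, int, str]]:
        counts = rng.multinomial(n, state_probs)
        sites = []
        for st, c in zip(cfg.state_catalog, counts):
            for _ in range(c):
                chrom, pos = draw_in_state(st)
                sites.append((chrom, pos, st))
        # shuffle so peak identity is not ordered by state
        order = rng.permutation(len(sites))
        return [sites[k] for k in order]

    def make_interval(chrom: str, mid: int, name: str) -> GenomicInterval:
        width = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
        start = mid - width // 2
        return GenomicInterval(chrom, start, start + width, name=name)

    a_sites = draw_weighted_batch(cfg.n_peaks_A)
    a_mids: list[tuple[str, int]] = [(c, p) for c, p, _ in a_sites]
    state_counts_A: dict[str, int] = {st: 0 for st in cfg.state_catalog}
    for _, _, st in a_sites:
        state_counts_A[st] += 1

    n_matched = int(np.floor(cfg.overlap_fraction * cfg.n_peaks_A))
    if cfg.n_peaks_B < n_matched:
        raise ValueError("n_peaks_B smaller than the number of planted partners")
    matched_a = rng.choice(cfg.n_peaks_A, size=n_matched, replace=False)
    offsets = _draw_offsets(cfg, rng, n_matched)

    b_mids: list[tuple[str, int]] = []
    b_partner_of: list[int | None] = []
    for a_idx, off in zip(matched_a, offsets):
        chrom, a_pos = a_mids[a_idx]
        b_mids.append((chrom, int(a_pos + off)))
        b_partner_of.append(int(a_idx))
    state_counts_B: dict[str, int] = {st: 0 for st in cfg.state_catalog}
    for chrom, pos in b_mids:
        state_counts_B[segmentation.state_at(chrom, pos)] = (
            state_counts_B.get(segmentation.state_at(chrom, pos), 0) + 1
        )
    for chrom, pos, st in draw_weighted_batch(cfg.n_peaks_B - n_matched):
        b_mids.append((chrom, pos))
        b_partner_of.append(None)
        state_counts_B[st] += 1

    a_ivs = [make_interval(c, m, f"peakA_{i + 1:05d}") for i, (c, m) in enumerate(a_mids)]
    b_ivs = [make_interval(c, m, f"peakB_{i + 1:05d}") for i, (c, m) in enumerate(b_mids)]

    # IgG: uniform over the genome, no spacing constraint
    total_bp = genome.total_bp
    chrom_probs = np.array([l for _, l in cfg.chroms], dtype=float) / total_bp
    igg_ivs: list[GenomicInterval] = []
    chosen = rng.choice(len(cfg.chroms), size=cfg.n_peaks_igg, p=chrom_probs)
    for i, ci in enumerate(chosen):
        chrom, length = cfg.chroms[ci]
        mid = int(rng.integers(margin, length - margin))
        igg_ivs.append(make_interval(chrom, mid, f"igg_{i + 1:05d}"))

    # sort sets and remap planted pair indices to sorted order
    a_order = sorted(range(len(a_ivs)), key=lambda k: a_ivs[k].sort_key())
    b_order = sorted(range(len(b_ivs)), key=lambda k: b_ivs[k].sort_key())
    a_rank = {orig: k for k, orig in enumerate(a_order)}
    b_rank = {orig: k for k, orig in enumerate(b_order)}
    matched_pairs = [
        (a_rank[b_partner_of[bo]], b_rank[bo])
        for bo in range(len(b_ivs))
        if b_partner_of[bo] is not None
    ]
    A = PeakSet(label="factor_A", intervals=[a_ivs[k] for k in a_order], genome=genome)
    B = PeakSet(label="factor_B", intervals=[b_ivs[k] for k in b_order], genome=genome)
    igg_ivs.sort(key=GenomicInterval.sort_key)
    IgG = PeakSet(label="IgG", intervals=igg_ivs, genome=genome)

    truth = SyntheticTruth(
        realized_pi=n_matched / cfg.n_peaks_A if cfg.n_peaks_A else 0.0,
        matched_pairs=sorted(matched_pairs),
        offsets=[int(o) for o in offsets],
        state_counts_A=state_counts_A,
        state_counts_B=state_counts_B,
        planted_log2_enrichment={
            st: float(np.log2(cfg.state_weights[st])) for st in cfg.state_catalog
        },
    )
    return A, B, IgG, truth


# ---------------------------------------------------------------------------
# Stage 3: expression and tags


def simulate_expression(cfg: SyntheticConfig, genes: list[GeneAnnotation]) -> dict[str, float]:
    """Log-normal steady-state expression values (FPKM-like scale)."""
    rng = _rng(cfg.seed, "expression")
    values = rng.lognormal(mean=2.0, sigma=1.5, size=len(genes))
    return {g.gene_id: float(v) for g, v in zip(genes, values)}


def simulate_tags(
    cfg: SyntheticConfig,
    annotation: tuple[GenomeTable, list[GeneAnnotation], Segmentation, PeakSet],
    expression: dict[str, float],
) -> PeakSet:
    """5' tag positions concentrated at TSSs, scaled by expression rank.

    Per-gene tag counts are multinomial with weights
    exp(expression_effect * normalized expression rank); positions are
    Laplace-spread around the TSS, plus a uniform background fraction.
    """
    genome, genes, _seg, _motifs = annotation
    rng = _rng(cfg.seed, "tags")
    missing = [g.gene_id for g in genes if g.gene_id not in expression]
    if missing:
        raise ValueError(f"expression missing for genes: {', '.join(missing[:5])}")
    intervals: list[GenomicInterval] = []
    chrom_len = {c: l for c, l in cfg.chroms}
    n_signal = int(round(cfg.n_tags * (1 - cfg.tag_background_frac))) if genes else 0
    if genes and n_signal:
        order = sorted(genes, key=lambda g: (expression[g.gene_id], g.gene_id))
        denom = max(1, len(order) - 1)
        weights = np.exp(cfg.expression_effect * np.arange(len(order)) / denom)
        counts = rng.multinomial(n_signal, weights / weights.sum())
        for g, c in zip(order, counts):
            if c == 0:
                continue
            pos = g.tss + np.rint(rng.laplace(0.0, cfg.tag_spread, size=c)).astype(int)
            pos = np.clip(pos, 0, chrom_len[g.chrom] - 1)
            strands = rng.choice(["+", "-"], size=c)
            intervals.extend(
                GenomicInterval(g.chrom, int(p), int(p) + 1, strand=str(s))
                for p, s in zip(pos, strands)
            )
    n_bg = cfg.n_tags - len(intervals)
    total_bp = genome.total_bp
    chrom_probs = np.array([l for _, l in cfg.chroms], dtype=float) / total_bp
    chosen = rng.choice(len(cfg.chroms), size=n_bg, p=chrom_probs)
    for ci in chosen:
        chrom, length = cfg.chroms[ci]
        p = int(rng.integers(0, length))
        strand = "+" if rng.random() < 0.5 else "-"
        intervals.append(GenomicInterval(chrom, p, p + 1, strand=strand))
    intervals.sort(key=GenomicInterval.sort_key)
    return PeakSet(label="tags", intervals=intervals, genome=genome)


# ---------------------------------------------------------------------------
# Stage 4: differential-expression tables


def simulate_de_table(
    cfg: SyntheticConfig,
    annotation: tuple[GenomeTable, list[GeneAnnotation], Segmentation, PeakSet],
    links,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Two DE tables with planted enhancer-linked DE gene counts.

    Exactly de_truth[0] linked genes pass the padj < 0.05 filter in
    condition 1 and de_truth[1] in condition 2 (the condition-2 set is
    a subset of condition 1, emulating loss of regulation after
    knockdown); unlinked genes are differentially expressed at a
    background rate, which leaves the planted intersections untouched.
    """
    _genome, genes, _seg, _motifs = annotation
    rng = _rng(cfg.seed, "de")
    linked = sorted({l.gene_id for l in links})
    n1, n2 = cfg.de_truth
    if n1 > len(linked) or n2 > len(linked):
        raise ValueError(
            f"requested {cfg.de_truth} linked DE genes but only {len(linked)} "
            "genes are enhancer-linked"
        )
    chosen1 = set(map(str, rng.choice(linked, size=n1, replace=False))) if n1 else set()
    pool2 = sorted(chosen1) if n2 <= n1 else linked
    chosen2 = set(map(str, rng.choice(pool2, size=n2, replace=False))) if n2 else set()

    linked_set = set(linked)

    def build(chosen: set[str]) -> pd.DataFrame:
        rows = []
        for g in genes:
            gid = g.gene_id
            if gid in chosen:
                de = True
            elif gid in linked_set:
                de = False  # linked but not chosen: must not pass the filter
            else:
                de = rng.random() < cfg.de_background_rate
            if de:
                padj = 10 ** (-rng.uniform(1.5, 6.0))
                mag = max(1.0, cfg.de_effect + rng.normal(0.0, cfg.de_noise))
                log2fc = mag if rng.random() < 0.5 else -mag
            else:
                padj = rng.uniform(0.05, 1.0)
                log2fc = rng.normal(0.0, 0.3)
            pvalue = padj * rng.uniform(0.05, 1.0)
            base_mean = float(rng.lognormal(5.0, 1.5))
            rows.append((gid, float(log2fc), float(pvalue), float(padj), base_mean))
        return pd.DataFrame(rows, columns=DE_COLUMNS)

    de1 = build(chosen1)
    de2 = build(chosen2)
    truth = SyntheticTruth(
        n_linked_available=len(linked),
        de_linked_cond1=sorted(chosen1),
        de_linked_cond2=sorted(chosen2),
    )
    return de1, de2, truth


# ---------------------------------------------------------------------------
# Full bundle


def simulate_bundle(cfg: SyntheticConfig, outdir: str | Path) -> tuple[dict[str, Path], SyntheticTruth]:
    """Generate and write every pipeline input plus the truth record.

    Writes chrom.sizes, genes.tsv, segmentation.bed, motifs.bed,
    peaks_A.bed, peaks_B.bed, peaks_igg.bed, tags.bed, expr.tsv,
    de_cond1.tsv, de_cond2.tsv and truth.json into ``outdir`` and
    returns ({name: path}, truth).  Byte-identical across runs with the
    same config.
    """
    from peaklink.cooccupancy import cooccurring_peaks
    from peaklink.genomic import midpoint as _midpoint
    from peaklink.linking import build_regulatory_domains, link_regions_to_genes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_genome_annotation(cfg)
    genome, genes, segmentation, motifs = annotation
    A, B, IgG, truth = simulate_peaksets(cfg, annotation)
    expression = simulate_expression(cfg, genes)
    tags = simulate_tags(cfg, annotation, expression)

    # enhancer-linked genes, computed exactly as the pipeline will
    cooc = cooccurring_peaks(A, B, window=cfg.window)
    enhancer_regions = PeakSet(
        label="enhancer_regions",
        intervals=[
            iv
            for iv in cooc.common_regions
            if segmentation.state_at(iv.chrom, _midpoint(iv)) == "Enhancer"
        ],
        genome=genome,
    )
    domains = build_regulatory_domains(genes, genome=genome)
    links = link_regions_to_genes(enhancer_regions, domains)
    de1, de2, de_truth = simulate_de_table(cfg, annotation, links)

    truth.n_linked_available = de_truth.n_linked_available
    truth.de_linked_cond1 = de_truth.de_linked_cond1
    truth.de_linked_cond2 = de_truth.de_linked_cond2
    truth.config = {
        "seed": cfg.seed,
        "overlap_fraction": cfg.overlap_fraction,
        "offset_median": cfg.offset_median,
        "offset_dist": cfg.offset_dist,
        "window": cfg.window,
        "de_truth": list(cfg.de_truth),
        "state_weights": dict(cfg.state_weights),
    }

    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "genes": outdir / "genes.tsv",
        "segmentation": outdir / "segmentation.bed",
        "motifs": outdir / "motifs.bed",
        "peaks_A": outdir / "peaks_A.bed",
        "peaks_B": outdir / "peaks_B.bed",
        "peaks_igg": outdir / "peaks_igg.bed",
        "tags": outdir / "tags.bed",
        "expr": outdir / "expr.tsv",
        "de_cond1": outdir / "de_cond1.tsv",
        "de_cond2": outdir / "de_cond2.tsv",
        "truth": outdir / "truth.json",
    }
    genome.to_file(paths["chrom_sizes"])
    write_gene_table(genes, paths["genes"])
    write_bed(segmentation, paths["segmentation"])
    write_bed(motifs, paths["motifs"])
    write_bed(A, paths["peaks_A"])
    write_bed(B, paths["peaks_B"])
    write_bed(IgG, paths["peaks_igg"])
    write_bed(tags, paths["tags"])
    with open(paths["expr"], "w") as fh:
        fh.write("gene_id\texpression\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{expression[g.gene_id]:.6g}\n")
    de1.to_csv(paths["de_cond1"], sep="\t", index=False, float_format="%.6g")
    de2.to_csv(paths["de_cond2"], sep="\t", index=False, float_format="%.6g")
    truth.to_json(paths["truth"])
    return paths, truth
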