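"""GREAT-style regulatory domains and enhancer-to-gene assignment.

Each gene receives a basal regulatory domain (5 kb upstream, 1 kb
downstream of its TSS by default) plus an extension in both directions
up to the nearest neighboring gene's basal domain or 1 Mb from the TSS,
whichever comes first (the "basal plus extension" association rule).
Regions overlapping a gene's extended domain are assigned to that gene;
a region-set binomial test quantifies enrichment of regions in the
union of a gene set's domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln

from peaklink.genomic import (
    GenomeTable,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    merge_intervals,
    midpoint,
    overlap_pairs,
)

BASAL_UP = 5_000
BASAL_DOWN = 1_000
MAX_EXTENSION = 1_000_000


@dataclass(slots=True)
class RegulatoryDomain:
    """Basal and extended regulatory intervals of one gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    basal: tuple[int, int]
    extended: tuple[int, int]

    def __post_init__(self) -> None:
        bs, be = self.basal
        es, ee = self.extended
        if not (es <= bs < be <= ee):
            raise ValueError(
                f"gene {self.gene_id}: basal {self.basal} not contained in extended {self.extended}"
            )


@dataclass(slots=True)
class EnhancerGeneLink:
    """A region assigned to a gene whose extended domain it overlaps.

    distance_to_tss is the strand-oriented signed distance from the
    region midpoint to the TSS (positive = downstream of the gene).
    """

    region: GenomicInterval
    gene_id: str
    distance_to_tss: int


@dataclass
class GeneSetIntersection:
    linked_genes: set[str]
    query_genes: set[str]
    n_overlap: int
    overlap_ids: set[str]


def build_basal_domains(
    genes: list[GeneAnnotation],
    basal_up: int = BASAL_UP,
    basal_down: int = BASAL_DOWN,
    genome: GenomeTable | None = None,
) -> list[tuple[str, tuple[int, int]]]:
    """Per-gene basal domain around the TSS, clipped to the chromosome.

    For a + strand gene with TSS p the basal domain is
    [p - basal_up, p + basal_down); for a - strand gene it is the
    mirror image [p - basal_down + 1, p + basal_up + 1), so that in
    both cases basal_up bases lie upstream and basal_down downstream of
    the TSS base.
    """
    out = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - basal_up, g.tss + basal_down
        else:
            start, end = g.tss - basal_down + 1, g.tss + basal_up + 1
        start = max(0, start)
        if genome is not None:
            end = min(end, genome[g.chrom])
        out.append((g.gene_id, (start, end)))
    return out


def extend_domains(
    basal: list[tuple[str, tuple[int, int]]],
    genes: list[GeneAnnotation],
    genome: GenomeTable | None = None,
    max_ext: int = MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Extend basal domains toward neighboring genes' basal domains.

    Each domain grows outward from its basal boundaries until it hits
    another gene's basal domain or reaches ``max_ext`` bp from the TSS,
    whichever is closer.  A gene's own basal domain is always kept, even
    when a neighbor's basal domain overlaps it.
    """
    by_id = {g.gene_id: g for g in genes}
    basal_by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for gid, (bs, be) in basal:
        g = by_id[gid]
        basal_by_chrom.setdefault(g.chrom, []).append((gid, bs, be))

    out: list[RegulatoryDomain] = []
    for gid, (bs, be) in basal:
        g = by_id[gid]
        others = [(s, e) for oid, s, e in basal_by_chrom[g.chrom] if oid != gid]
        cap_left = max(0, g.tss - max_ext)
        cap_right = g.tss + max_ext
        if genome is not None:
            cap_right = min(cap_right, genome[g.chrom])
        # extension stops at the first foreign basal boundary it meets
        left_stop = cap_left
        right_stop = cap_right
        for os_, oe in others:
            if os_ < bs:  # foreign basal to the left (or overlapping own start)
                left_stop = max(left_stop, min(oe, bs))
            if oe > be:  # foreign basal to the right (or overlapping own end)
                right_stop = min(right_stop, max(os_, be))
        ext_start = min(bs, max(cap_left, left_stop))
        ext_end = max(be, min(cap_right, right_stop))
        out.append(
            RegulatoryDomain(
                gene_id=gid,
                chrom=g.chrom,
                strand=g.strand,
                tss=g.tss,
                basal=(bs, be),
                extended=(ext_start, ext_end),
            )
        )
    return out


def build_regulatory_domains(
    genes: list[GeneAnnotation],
    genome: GenomeTable | None = None,
    basal_up: int = BASAL_UP,
    basal_down: int = BASAL_DOWN,
    max_ext: int = MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Convenience: basal construction followed by extension."""
    basal = build_basal_domains(genes, basal_up=basal_up, basal_down=basal_down, genome=genome)
    return extend_domains(basal, genes, genome=genome, max_ext=max_ext)


def link_regions_to_genes(
    regions: PeakSet, domains: list[RegulatoryDomain]
) -> list[EnhancerGeneLink]:
    """Assign each region to every gene whose extended domain it overlaps.

    A region may link zero, one or several genes.
    """
    indexed = sorted(
        (
            (GenomicInterval(d.chrom, d.extended[0], d.extended[1], name=d.gene_id), d)
            for d in domains
        ),
        key=lambda pair: pair[0].sort_key(),
    )
    dom_set = PeakSet(label="_domains", intervals=[iv for iv, _ in indexed])
    links: list[EnhancerGeneLink] = []
    for i, j in overlap_pairs(regions, dom_set):
        d = indexed[j][1]
        m = midpoint(regions[i])
        signed = m - d.tss
        if d.strand == "-":
            signed = -signed
        links.append(EnhancerGeneLink(region=regions[i], gene_id=d.gene_id, distance_to_tss=signed))
    return links


def gene_set_intersection(
    links: list[EnhancerGeneLink], query: set[str]
) -> GeneSetIntersection:
    """Intersect the enhancer-linked gene set with a query gene set."""
    linked = {l.gene_id for l in links}
    overlap = linked & set(query)
    return GeneSetIntersection(
        linked_genes=linked,
        query_genes=set(query),
        n_overlap=len(overlap),
        overlap_ids=overlap,
    )


def binomial_region_enrichment(
    regions: PeakSet,
    domains: list[RegulatoryDomain],
    gene_set: set[str],
    genome: GenomeTable,
) -> tuple[int, float, float]:
    """Region-set binomial enrichment for a gene set's regulatory domains.

    f is the fraction of the genome covered by the union of the
    extended domains of ``gene_set``; k counts regions whose midpoint
    falls in that union; the p-value is P(X >= k) with
    X ~ Binomial(n_regions, f), evaluated by direct summation of the
    binomial terms.

    Returns (k, f, p).
    """
    n = len(regions)
    if n == 0:
        raise ValueError("binomial_region_enrichment: empty region set")
    union = merge_intervals(
        GenomicInterval(d.chrom, d.extended[0], d.extended[1])
        for d in domains
        if d.gene_id in gene_set
    )
    covered = sum(iv.length for iv in union)
    f = covered / genome.total_bp
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in union:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    k = 0
    for r in regions:
        m = midpoint(r)
        for s, e in by_chrom.get(r.chrom, ()):
            if s <= m < e:
                k += 1
                break
    return k, f, binomial_sf(k, n, f)


def binomial_sf(k: int, n: int, f: float) -> float:
    """P(X >= k) for X ~ Binomial(n, f) by direct term summation.

    Terms are evaluated in log space (log-gamma) and accumulated with
    compensated summation; exact 0/1 edge cases are handled explicitly.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if f == 0.0:
        return 0.0  # k >= 1 cannot happen with zero success probability
    if f == 1.0:
        return 1.0
    log_f, log_1mf = math.log(f), math.log1p(-f)
    terms = []
    for i in range(k, n + 1):
        log_c = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        terms.append(math.exp(log_c + i * log_f + (n - i) * log_1mf))
    return min(1.0, math.fsum(terms))
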