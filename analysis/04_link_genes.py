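"""Link enhancer-state co-occupied regions to genes.

Builds basal-plus-extension regulatory domains (5 kb up / 1 kb down,
capped at 1 Mb), keeps common regions whose midpoint lies in an
enhancer state, and assigns each to every gene whose extended domain it
overlaps; writes results/links.tsv and a binomial enrichment summary.
"""

from pathlib import Path

from peaklink import (
    PeakSet,
    binomial_region_enrichment,
    link_regions_to_genes,
    read_bed,
    read_gene_table,
    read_genome_table,
)
from peaklink.genomic import midpoint
from peaklink.linking import build_regulatory_domains

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    genome = read_genome_table(BUNDLE / "chrom.sizes")
    common = read_bed(ROOT / "results" / "common_regions.bed", genome)
    seg = read_bed(BUNDLE / "segmentation.bed", genome, kind="segmentation")
    genes = read_gene_table(BUNDLE / "genes.tsv")

    enhancers = PeakSet(
        label="enhancer_regions",
        intervals=[
            iv for iv in common if seg.state_at(iv.chrom, midpoint(iv)) == "Enhancer"
        ],
        genome=genome,
    )
    domains = build_regulatory_domains(genes, genome=genome)
    links = link_regions_to_genes(enhancers, domains)
    linked_genes = sorted({l.gene_id for l in links})

    out = ROOT / "results"
    with open(out / "links.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\tdistance_to_tss\n")
        for l in links:
            fh.write(
                f"{l.region.chrom}\t{l.region.start}\t{l.region.end}\t{l.gene_id}\t{l.distance_to_tss}\n"
            )

    k, f, p = binomial_region_enrichment(enhancers, domains, set(linked_genes), genome)
    print(
        f"{len(enhancers)} enhancer regions of {len(common)} common regions; "
        f"{len(links)} links to {len(linked_genes)} genes"
    )
    print(f"binomial enrichment of linked-gene domains: k={k}, f={f:.3f}, p={p:.3g}")


if __name__ == "__main__":
    main()
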