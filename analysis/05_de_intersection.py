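"""Intersect enhancer-linked genes with the DE gene sets.

Applies the padj < 0.05 filter to both condition tables (all / up /
down variants) and intersects each DE set with the enhancer-linked
genes from the previous step; writes results/de_intersections.tsv.
"""

from pathlib import Path

import pandas as pd

from peaklink import gene_set_intersection, read_de_table
from peaklink.genomic import GenomicInterval
from peaklink.linking import EnhancerGeneLink
from peaklink.quantstats import de_filter

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    frame = pd.read_csv(ROOT / "results" / "links.tsv", sep="\t")
    links = [
        EnhancerGeneLink(
            region=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            gene_id=r.gene_id,
            distance_to_tss=int(r.distance_to_tss),
        )
        for r in frame.itertuples()
    ]

    rows = []
    for cond in ("cond1", "cond2"):
        table = read_de_table(BUNDLE / f"de_{cond}.tsv")
        for direction in ("all", "up", "down"):
            query = de_filter(table, mode="replicates", alpha=0.05, direction=direction)
            inter = gene_set_intersection(links, query)
            rows.append((cond, direction, len(query), inter.n_overlap))
            if direction == "all":
                print(
                    f"{cond}: {inter.n_overlap} of {len(query)} DE genes are enhancer-linked"
                )
    out = pd.DataFrame(rows, columns=["condition", "direction", "n_de", "n_overlap"])
    out.to_csv(ROOT / "results" / "de_intersections.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
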