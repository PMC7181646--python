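# peaklink

Integration of ChIP-exo binding locations for two chromatin factors with
chromatin-state annotations and RNA-seq differential expression.  The
package answers a family of questions that comes up whenever two factors
are suspected to act together on enhancers: how often do their peaks
co-occur, how tightly are the co-occurring peaks spaced, in which
chromatin states do the shared sites sit relative to a non-specific IgG
background, which genes do the enhancer-borne sites regulate, and do
those genes respond in expression data?

It is written for computational biologists who have peak calls (BED),
a ChromHMM-style segmentation (BED4), gene TSS annotations (TSV/BED6)
and DE tables (TSV), and want the downstream integration steps as
tested, scriptable functions rather than a chain of one-off commands.

## The analysis

1. **Co-occupancy.** Each peak is reduced to its midpoint and expanded
   to a fixed window `[m - w/2, m - w/2 + w)`, `w = 100` bp by default.
   Two factors co-occupy a site when their windows share at least one
   base.  Reported: co-occurring counts, the fraction of each set (and
   of the union) with a partner, and the median midpoint distance
   `median |m_A - m_B|` over co-occurring pairs (nearest partner per
   peak, or all pairs).
2. **Chromatin-state enrichment.** Each region is assigned the state at
   its midpoint; per-state frequencies are compared against an IgG
   control as `log2((f_sample + eps) / (f_IgG + eps))`.
3. **Gene linking (basal plus extension).** Every gene gets a basal
   regulatory domain `[TSS - 5 kb, TSS + 1 kb)` (strand-oriented) and an
   extension in both directions up to the nearest neighboring gene's
   basal domain, capped at 1 Mb from the TSS.  A region is linked to
   every gene whose extended domain it overlaps.  A binomial test
   (`P(X >= k)`, `X ~ Bin(n_regions, f)` with `f` the genomic fraction
   covered by a gene set's domains) quantifies region-set enrichment.
4. **DE intersection.** DE gene sets are thresholded at `padj < 0.05`
   (optionally plus `|log2FC| >= 1`) and intersected with the linked
   genes, for all/up/down variants.
5. Supporting utilities: motif co-localization filtering, TSS/motif
   tag pileups binned by expression, consensus merging of replicate
   peak sets, FPKM, Benjamini-Hochberg adjustment, and ChIP-qPCR
   standard-curve quantification as fold over IgG.

A seeded synthetic-data generator (`peaklink.simulate`) fabricates every
input with planted, recoverable structure — overlap fraction, midpoint
offset distribution, per-state placement multipliers, expression-scaled
tags, DE tables with a fixed number of enhancer-linked DE genes — so the
whole pipeline is verifiable end to end by parameter recovery, without
any external data.

## Worked example

```bash
python analysis/01_simulate.py          # write the synthetic bundle
python analysis/02_cooccupancy.py
python analysis/03_state_enrichment.py
python analysis/04_link_genes.py
python analysis/05_de_intersection.py
```

With the default configuration (seed 0) this prints:

```
1100 co-occurring window pairs; 22.0% of A and 22.0% of B peaks co-occur
median peak-peak distance: 94.0 bp over 1100 pairs
...
Enhancer         log2(sample/IgG) = +1.892
Promoter         log2(sample/IgG) = +1.127
...
495 enhancer regions of 1100 common regions; 832 links to 664 genes
cond1: 541 of 846 DE genes are enhancer-linked
cond2: 49 of 393 DE genes are enhancer-linked
```

Reading: 22% of factor-A peaks have a factor-B window within reach and
the co-occurring pairs sit a median of 94 bp apart — close enough to
suggest a shared complex.  Shared sites are ~4x enriched on enhancers
over the IgG background (log2 ~ 2 under the planted conditions) and
de-enriched in heterochromatin/repressed states.  Of the genes linked to
enhancer-borne shared sites, 541 are differentially expressed in
condition 1 but only 49 in condition 2 — the planted truth, recovered
exactly.

The same stages run from a single config via the CLI
(`peaklink run-all --config cfg.yaml`), and each stage is also exposed
individually (`peaklink cooccur|state-enrich|motif-filter|tss-pileup|
domains|link|de-intersect|simulate`).

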