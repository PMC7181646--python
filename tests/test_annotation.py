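"""Chromatin-state assignment/enrichment, motif filtering and pileups."""

import numpy as np
import pytest
from scipy import stats as sps

from peaklink import (
    GenomicInterval,
    PeakSet,
    Segmentation,
    UNANNOTATED,
    filter_motifs_near_peaks,
    motif_composite_profile,
    state_enrichment,
    state_frequencies,
    tss_pileup,
)
from peaklink.genomic import GeneAnnotation, midpoint

from conftest import make_peaks


@pytest.fixture
def seg():
    ivs = [
        GenomicInterval("chr1", 0, 10_000, name="Enhancer"),
        GenomicInterval("chr1", 10_000, 30_000, name="Promoter"),
        GenomicInterval("chr1", 40_000, 90_000, name="Heterochromatin"),  # gap 30k-40k
        GenomicInterval("chr2", 0, 50_000, name="Enhancer"),
    ]
    return Segmentation.from_intervals(
        ivs, state_catalog=["Promoter", "Enhancer", "Heterochromatin"]
    )


def peaks_at(positions, chrom="chr1", width=11, label="p"):
    ivs = [GenomicInterval(chrom, p - width // 2, p - width // 2 + width) for p in positions]
    return make_peaks(sorted(ivs, key=GenomicInterval.sort_key), label=label)


class TestStateFrequencies:
    def test_all_in_one_state(self, seg):
        counts, freqs = state_frequencies(peaks_at([1_000, 2_000, 9_000]), seg)
        assert freqs["Enhancer"] == 1.0
        assert counts["Promoter"] == 0

    def test_boundary_midpoint_goes_to_following_segment(self, seg):
        # midpoint exactly at a segment end belongs to the next (half-open)
        counts, _ = state_frequencies(peaks_at([10_000]), seg)
        assert counts["Promoter"] == 1 and counts["Enhancer"] == 0

    def test_gap_is_unannotated_and_freqs_sum_to_one(self, seg):
        counts, freqs = state_frequencies(peaks_at([35_000, 1_000, 50_000]), seg)
        assert counts[UNANNOTATED] == 1
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_peak_brute_force(self, seg):
        rng = np.random.default_rng(4)
        pos = [int(p) for p in rng.integers(100, 89_000, 500)]
        ps = peaks_at(pos)
        counts, _ = state_frequencies(ps, seg)
        brute = {}
        for iv in ps:
            st = seg.state_at(iv.chrom, midpoint(iv))
            brute[st] = brute.get(st, 0) + 1
        for st, c in brute.items():
            assert counts[st] == c
        assert sum(counts.values()) == 500

    def test_empty_peaks_rejected(self, seg):
        with pytest.raises(ValueError):
            state_frequencies(make_peaks([]), seg)

    def test_max_overlap_assignment(self, seg):
        # peak [9,990, 10,030): 10 bp Enhancer, 30 bp Promoter
        ps = make_peaks([GenomicInterval("chr1", 9_990, 10_030)])
        counts_mid, _ = state_frequencies(ps, seg)
        counts_ov, _ = state_frequencies(ps, seg, assign="max_overlap")
        assert counts_mid["Promoter"] == 1  # midpoint 10,010
        assert counts_ov["Promoter"] == 1
        # peak [9,900, 10,010): 100 bp Enhancer beats 10 bp Promoter,
        # while the midpoint (9,955) also says Enhancer
        ps2 = make_peaks([GenomicInterval("chr1", 9_900, 10_010)])
        counts_ov2, _ = state_frequencies(ps2, seg, assign="max_overlap")
        assert counts_ov2["Enhancer"] == 1
        # mostly uncovered peak reports Unannotated under max overlap
        ps3 = make_peaks([GenomicInterval("chr1", 29_990, 34_000)])
        counts_ov3, _ = state_frequencies(ps3, seg, assign="max_overlap")
        assert counts_ov3[UNANNOTATED] == 1


class TestStateEnrichment:
    def test_identity_gives_zero_log2fc(self, seg):
        ps = peaks_at([1_000, 15_000, 50_000])
        enr = state_enrichment(ps, ps, seg)
        for st in enr.states:
            assert enr.log2fc[st] == 0.0

    def test_antisymmetry_on_swap(self, seg):
        a = peaks_at([1_000, 2_000, 15_000, 50_000])
        b = peaks_at([15_000, 17_000, 50_000, 60_000])
        fw = state_enrichment(a, b, seg)
        bw = state_enrichment(b, a, seg)
        for st in fw.states:
            assert fw.log2fc[st] == pytest.approx(-bw.log2fc[st], abs=1e-12)

    def test_state_absent_from_both_zero_via_pseudocount(self, seg):
        a = peaks_at([1_000])
        b = peaks_at([2_000])
        enr = state_enrichment(a, b, seg)
        assert enr.log2fc["Heterochromatin"] == 0.0

    def test_empty_control_rejected(self, seg):
        with pytest.raises(ValueError, match="control"):
            state_enrichment(peaks_at([1_000]), make_peaks([]), seg)

    def test_planted_fourfold_enhancer_enrichment(self):
        # a 4x enhancer placement multiplier vs a uniform control recovers
        # log2fc ~ 2 when the weighted state proportions sum to 1
        rng = np.random.default_rng(12)
        L = 1_000_000
        seg = Segmentation.from_intervals(
            [
                GenomicInterval("chr1", 0, L // 2, name="Enhancer"),
                GenomicInterval("chr1", L // 2, L, name="Other"),
            ],
            state_catalog=["Enhancer", "Other"],
        )
        n = 5_000
        # weights: enhancer 4x on half the genome -> sample freq 0.8 is
        # log2(0.8/0.5) != 2; instead plant freq = 4 * 0.5 is impossible,
        # so use proportions 0.1 enhancer: weight 4 with Z = 1
        seg2 = Segmentation.from_intervals(
            [
                GenomicInterval("chr1", 0, L // 10, name="Enhancer"),
                GenomicInterval("chr1", L // 10, L, name="Other"),
            ],
            state_catalog=["Enhancer", "Other"],
        )
        p_enh = 4 * 0.1 / (4 * 0.1 + (2 / 3) * 0.9)  # Z = 1 with other-weight 2/3
        n_enh = rng.binomial(n, p_enh)
        sample_pos = np.concatenate(
            [
                rng.integers(10, L // 10 - 10, n_enh),
                rng.integers(L // 10 + 10, L - 10, n - n_enh),
            ]
        )
        control_pos = rng.integers(10, L - 10, n)
        sample = peaks_at(sorted(int(p) for p in sample_pos))
        control = peaks_at(sorted(int(p) for p in control_pos))
        enr = state_enrichment(sample, control, seg2)
        assert enr.log2fc["Enhancer"] == pytest.approx(2.0, abs=0.2)


class TestMotifFilter:
    def test_threshold_boundary_100_vs_101(self):
        peaks = peaks_at([10_000], width=100)  # peak [9950, 10050)
        motif_100 = make_peaks([GenomicInterval("chr1", 10_150, 10_160)], label="m")
        motif_101 = make_peaks([GenomicInterval("chr1", 10_151, 10_161)], label="m")
        assert len(filter_motifs_near_peaks(motif_100, peaks, window=100)) == 1
        assert len(filter_motifs_near_peaks(motif_101, peaks, window=100)) == 0

    def test_no_peaks_empty_output(self):
        motifs = make_peaks([GenomicInterval("chr1", 10, 20)], label="m")
        assert len(filter_motifs_near_peaks(motifs, make_peaks([], label="p"))) == 0

    def test_overlapping_motif_distance_zero(self):
        peaks = peaks_at([10_000], width=100)
        motifs = make_peaks([GenomicInterval("chr1", 10_000, 10_012)], label="m")
        out = filter_motifs_near_peaks(motifs, peaks)
        assert out[0].score == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_distance_check(self, seed):
        rng = np.random.default_rng(seed)
        window = 100
        motifs = make_peaks(
            sorted(
                (GenomicInterval("chr1", int(s), int(s) + 12) for s in rng.integers(200, 50_000, 300)),
                key=GenomicInterval.sort_key,
            ),
            label="m",
        )
        peaks = peaks_at(sorted(int(p) for p in rng.integers(200, 50_000, 50)), width=60)
        out = filter_motifs_near_peaks(motifs, peaks, window=window)
        kept = {(iv.start, iv.end) for iv in out}
        for m in motifs:
            gaps = [
                max(0, max(m.start, p.start) - min(m.end, p.end)) for p in peaks
            ]
            expected = min(gaps) <= window
            assert ((m.start, m.end) in kept) == expected


class TestCompositeProfile:
    def test_tags_at_anchor_midpoints_pile_at_zero(self):
        anchors = peaks_at([1_000, 5_000, 9_000], width=11)
        tags = make_peaks(
            [GenomicInterval("chr1", p, p + 1) for p in (1_000, 5_000, 9_000)], label="t"
        )
        mat = motif_composite_profile(tags, anchors, half_width=50)
        assert mat.total == 3
        assert mat.counts[0, 50] == 3  # offset 0

    def test_minus_strand_anchor_flips_offset(self):
        anchors = make_peaks(
            [GenomicInterval("chr1", 995, 1_006, strand="-")], label="a"
        )  # midpoint 1000
        tags = make_peaks([GenomicInterval("chr1", 1_010, 1_011)], label="t")
        mat = motif_composite_profile(tags, anchors, half_width=50)
        assert mat.counts[0, -10 + 50] == 1

    def test_uniform_tags_flat_profile(self):
        rng = np.random.default_rng(8)
        anchors = peaks_at(list(range(10_000, 200_000, 10_000)))
        positions = rng.integers(5_000, 200_000, 20_000)
        tags = make_peaks(
            sorted(
                (GenomicInterval("chr1", int(p), int(p) + 1) for p in positions),
                key=GenomicInterval.sort_key,
            ),
            label="t",
        )
        mat = motif_composite_profile(tags, anchors, half_width=100)
        binned = mat.counts[0].reshape(20, 10).sum(axis=1)  # 10-bp bins
        chi2 = ((binned - binned.mean()) ** 2 / binned.mean()).sum()
        assert sps.chi2.sf(chi2, df=len(binned) - 1) > 1e-4

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        anchors = peaks_at([2_000, 6_000])
        positions = rng.integers(0, 10_000, 500)
        tags = make_peaks(
            sorted(
                (GenomicInterval("chr1", int(p), int(p) + 1) for p in positions),
                key=GenomicInterval.sort_key,
            ),
            label="t",
        )
        W = 300
        mat = motif_composite_profile(tags, anchors, half_width=W)
        # oracle: nearest-anchor assignment with in-range strand-oriented offset
        expected = 0
        for p in positions:
            d = min(abs(int(p) - 2_000), abs(int(p) - 6_000))
            anchor = 2_000 if abs(int(p) - 2_000) <= abs(int(p) - 6_000) else 6_000
            off = int(p) - anchor
            if -W <= off <= W - 1:
                expected += 1
        assert mat.total == expected


class TestTssPileup:
    @pytest.fixture
    def genes(self):
        return [
            GeneAnnotation(f"g{i}", "chr1", "+", 10_000 * (i + 1)) for i in range(8)
        ]

    def test_signal_confined_to_top_bin(self, genes):
        expr = {g.gene_id: float(8 - i) for i, g in enumerate(genes)}  # g0 highest
        top = [g for g in genes if expr[g.gene_id] >= 7]  # g0, g1 -> bin 0
        tags = make_peaks(
            [GenomicInterval("chr1", g.tss, g.tss + 1) for g in top], label="t"
        )
        mat = tss_pileup(tags, genes, expr, n_bins=4, half_width=500)
        assert mat.counts[0, 500] == 2
        assert mat.row_totals()[0] == 2
        assert mat.row_totals()[1:].sum() == 0

    def test_intensity_proportional_to_expression_is_monotone(self, genes):
        rng = np.random.default_rng(6)
        expr = {g.gene_id: float(100 * (8 - i)) for i, g in enumerate(genes)}
        ivs = []
        for i, g in enumerate(genes):
            n = 80 * (8 - i)  # more tags for higher expression
            pos = g.tss + np.rint(rng.laplace(0, 40, n)).astype(int)
            ivs.extend(GenomicInterval("chr1", int(p), int(p) + 1) for p in pos)
        tags = make_peaks(sorted(ivs, key=GenomicInterval.sort_key), label="t")
        mat = tss_pileup(tags, genes, expr, n_bins=4, half_width=1_000)
        totals = mat.row_totals()
        assert all(totals[i] > totals[i + 1] for i in range(3))

    def test_single_bin_reduces_to_composite(self, genes):
        rng = np.random.default_rng(10)
        expr = {g.gene_id: float(i) for i, g in enumerate(genes)}
        positions = rng.integers(5_000, 90_000, 2_000)
        tags = make_peaks(
            sorted(
                (GenomicInterval("chr1", int(p), int(p) + 1) for p in positions),
                key=GenomicInterval.sort_key,
            ),
            label="t",
        )
        mat = tss_pileup(tags, genes, expr, n_bins=1, half_width=800)
        anchors = make_peaks(
            [GenomicInterval(g.chrom, g.tss, g.tss + 1, strand=g.strand) for g in genes],
            label="a",
        )
        comp = motif_composite_profile(tags, anchors, half_width=800)
        assert np.array_equal(mat.counts, comp.counts)

    def test_missing_expression_lists_gene_ids(self, genes):
        expr = {g.gene_id: 1.0 for g in genes[:-1]}
        with pytest.raises(ValueError, match=genes[-1].gene_id):
            tss_pileup(make_peaks([], label="t"), genes, expr)

    def test_minus_strand_gene_downstream_offset(self):
        genes = [GeneAnnotation("g1", "chr1", "-", 5_000)]
        tags = make_peaks([GenomicInterval("chr1", 4_990, 4_991)], label="t")
        mat = tss_pileup(tags, genes, {"g1": 1.0}, n_bins=1, half_width=100)
        assert mat.counts[0, 10 + 100] == 1  # 10 bp left of a minus-strand TSS = downstream
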