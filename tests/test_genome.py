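import numpy as np
import pandas as pd
import pytest

from strandmod.genome import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    InvalidParameterError,
    UnknownChromosomeError,
    apply_exclusion,
    assign_feature,
    assign_features,
    count_reads_in_regions,
    count_reads_in_windows,
    overlap_any,
    pool_read_sets,
    tile_genome,
)

from conftest import make_reads


class TestTypes:
    def test_layout_rejects_nonpositive_length(self):
        with pytest.raises(InvalidParameterError):
            GenomeLayout({"chr1": 0})

    def test_interval_rejects_inverted(self):
        with pytest.raises(InvalidParameterError):
            GenomicInterval("chr1", 10, 10)

    def test_interval_midpoint(self):
        assert GenomicInterval("chr1", 990, 1050).midpoint == 1020

    def test_gene_tss_tts_follow_strand(self):
        plus = GeneModel("g1", GenomicInterval("chr1", 100, 900, "+"))
        minus = GeneModel("g2", GenomicInterval("chr1", 100, 900, "-"))
        assert (plus.tss, plus.tts) == (100, 900)
        assert (minus.tss, minus.tts) == (900, 100)
        assert plus.template_strand == "-"
        assert minus.template_strand == "+"

    def test_gene_requires_strand(self):
        with pytest.raises(InvalidParameterError):
            GeneModel("g", GenomicInterval("chr1", 0, 10))

    def test_read_set_library_size(self):
        rs = make_reads([("chr1", 0, 100, "+"), ("chr1", 50, 150, "-")])
        assert rs.library_size == 2

    def test_read_set_bounds_check(self):
        rs = make_reads([("chr1", 0, 200, "+")])
        with pytest.raises(InvalidParameterError):
            rs.validate_bounds(GenomeLayout({"chr1": 100}))

    def test_read_set_unknown_chromosome(self):
        rs = make_reads([("chrX", 0, 50, "+")])
        with pytest.raises(UnknownChromosomeError):
            rs.validate_bounds(GenomeLayout({"chr1": 100}))


class TestTiling:
    def test_exact_division(self):
        win = tile_genome(GenomeLayout({"chr1": 3000}), 1000)
        assert list(win["start"]) == [0, 1000, 2000]
        assert list(win["end"]) == [1000, 2000, 3000]
        assert not win["partial"].any()

    def test_trailing_partial(self):
        win = tile_genome(GenomeLayout({"chr1": 2500}), 1000)
        assert len(win) == 3
        last = win.iloc[-1]
        assert (last["start"], last["end"]) == (2000, 2500)
        assert list(win["partial"]) == [False, False, True]

    def test_window_count_10mb(self):
        win = tile_genome(GenomeLayout({"chr1": 10_000_000}), 1000)
        assert len(win) == 10_000

    def test_invalid_window_size(self):
        with pytest.raises(InvalidParameterError):
            tile_genome(GenomeLayout({"chr1": 1000}), 0)

    def test_tiling_covers_chromosomes_exactly(self, tiny_layout):
        for w in (100, 999, 1000, 7777):
            win = tile_genome(tiny_layout, w)
            for chrom, clen in tiny_layout.chrom_sizes.items():
                grp = win[win["chrom"] == chrom]
                assert grp["start"].iloc[0] == 0
                assert grp["end"].iloc[-1] == clen
                assert (grp["start"].iloc[1:].to_numpy() == grp["end"].iloc[:-1].to_numpy()).all()
                assert (grp["end"] - grp["start"]).sum() == clen


class TestWindowCounting:
    def test_midpoint_assignment(self):
        # read [990,1050) has midpoint 1020 -> second window, plus strand
        layout = GenomeLayout({"chr1": 3000})
        rs = make_reads([("chr1", 990, 1050, "+")])
        wc = count_reads_in_windows(rs, tile_genome(layout, 1000), layout, 1000)
        assert wc.counts[1, 0, 0] == 1
        assert wc.counts.sum() == 1

    def test_three_reads_one_window(self):
        layout = GenomeLayout({"chr1": 3000})
        rs = make_reads(
            [("chr1", 1100, 1200, "+"), ("chr1", 1300, 1400, "-"), ("chr1", 1500, 1600, "+")]
        )
        wc = count_reads_in_windows(rs, tile_genome(layout, 1000), layout, 1000)
        assert wc.counts[1].sum() == 3
        assert wc.counts[1, 0, 0] == 2 and wc.counts[1, 0, 1] == 1

    def test_empty_read_set(self):
        layout = GenomeLayout({"chr1": 3000})
        rs = make_reads([])
        wc = count_reads_in_windows(rs, tile_genome(layout, 1000), layout, 1000)
        assert wc.counts.sum() == 0

    def test_unknown_chromosome_named_in_error(self):
        layout = GenomeLayout({"chr1": 3000})
        win = tile_genome(layout, 1000)
        rs = make_reads([("chrZ", 0, 100, "+")])
        with pytest.raises(UnknownChromosomeError, match="chrZ"):
            count_reads_in_windows(rs, win, GenomeLayout({"chr1": 3000, "chrZ": 5000}), 1000)

    def test_count_conservation(self, small_exp):
        from strandmod.genome import tile_genome as tg

        layout = small_exp.genome.layout
        rs = next(iter(small_exp.samples.values()))
        wc = count_reads_in_windows(rs, tg(layout, 1000), layout, 1000)
        assert wc.counts.sum() + wc.dropped[rs.sample_id] == rs.library_size


class TestRegionCounting:
    def test_gene_spanning_midpoint(self):
        rs = make_reads([("chr1", 100, 200, "+")])
        out = count_reads_in_regions(rs, [GenomicInterval("chr1", 0, 1000)])
        assert out.loc[0, "plus"] == 1

    def test_overlapping_regions_both_increment(self):
        rs = make_reads([("chr1", 100, 200, "-")])
        regions = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 100, 600)]
        out = count_reads_in_regions(rs, regions)
        assert list(out["minus"]) == [1, 1]

    def test_tss_region_clipped_at_chromosome_start(self):
        # TSS at 500, flank 2 kb -> region [-1500, 2500) clipped to [0, 2500)
        rs = make_reads([("chr1", 0, 100, "+"), ("chr1", 2600, 2700, "+")])
        region = pd.DataFrame({"chrom": ["chr1"], "start": [500 - 2000], "end": [2500]})
        out = count_reads_in_regions(rs, region)
        assert out.loc[0, "plus"] == 1  # only the read with midpoint < 2500

    def test_empty_region_list(self):
        rs = make_reads([("chr1", 0, 100, "+")])
        out = count_reads_in_regions(rs, [])
        assert len(out) == 0


class TestFeatureAssignment:
    @pytest.fixture()
    def annotation(self):
        layout = GenomeLayout({"chr1": 100_000})
        genes = [
            GeneModel(
                "coding1",
                GenomicInterval("chr1", 10_000, 30_000, "+"),
                exons=((10_000, 12_000), (20_000, 22_000), (28_000, 30_000)),
            ),
            GeneModel("linc1", GenomicInterval("chr1", 60_000, 70_000, "-"), biotype="lncRNA"),
        ]
        return layout, genes

    def test_intron_window(self, annotation):
        layout, genes = annotation
        win = GenomicInterval("chr1", 15_000, 16_000)
        assert assign_feature(win, genes, layout) == "intron"

    def test_tss_beats_exon(self, annotation):
        layout, genes = annotation
        # window overlapping both the TSS flank [8000,12000) and exon 1
        win = GenomicInterval("chr1", 11_000, 12_000)
        assert assign_feature(win, genes, layout) == "TSS"

    def test_intergenic_fallback(self, annotation):
        layout, genes = annotation
        assert assign_feature(GenomicInterval("chr1", 90_000, 91_000), genes, layout) == "intergenic"

    def test_lncrna_label(self, annotation):
        layout, genes = annotation
        assert assign_feature(GenomicInterval("chr1", 65_000, 66_000), genes, layout) == "lncRNA"

    def test_matches_bruteforce(self, annotation):
        layout, genes = annotation
        win = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(0, 100_000, 1000),
                "end": np.arange(1000, 101_000, 1000),
            }
        )
        fast = assign_features(win, genes, layout)

        # brute force: check every label's raw intervals in precedence order
        from strandmod.genome import FEATURE_PRECEDENCE, build_feature_index

        index = build_feature_index(genes, layout)
        for i, row in win.iterrows():
            expected = "intergenic"
            for label in FEATURE_PRECEDENCE[:-1]:
                refs = index[label]
                if any(
                    (r.chrom == row.chrom and r.start < row.end and r.end > row.start)
                    for r in refs.itertuples()
                ):
                    expected = label
                    break
            assert fast.loc[i] == expected


class TestOverlapAny:
    def test_against_bruteforce_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            qs = rng.integers(0, 1000, 50)
            qe = qs + rng.integers(1, 100, 50)
            rs_ = rng.integers(0, 1000, 30)
            re_ = rs_ + rng.integers(1, 100, 30)
            fast = overlap_any(qs, qe, rs_, re_)
            brute = np.array(
                [((rs_ < e) & (re_ > s)).any() for s, e in zip(qs, qe)]
            )
            assert (fast == brute).all()


class TestExclusionAndPooling:
    def test_apply_exclusion_drops_overlapping_reads(self):
        rs = make_reads([("chr1", 100, 200, "+"), ("chr1", 5000, 5100, "-")])
        excl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        kept = apply_exclusion(rs, excl)
        assert kept.library_size == 1
        assert kept.reads["chr1"]["starts"][0] == 5000

    def test_pool_read_sets_concatenates(self):
        a = make_reads([("chr1", 0, 100, "+")], sample_id="a")
        b = make_reads([("chr1", 200, 300, "-")], sample_id="b")
        pooled = pool_read_sets([a, b])
        assert pooled.library_size == 2

    def test_pool_empty_errors(self):
        with pytest.raises(InvalidParameterError):
            pool_read_sets([])
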