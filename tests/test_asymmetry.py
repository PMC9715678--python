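import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandmod.asymmetry import (
    asymmetry_by_expression,
    asymmetry_by_size,
    asymmetry_coefficient,
    asymmetry_correlations,
    ch_asymmetry,
    ch_counts,
    ch_template_ratio,
    coefficient_array,
    concordance_curve,
    gene_template_ratio,
    gene_template_ratios,
    repeat_family_asymmetry,
    sample_windows,
)
from strandmod.genome import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    InvalidParameterError,
    pool_read_sets,
)

from conftest import make_reads

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


class TestCoefficient:
    def test_worked_values(self):
        assert asymmetry_coefficient(30, 10) == 0.5
        assert asymmetry_coefficient(10, 10) == 0.0

    def test_total_19_excluded(self):
        assert asymmetry_coefficient(9, 10) is None

    def test_zero_zero_excluded(self):
        assert asymmetry_coefficient(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            asymmetry_coefficient(-1, 5)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_strand_swap_invariance_and_range(self, p, m):
        a = asymmetry_coefficient(p, m)
        b = asymmetry_coefficient(m, p)
        assert a == b
        if a is not None:
            assert 0 <= a <= 1

    def test_array_matches_scalar_bruteforce(self):
        rng = np.random.default_rng(0)
        plus = rng.integers(0, 100, 1000)
        minus = rng.integers(0, 100, 1000)
        coef, ok = coefficient_array(plus, minus)
        for i in range(1000):
            want = asymmetry_coefficient(int(plus[i]), int(minus[i]))
            if want is None:
                assert not ok[i]
            else:
                assert ok[i] and coef[i] == pytest.approx(want)


class TestSampling:
    def test_windows_in_bounds_exact_size(self, tiny_layout):
        win = sample_windows(tiny_layout, 1000, n=500, rng=1)
        assert ((win["end"] - win["start"]) == 1000).all()
        for chrom, grp in win.groupby("chrom"):
            assert (grp["start"] >= 0).all()
            assert (grp["end"] <= tiny_layout.length(chrom)).all()

    def test_same_seed_identical(self, tiny_layout):
        a = sample_windows(tiny_layout, 500, n=100, rng=7)
        b = sample_windows(tiny_layout, 500, n=100, rng=7)
        assert a.equals(b)

    def test_size_exceeding_all_chromosomes_errors(self, tiny_layout):
        with pytest.raises(InvalidParameterError):
            sample_windows(tiny_layout, 10_000_000, n=10)

    def test_exclusion_respected(self, tiny_layout):
        excl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [90_000]})
        win = sample_windows(tiny_layout, 1000, n=200, rng=3, exclusion=excl)
        bad = (win["chrom"] == "chr1") & (win["start"] < 90_000)
        assert not bad.any()


class TestTemplateRatio:
    def _gene(self, strand):
        return GeneModel("g", GenomicInterval("chr1", 0, 1000, strand))

    def test_plus_gene(self):
        rs = make_reads(
            [("chr1", 0, 100, "+")] * 30 + [("chr1", 0, 100, "-")] * 70
        )
        assert gene_template_ratio(rs, self._gene("+")) == pytest.approx(0.7)

    def test_minus_gene_flips(self):
        rs = make_reads(
            [("chr1", 0, 100, "+")] * 30 + [("chr1", 0, 100, "-")] * 70
        )
        assert gene_template_ratio(rs, self._gene("-")) == pytest.approx(0.3)

    def test_min_reads_excluded(self):
        rs = make_reads([("chr1", 0, 100, "+")] * 15)
        assert gene_template_ratio(rs, self._gene("+")) is None

    def test_vectorized_matches_bruteforce(self, small_exp):
        pooled = pool_read_sets(small_exp.read_sets("D1", "5hmC"))
        genes = small_exp.genome.genes[:50]
        table = gene_template_ratios(pooled, genes)
        for g, row in zip(genes, table.itertuples(index=False)):
            want = gene_template_ratio(pooled, g)
            if want is None:
                assert not row.pass_filter
            else:
                assert row.template_ratio == pytest.approx(want)


class TestCH:
    def test_worked_examples(self):
        assert ch_asymmetry("CACACACA") == 1.0
        assert ch_asymmetry("CATG") == 0.0
        assert ch_asymmetry("AAAA") is None
        assert ch_asymmetry("") is None

    def test_counts_examples(self):
        assert ch_counts("CACACACA") == (4, 0)
        assert ch_counts("CATG") == (1, 1)

    def test_n_not_counted(self):
        # C followed by N: neighbour unknown, not counted on either strand
        assert ch_counts("CN") == (0, 0)
        assert ch_counts("NG") == (0, 0)

    def test_revcomp_duality_random(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGTN"))
        for _ in range(200):
            s = "".join(rng.choice(bases, size=rng.integers(2, 80), p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            cp, cm = ch_counts(s)
            rp, rm = ch_counts(revcomp(s))
            assert (cp, cm) == (rm, rp)

    def test_template_ratio_orientation(self):
        # all CH on plus strand; for a plus gene the template is minus
        assert ch_template_ratio("CACACACA", "+") == 0.0
        assert ch_template_ratio("CACACACA", "-") == 1.0


class TestBySizeAndConcordance:
    def test_symmetric_data_median_shrinks_with_size(self):
        rng = np.random.default_rng(5)
        layout = GenomeLayout({"chr1": 1_000_000})
        n = 100_000
        starts = rng.integers(0, 999_900, n)
        strands = rng.choice(["+", "-"], n)
        rs = make_reads(
            [("chr1", int(s), int(s) + 100, str(st_)) for s, st_ in zip(starts, strands)]
        )
        out = asymmetry_by_size(rs, layout, [1000, 100_000], n=300, seed=2)
        med = out["summary"].set_index("size")["median"]
        assert med[1000] > med[100_000]
        assert med[100_000] < 0.05

    def test_empty_distribution_not_error(self, tiny_layout):
        rs = make_reads([("chr1", 0, 100, "+")] * 5)
        out = asymmetry_by_size(rs, tiny_layout, [1000], n=50, seed=1)
        assert out["summary"].loc[0, "n_evaluated"] == 0

    def test_fully_symmetric_concordance_near_half(self):
        rng = np.random.default_rng(8)
        layout = GenomeLayout({"chr1": 1_000_000})
        n = 200_000
        starts = rng.integers(0, 999_900, n)
        strands = rng.choice(["+", "-"], n)
        rs = make_reads(
            [("chr1", int(s), int(s) + 100, str(st_)) for s, st_ in zip(starts, strands)]
        )
        curve = concordance_curve(rs, layout, [2000], n=2000, seed=4)
        row = curve.table.iloc[0]
        assert row["adjacent_frac"] == pytest.approx(0.5, abs=0.05)
        assert row["random_frac"] == pytest.approx(0.5, abs=0.05)

    def test_alternating_domains_concordant_below_scale(self):
        """10-kb domains with fractions 0.3/0.7: 1-kb adjacent pairs mostly
        share a domain (concordant); 100-kb windows span many domains."""
        rng = np.random.default_rng(9)
        layout = GenomeLayout({"chr1": 2_000_000})
        reads = []
        lam = 40  # reads per kb cell
        for cell in range(2000):
            domain = cell // 10
            frac = 0.7 if domain % 2 == 0 else 0.3
            k = rng.poisson(lam)
            plus = rng.binomial(k, frac)
            for i in range(k):
                s = cell * 1000 + int(rng.integers(0, 900))
                reads.append(("chr1", s, s + 100, "+" if i < plus else "-"))
        rs = make_reads(reads)
        curve = concordance_curve(rs, layout, [1000, 100_000], n=3000, seed=10)
        tbl = curve.table.set_index("size")
        assert tbl.loc[1000, "adjacent_frac"] > 0.75
        assert tbl.loc[1000, "random_frac"] == pytest.approx(0.5, abs=0.05)
        assert tbl.loc[100_000, "adjacent_frac"] == pytest.approx(0.5, abs=0.1)


class TestByExpressionAndRepeats:
    def test_monotone_planted_fractions_recovered(self, planted_exp):
        cfg = planted_exp.config
        pooled = pool_read_sets(planted_exp.read_sets("D1", "5hmC"))
        ratios = gene_template_ratios(pooled, planted_exp.genome.genes)
        strata = planted_exp.truth.gene_truth["decile"]
        tbl = asymmetry_by_expression(ratios, strata).set_index("stratum")
        deciles = [f"q{i}" for i in range(1, 11)]
        medians = tbl.loc[deciles, "median"].to_numpy()
        assert (np.diff(medians) > -0.01).all()  # monotone up to noise
        from scipy.stats import spearmanr

        assert spearmanr(medians, np.arange(10)).statistic > 0.95

    def test_repeat_family_planted_fraction(self, planted_exp):
        cfg = planted_exp.config
        pooled = pool_read_sets(planted_exp.read_sets("D1", "5hmC"))
        out = repeat_family_asymmetry(pooled, planted_exp.genome.repeats)
        summary = out["summary"].set_index("family")
        for family, planted in cfg.repeat_family_template_frac.items():
            assert summary.loc[family, "median_oriented_ratio"] == pytest.approx(
                planted, abs=0.06
            )
        elements = out["elements"]
        assert (~elements["pass_filter"]).eq(
            elements["plus"] + elements["minus"] < 20
        ).all()

    def test_unknown_family_grouped_as_other(self):
        rs = make_reads([("chr1", 0, 100, "+")] * 25)
        repeats = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [0],
                "end": [500],
                "name": ["weird"],
                "score": [0],
                "strand": ["+"],
            }
        )
        out = repeat_family_asymmetry(rs, repeats, known_families=["LINE"])
        assert list(out["summary"]["family"]) == ["other"]


class TestCorrelations:
    def test_identical_sets_correlation_one(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "template_ratio": np.linspace(0.3, 0.7, 10),
                "pass_filter": True,
            }
        )
        mat = asymmetry_correlations({"a": df, "b": df.copy()})
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_sets_near_zero(self):
        rng = np.random.default_rng(3)
        mk = lambda: pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(500)],
                "template_ratio": rng.random(500),
                "pass_filter": True,
            }
        )
        mat = asymmetry_correlations({"a": mk(), "b": mk()})
        assert abs(mat.loc["a", "b"]) < 0.15

    def test_insufficient_overlap_nan(self):
        a = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "template_ratio": [0.5, 0.6], "pass_filter": True}
        )
        b = pd.DataFrame(
            {"gene_id": ["g1", "g9"], "template_ratio": [0.5, 0.6], "pass_filter": True}
        )
        mat = asymmetry_correlations({"a": a, "b": b})
        assert np.isnan(mat.loc["a", "b"])

    def test_shared_planting_correlates_cell_types(self):
        """Wide planted per-decile spread, shared by both cell types, drives
        D1-vs-D2 gene-ratio Spearman > 0.9 at >= 200 reads/gene."""
        from strandmod.simulate import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(
            seed=77,
            chrom_sizes={"chr1": 4_000_000},
            n_genes=150,
            gene_length_range=(5_000, 15_000),
            n_repeats=0,
            reads_per_sample={"5hmC": 400_000},
            assays=("5hmC",),
            n_clusters=0,
            n_enriched_tfs=0,
            template_frac_deciles=tuple(np.round(np.linspace(0.35, 0.80, 10), 3)),
        )
        exp = simulate_experiment(cfg)
        d1 = pool_read_sets(exp.read_sets("D1", "5hmC"))
        d2 = pool_read_sets(exp.read_sets("D2", "5hmC"))
        genes = exp.genome.genes
        mat = asymmetry_correlations(
            {
                "D1": gene_template_ratios(d1, genes, min_reads=200),
                "D2": gene_template_ratios(d2, genes, min_reads=200),
            }
        )
        assert mat.loc["D1", "D2"] > 0.9
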