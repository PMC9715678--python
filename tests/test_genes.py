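import numpy as np
import pandas as pd
import pytest

from strandmod.genes import (
    CAT_LESS,
    CAT_MIXED,
    CAT_MORE,
    CAT_NOT_DE,
    classify_hmc_expression_direction,
    correlate_mod_expression,
    cpm_table,
    merge_gene_calls,
    metagene_profile,
    stratify_expression,
)
from strandmod.genome import GeneModel, GenomeLayout, GenomicInterval, InvalidParameterError

from conftest import make_reads


class TestStratification:
    def test_quintiles_equal_sizes(self):
        cpm = pd.Series(
            np.linspace(1, 100, 1000), index=[f"g{i:04d}" for i in range(1000)]
        )
        labels = stratify_expression(cpm, n_strata=5)
        counts = labels.value_counts()
        assert all(counts[f"q{i}"] == 200 for i in range(1, 6))

    def test_zero_cpm_is_silent(self):
        cpm = pd.Series([0.0] + [10.0] * 10, index=[f"g{i}" for i in range(11)])
        labels = stratify_expression(cpm, n_strata=2)
        assert labels["g0"] == "silent"

    def test_between_band_excluded(self):
        cpm = pd.Series([0.5] + [10.0] * 10, index=[f"g{i}" for i in range(11)])
        labels = stratify_expression(cpm, n_strata=2)
        assert labels["g0"] == "excluded"

    def test_tie_stability(self):
        cpm = pd.Series([5.0] * 10, index=[f"g{i}" for i in range(10)])
        a = stratify_expression(cpm, n_strata=2)
        b = stratify_expression(cpm.sample(frac=1, random_state=1), n_strata=2)
        assert a.sort_index().equals(b.sort_index())

    def test_too_few_expressed_errors(self):
        cpm = pd.Series([10.0], index=["g0"])
        with pytest.raises(InvalidParameterError):
            stratify_expression(cpm, n_strata=5)

    def test_cpm_table(self):
        counts = pd.DataFrame({"s1": [90, 10], "s2": [400, 100]}, index=["a", "b"])
        cpm = cpm_table(counts)
        assert cpm.loc["a", "s1"] == pytest.approx(900_000)
        assert cpm.loc["b", "s2"] == pytest.approx(200_000)


class TestMetagene:
    def _uniform_setup(self, strand="+"):
        rng = np.random.default_rng(0)
        layout = GenomeLayout({"chr1": 100_000})
        gene = GeneModel("g1", GenomicInterval("chr1", 20_000, 40_000, strand))
        n = 50_000
        starts = rng.integers(0, 99_900, n)
        strands = rng.choice(["+", "-"], n)
        rs = make_reads(
            [("chr1", int(s), int(s) + 100, str(t)) for s, t in zip(starts, strands)]
        )
        return layout, gene, rs

    def test_uniform_input_flat_profile(self):
        layout, gene, rs = self._uniform_setup()
        out = metagene_profile(rs, [gene], layout)
        prof = out["profiles"]["combined"].iloc[0].to_numpy()
        assert prof.std() / prof.mean() < 0.35
        assert abs(prof[:40].mean() - prof[40:140].mean()) / prof.mean() < 0.1

    def test_minus_strand_orientation_flipped(self):
        layout = GenomeLayout({"chr1": 100_000})
        gene = GenomicInterval("chr1", 20_000, 40_000, "-")
        gm = GeneModel("g1", gene)
        # reads piled just downstream of the TSS (which is at 40_000 for minus)
        rs = make_reads([("chr1", 39_000, 39_100, "+")] * 100)
        out = metagene_profile(rs, [gm], layout)
        prof = out["profiles"]["combined"].iloc[0].to_numpy()
        # signal must appear at the body start (bins just after the 40 flank bins)
        assert prof[40:50].sum() > 0
        assert prof[130:140].sum() == 0

    def test_short_gene_skipped(self):
        layout = GenomeLayout({"chr1": 100_000})
        gm = GeneModel("tiny", GenomicInterval("chr1", 50_000, 50_050, "+"))
        rs = make_reads([("chr1", 50_000, 50_040, "+")])
        out = metagene_profile(rs, [gm], layout)
        assert ("tiny", "short") in out["skipped"]

    def test_strand_split_sums_to_combined(self):
        layout, gene, rs = self._uniform_setup()
        both = metagene_profile(rs, [gene], layout, strand_mode="template-vs-coding")
        comb = metagene_profile(rs, [gene], layout, strand_mode="combined")
        total = (
            both["profiles"]["template"].iloc[0] + both["profiles"]["coding"].iloc[0]
        )
        assert np.allclose(total, comb["profiles"]["combined"].iloc[0])

    def test_planted_tss_dip_recovered(self, planted_exp):
        """5hmC TSS dip planted for expressed genes shows as a profile minimum
        near the TSS-adjacent bins of the top stratum."""
        layout = planted_exp.genome.layout
        pooled = [s for s in planted_exp.samples.values() if s.assay == "5hmC"]
        truth = planted_exp.truth.gene_truth
        strata = truth["decile"]
        out = metagene_profile(pooled, planted_exp.genome.genes, layout, strata=strata)
        top = out["profiles"]["combined"].loc["q10"].to_numpy()
        # TSS sits at bin 40 (first body bin); dip half-width 500 bp
        tss_zone = top[38:44]
        body = top[60:120]
        assert tss_zone.min() < 0.5 * body.mean()


class TestMergeCalls:
    def _mk_results(self, sig_ids, units):
        df = pd.DataFrame(units, columns=["unit_id", "chrom", "start", "end"])
        df["log2fc"] = 1.0
        df["padj"] = np.where(df["unit_id"].isin(sig_ids), 0.01, 0.5)
        df["significant"] = df["unit_id"].isin(sig_ids)
        df["direction"] = np.where(df["significant"], "A-up", "none")
        return df

    def test_evidence_sets(self):
        genes = [
            GeneModel("g1", GenomicInterval("chr1", 10_000, 20_000, "+")),
            GeneModel("g2", GenomicInterval("chr1", 50_000, 60_000, "+")),
            GeneModel("g3", GenomicInterval("chr1", 80_000, 90_000, "+")),
        ]
        tss = self._mk_results(["g1"], [(g.gene_id, "chr1", 0, 1) for g in genes])
        body = self._mk_results([], [(g.gene_id, "chr1", 0, 1) for g in genes])
        # window 1.5 kb past the end of g2 -> within the 2-kb flank
        win = self._mk_results(
            ["w1"], [("w1", "chr1", 61_500, 62_500), ("w2", "chr1", 95_000, 96_000)]
        )
        out = merge_gene_calls(tss, body, win, genes)
        calls = out["calls"].set_index("gene_id")
        assert calls.loc["g1", "evidence"] == "TSS"
        assert calls.loc["g2", "evidence"] == "window"
        assert "g3" not in calls.index
        assert out["venn"] == {"TSS": 1, "window": 1}

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(4)
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 900_000))
            genes.append(
                GeneModel(f"g{i}", GenomicInterval("chr1", s, s + int(rng.integers(2_000, 20_000)), "+"))
            )
        win_units = []
        for i in range(60):
            s = int(rng.integers(0, 990_000) // 1000 * 1000)
            win_units.append((f"w{i}", "chr1", s, s + 1000))
        sig = [f"w{i}" for i in range(60) if rng.random() < 0.4]
        win = self._mk_results(sig, win_units)
        tss = self._mk_results([], [(g.gene_id, "chr1", 0, 1) for g in genes])
        body = self._mk_results([], [(g.gene_id, "chr1", 0, 1) for g in genes])
        out = merge_gene_calls(tss, body, win, genes, flank=2000)
        got = set(out["calls"]["gene_id"]) if len(out["calls"]) else set()
        sig_rows = win[win["significant"]]
        want = set()
        for g in genes:
            lo, hi = g.interval.start - 2000, g.interval.end + 2000
            for r in sig_rows.itertuples(index=False):
                if r.start < hi and r.end > lo:
                    want.add(g.gene_id)
                    break
        assert got == want


class TestCorrelation:
    def test_exact_negative_coupling(self):
        mod = pd.Series([1.0, 2.0, -1.0, 0.5], index=list("abcd"))
        out = correlate_mod_expression(mod, -mod)
        assert out["pearson"] == pytest.approx(-1.0)
        assert out["slope"] == pytest.approx(-1.0)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(12)
        x = pd.Series(rng.normal(0, 1, 200), index=[f"g{i}" for i in range(200)])
        y = -0.8 * x + rng.normal(0, 0.3, 200)
        out = correlate_mod_expression(x, y)
        assert out["slope"] == pytest.approx(-0.8, abs=0.1)

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(13)
        x = pd.Series(rng.normal(0, 1, 300), index=[f"g{i}" for i in range(300)])
        y = pd.Series(rng.normal(0, 1, 300), index=x.index)
        out = correlate_mod_expression(x, y)
        assert abs(out["slope"]) < 2.5 * out["slope_stderr"] + 1e-9

    def test_constant_mod_errors(self):
        mod = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.raises(InvalidParameterError):
            correlate_mod_expression(mod, mod * 0)

    def test_too_few_genes_errors(self):
        mod = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(InvalidParameterError):
            correlate_mod_expression(mod, -mod)


class TestHmcExpressionDirection:
    def _setup(self):
        genes = [
            GeneModel(f"g{i}", GenomicInterval("chr1", i * 50_000, i * 50_000 + 10_000, "+"))
            for i in range(4)
        ]
        win = pd.DataFrame(
            {
                "unit_id": ["w0", "w1", "w2a", "w2b", "w3"],
                "chrom": "chr1",
                "start": [2_000, 52_000, 102_000, 104_000, 152_000],
                "end": [3_000, 53_000, 103_000, 105_000, 153_000],
                "significant": True,
                "direction": ["A-up", "B-up", "A-up", "B-up", "A-up"],
            }
        )
        de = pd.DataFrame(
            {
                "de": [True, True, True, False],
                "log2fc": [-1.0, -1.0, 2.0, 0.0],
            },
            index=[f"g{i}" for i in range(4)],
        )
        return genes, win, de

    def test_categories(self):
        genes, win, de = self._setup()
        out = classify_hmc_expression_direction(win, genes, de)
        cats = out["table"].set_index("gene_id")["category"]
        assert cats["g0"] == CAT_LESS  # more 5hmC in A, less expressed in A
        assert cats["g1"] == CAT_MORE  # more 5hmC in B, more expressed in B
        assert cats["g2"] == CAT_MIXED
        assert cats["g3"] == CAT_NOT_DE

    def test_exclusion_list(self):
        genes, win, de = self._setup()
        out = classify_hmc_expression_direction(win, genes, de, exclude_gene_ids={"g0"})
        assert "g0" not in set(out["table"]["gene_id"])

    def test_multinomial_fraction_recovery(self):
        """Planted 40/10/10/40 category mix recovered within +-3 points."""
        rng = np.random.default_rng(5)
        n = 500
        genes, wins, de_rows = [], [], []
        cats = rng.choice(
            [CAT_LESS, CAT_MORE, CAT_MIXED, CAT_NOT_DE], size=n, p=[0.4, 0.1, 0.1, 0.4]
        )
        for i, cat in enumerate(cats):
            s = i * 30_000
            genes.append(GeneModel(f"g{i}", GenomicInterval("chr1", s, s + 10_000, "+")))
            if cat == CAT_MIXED:
                wins.append((f"w{i}a", s + 1000, "A-up"))
                wins.append((f"w{i}b", s + 3000, "B-up"))
                de_rows.append((True, 1.0))
            elif cat == CAT_NOT_DE:
                wins.append((f"w{i}", s + 1000, "A-up"))
                de_rows.append((False, 0.0))
            elif cat == CAT_LESS:
                wins.append((f"w{i}", s + 1000, "A-up"))
                de_rows.append((True, -1.0))
            else:
                wins.append((f"w{i}", s + 1000, "A-up"))
                de_rows.append((True, 1.0))
        win = pd.DataFrame(
            {
                "unit_id": [w[0] for w in wins],
                "chrom": "chr1",
                "start": [w[1] for w in wins],
                "end": [w[1] + 1000 for w in wins],
                "significant": True,
                "direction": [w[2] for w in wins],
            }
        )
        de = pd.DataFrame(
            {"de": [r[0] for r in de_rows], "log2fc": [r[1] for r in de_rows]},
            index=[f"g{i}" for i in range(n)],
        )
        out = classify_hmc_expression_direction(win, genes, de)
        realized = pd.Series(cats).value_counts(normalize=True)
        for cat, nominal in [(CAT_LESS, 0.4), (CAT_MORE, 0.1), (CAT_MIXED, 0.1), (CAT_NOT_DE, 0.4)]:
            # classification recovers the realized planted mix exactly; the
            # realized mix itself sits within multinomial noise of nominal
            assert out["fractions"].get(cat, 0.0) == pytest.approx(realized[cat], abs=1e-12)
            assert realized[cat] == pytest.approx(nominal, abs=0.07)
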