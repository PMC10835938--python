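"""Additive-dosage association scans, LD, and conditional re-analysis."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from solmark.gwas import (
    DosageMatrix,
    association_scan,
    conditional_scan,
    genome_wide_hits,
    ld_r2,
    manhattan_table,
    read_dosage_table,
    read_vcf_dosages,
    write_dosage_table,
)


def make_matrix(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n_var = dosages.shape[1]
    meta = pd.DataFrame(
        {
            "id": ids or [f"v{i}" for i in range(n_var)],
            "chrom": ["1"] * n_var,
            "pos": np.arange(1, n_var + 1) * 1000,
        }
    )
    return DosageMatrix(dosages, meta)


class TestScan:
    def test_matches_statsmodels_per_variant(self, rng):
        n, p = 60, 5
        G = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.5 * G[:, 1] + cov @ [0.3, -0.2] + rng.normal(size=n)
        res = association_scan(make_matrix(G), y, covariates=cov)
        for j in range(p):
            X = sm.add_constant(np.column_stack([cov, G[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res.loc[j, "beta"] == pytest.approx(fit.params[-1], rel=1e-10)
            assert res.loc[j, "se"] == pytest.approx(fit.bse[-1], rel=1e-10)
            assert res.loc[j, "p"] == pytest.approx(fit.pvalues[-1], rel=1e-8)

    def test_covariate_free_closed_form(self, rng):
        n = 80
        g = rng.binomial(2, 0.4, size=n).astype(float)
        y = rng.normal(size=n)
        res = association_scan(make_matrix(g[:, None]), y)
        gc, yc = g - g.mean(), y - y.mean()
        beta = (gc @ yc) / (gc @ gc)
        assert res.loc[0, "beta"] == pytest.approx(beta, rel=1e-10)

    def test_noiseless_signal_recovered(self, rng):
        g = rng.binomial(2, 0.3, size=50).astype(float)
        res = association_scan(make_matrix(g[:, None]), g.copy())
        assert res.loc[0, "beta"] == pytest.approx(1.0, abs=1e-12)
        assert res.loc[0, "p"] < 1e-100

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(77)
        n, p = 200, 2000
        G = rng.binomial(2, rng.uniform(0.05, 0.5, p), size=(n, p)).astype(float)
        y = rng.normal(size=n)  # independent of every variant
        res = association_scan(make_matrix(G), y)
        pvals = res["p"].dropna().to_numpy()
        assert st.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_and_all_missing_skipped(self, rng):
        G = np.column_stack(
            [
                np.full(30, 1.0),
                rng.binomial(2, 0.4, 30).astype(float),
                np.full(30, np.nan),
            ]
        )
        res = association_scan(make_matrix(G), rng.normal(size=30))
        assert res.loc[0, "note"] == "monomorphic"
        assert np.isnan(res.loc[0, "p"])
        assert res.loc[1, "note"] == ""
        assert res.loc[2, "note"] == "all-missing"

    def test_missing_dosages_mean_imputed(self, rng):
        g = rng.binomial(2, 0.4, 40).astype(float)
        g_missing = g.copy()
        g_missing[:5] = np.nan
        g_filled = g.copy()
        g_filled[:5] = g[5:].mean()
        y = rng.normal(size=40)
        r1 = association_scan(make_matrix(g_missing[:, None]), y)
        r2 = association_scan(make_matrix(g_filled[:, None]), y)
        assert r1.loc[0, "beta"] == pytest.approx(r2.loc[0, "beta"], rel=1e-12)

    def test_rank_deficient_covariates_rejected(self, rng):
        g = rng.binomial(2, 0.4, 30).astype(float)
        cov = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank"):
            association_scan(make_matrix(g[:, None]), rng.normal(size=30), covariates=cov)


class TestLD:
    def test_self_and_flip(self, rng):
        a = rng.binomial(2, 0.3, 100).astype(float)
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)
        assert ld_r2(a, rng.binomial(2, 0.3, 100)) == pytest.approx(
            ld_r2(rng.binomial(2, 0.3, 100), a), abs=1.0
        )  # symmetric signature sanity

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.4, 10_000).astype(float)
        assert ld_r2(a, b) < 0.005

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(np.ones(10), np.arange(10, dtype=float))


class TestConditional:
    @pytest.fixture()
    def single_signal(self):
        rng = np.random.default_rng(99)
        n = 300
        causal = rng.binomial(2, 0.25, n).astype(float)
        proxy = causal.copy()
        flip = rng.random(n) < 0.05
        proxy[flip] = rng.binomial(2, 0.25, int(flip.sum()))
        noise = rng.binomial(2, 0.3, size=(n, 50)).astype(float)
        G = np.column_stack([causal, proxy, noise])
        ids = ["causal", "proxy"] + [f"bg{i}" for i in range(50)]
        y = 0.8 * causal + rng.normal(size=n)
        return make_matrix(G, ids=ids), y

    def test_adjusting_for_causal_extinguishes_hits(self, single_signal):
        dm, y = single_signal
        base_hits = genome_wide_hits(association_scan(dm, y))
        assert "causal" in set(base_hits["id"])
        cond = conditional_scan(dm, y, adjust_for="causal")
        assert genome_wide_hits(cond).empty

    def test_adjusting_for_unrelated_variant_keeps_top_hit(self, single_signal):
        dm, y = single_signal
        base = association_scan(dm, y)
        top = base.loc[base["p"].idxmin(), "id"]
        cond = conditional_scan(dm, y, adjust_for="bg0")
        cond_ok = cond[cond["p"].notna()]
        assert cond_ok.loc[cond_ok["p"].idxmin(), "id"] == top

    def test_adjusting_variant_itself_skipped(self, single_signal):
        dm, y = single_signal
        cond = conditional_scan(dm, y, adjust_for="causal")
        row = cond[cond["id"] == "causal"].iloc[0]
        assert row["note"] == "adjusted-for"
        assert np.isnan(row["p"])

    def test_threshold_logic(self, single_signal):
        dm, y = single_signal
        res = association_scan(dm, y)
        hits = genome_wide_hits(res)
        expected = res[res["p"].notna() & (res["p"] < 5e-8)]
        assert set(hits["id"]) == set(expected["id"])


class TestIO:
    def test_dosage_table_round_trip(self, tmp_path, rng):
        dm = make_matrix(rng.binomial(2, 0.3, size=(12, 4)).astype(float))
        path = tmp_path / "dosages.tsv"
        write_dosage_table(dm, path)
        back = read_dosage_table(path)
        assert np.allclose(back.dosages, dm.dosages)
        assert list(back.variants["id"]) == list(dm.variants["id"])

    def test_minimal_vcf_reader(self, tmp_path):
        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=22>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "22\t42130000\trsA\tG\tA\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "22\t42131000\trsB\tC\tT\t.\t.\t.\tGT\t0/1\t./.\t0/0\n"
        )
        dm = read_vcf_dosages(vcf)
        assert dm.subject_ids == ["S1", "S2", "S3"]
        assert dm.dosages[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert dm.dosages[0, 1] == 1.0 and np.isnan(dm.dosages[1, 1])

    def test_manhattan_table_columns(self, rng):
        dm = make_matrix(rng.binomial(2, 0.3, size=(40, 3)).astype(float))
        res = association_scan(dm, rng.normal(size=40))
        man = manhattan_table(res)
        assert list(man.columns) == ["chrom", "pos", "neglog10_p"]
        assert np.allclose(man["neglog10_p"], -np.log10(res["p"].dropna()))
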