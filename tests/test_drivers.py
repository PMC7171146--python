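import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uvmtk import PipelineConfig
from uvmtk.drivers import (
    combine_fisher,
    cox_univariate,
    frequency_filter,
    purity_adjusted_association,
    rank_candidates,
    rpkm_normalize,
)


class TestRPKM:
    def test_identical_columns_give_unit_size_factors(self):
        col = pd.Series([10, 20, 30], index=["g1", "g2", "g3"])
        counts = pd.DataFrame({"s1": col, "s2": col, "s3": col})
        norm = rpkm_normalize(counts, pd.Series(1000, index=counts.index))
        np.testing.assert_allclose(norm.size_factors, 1.0)

    def test_formula_identity(self):
        # one gene carrying the whole library: count 1000, length 1000 bp,
        # effective library 1e6 -> RPKM = 1000e9 / (1e6 * 1e3) = 1000
        counts = pd.DataFrame({"s1": [1000]}, index=["g1"])
        lengths = pd.Series([1000], index=["g1"])
        norm = rpkm_normalize(counts, lengths)
        # single sample: size factor 1, effective library = raw library
        assert norm.effective_lib["s1"] == pytest.approx(1000)
        assert norm.rpkm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_doubling_one_sample_leaves_rpkm_unchanged(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(500, 5000, 30), index=counts.index)
        base = rpkm_normalize(counts, lengths)
        doubled = counts.copy()
        doubled["b"] = doubled["b"] * 2
        new = rpkm_normalize(doubled, lengths)
        # the doubled sample's effective library size doubles ...
        assert new.effective_lib["b"] == pytest.approx(
            2 * base.effective_lib["b"]
        )
        # ... and every RPKM value is unchanged
        pd.testing.assert_frame_equal(
            new.rpkm, base.rpkm, check_exact=False, atol=1e-9
        )

    def test_fallback_when_no_all_positive_gene(self):
        counts = pd.DataFrame(
            {"s1": [0, 5], "s2": [5, 0]}, index=["g1", "g2"]
        )
        with pytest.warns(UserWarning, match="library-size"):
            norm = rpkm_normalize(counts, pd.Series(1000, index=counts.index))
        np.testing.assert_allclose(norm.size_factors, 1.0)


class TestAssociation:
    def test_perfect_fit_recovers_slope(self):
        cn = pd.DataFrame(
            [np.linspace(-1, 1, 10)], index=["g"],
            columns=[f"s{i}" for i in range(10)],
        )
        expr = 2.0 * cn
        purity = pd.Series(0.6, index=cn.columns)
        res = purity_adjusted_association(
            expr, cn, purity, log_transform=False
        )
        assert res.loc["g", "slope"] == pytest.approx(2.0)
        assert res.loc["g", "p"] < 1e-30  # numerically zero

    def test_constant_cn_dropped(self):
        cn = pd.DataFrame(
            [[0.5] * 8], index=["g"], columns=[f"s{i}" for i in range(8)]
        )
        expr = pd.DataFrame(
            [np.arange(8.0)], index=["g"], columns=cn.columns
        )
        purity = pd.Series(np.linspace(0.3, 0.9, 8), index=cn.columns)
        res = purity_adjusted_association(expr, cn, purity, log_transform=False)
        assert res.loc["g", "status"] == "dropped_degenerate"
        assert np.isnan(res.loc["g", "p"])

    def test_purity_covariate_removes_confounding(self):
        # expression driven solely by purity; cn independent of expression.
        rng = np.random.default_rng(2)
        n = 60
        purity = pd.Series(rng.uniform(0.3, 0.9, n),
                           index=[f"s{i}" for i in range(n)])
        cn = pd.DataFrame(rng.normal(0, 0.5, (30, n)),
                          index=[f"g{i}" for i in range(30)],
                          columns=purity.index)
        expr = pd.DataFrame(
            3.0 * purity.values + rng.normal(0, 0.1, (30, n)),
            index=cn.index, columns=purity.index,
        )
        res = purity_adjusted_association(expr, cn, purity, log_transform=False)
        # no gene should show a strong copy-number association
        assert (res["p"] > 1e-4).all()

    def test_null_p_values_uniform(self):
        # beta = 0 everywhere: p ~ U(0,1) by Kolmogorov-Smirnov at alpha=0.01
        rng = np.random.default_rng(3)
        n, G = 40, 5000
        purity = pd.Series(rng.uniform(0.3, 0.9, n),
                           index=[f"s{i}" for i in range(n)])
        cn = pd.DataFrame(rng.choice([0.0, 0.58], size=(G, n)),
                          index=[f"g{i}" for i in range(G)],
                          columns=purity.index)
        expr = pd.DataFrame(rng.normal(5, 1, (G, n)),
                            index=cn.index, columns=purity.index)
        res = purity_adjusted_association(expr, cn, purity, log_transform=False)
        ok = res.dropna(subset=["p"])
        assert len(ok) > 4500
        ks = stats.kstest(ok["p"].values, "uniform")
        assert ks.pvalue > 0.01


class TestCombineFisher:
    def test_unit_inputs_give_one(self):
        assert combine_fisher(1.0, 1.0) == pytest.approx(1.0)

    def test_known_values(self):
        # chi2(4) survival at -4 ln 0.05 = 11.9829 and -4 ln 0.5 = 2.7726;
        # closed form exp(-x/2) (1 + x/2)
        for p in (0.05, 0.5):
            x = -4.0 * np.log(p)
            expected = np.exp(-x / 2) * (1 + x / 2)
            assert combine_fisher(p, p) == pytest.approx(expected, rel=1e-9)
        assert combine_fisher(0.05, 0.05) == pytest.approx(0.0175, abs=5e-5)
        assert combine_fisher(0.5, 0.5) == pytest.approx(0.5966, abs=5e-5)

    def test_symmetric_and_monotone(self):
        assert combine_fisher(0.01, 0.7) == combine_fisher(0.7, 0.01)
        grid = np.linspace(0.01, 1, 25)
        vals = [combine_fisher(p, 0.3) for p in grid]
        assert all(a < b + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = combine_fisher(0.0, 0.5)
        assert 0 <= out < 1e-10


class TestFrequencyFilter:
    def _statuses(self, freqs, n=20):
        rows = []
        for f in freqs:
            k = round(f * n)
            rows.append([0.5] * k + [0.0] * (n - k))
        return pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(freqs))],
            columns=[f"s{i}" for i in range(n)],
        )

    def test_equal_frequencies_all_retained(self, config):
        st = self._statuses([0.3, 0.3, 0.3, 0.3])
        out = frequency_filter(st, "gain", config)
        assert out["retained"].all()

    def test_type7_quantile_cutoff(self, config):
        st = self._statuses([0.1, 0.2, 0.3, 0.4])
        # type-7 Q3 of (0.1, 0.2, 0.3, 0.4) is 0.325
        assert np.quantile([0.1, 0.2, 0.3, 0.4], 0.75) == pytest.approx(0.325)
        out = frequency_filter(st, "gain", config)
        assert list(out.index[out["retained"]]) == ["g3"]

    def test_subthreshold_gene_gets_zero_frequency(self, config):
        st = self._statuses([0.4, 0.4, 0.4])
        st.loc["g_low"] = 0.1  # |log2| < 0.2 in every sample
        out = frequency_filter(st, "gain", config)
        assert out.loc["g_low", "frequency"] == 0.0
        assert not out.loc["g_low", "retained"]

    def test_direction_respected(self, config):
        st = self._statuses([0.5])
        out = frequency_filter(st, "loss", config)
        assert out.loc["g0", "frequency"] == 0.0


class TestCox:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            n = 100
            x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            t = rng.exponential(10, n)
            surv = pd.DataFrame(
                {"time": np.minimum(t, 25), "event": (t <= 25).astype(int)},
                index=x.index,
            )
            fit = cox_univariate(x, surv)
            if fit["testable"]:
                pvals.append(fit["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_hazard_recovered(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 60
        for _ in range(reps):
            n = 200
            x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            lam = 0.1 * np.exp(0.7 * x.values)
            t = rng.exponential(1 / lam)
            surv = pd.DataFrame(
                {"time": np.minimum(t, 30), "event": (t <= 30).astype(int)},
                index=x.index,
            )
            fit = cox_univariate(x, surv)
            if fit["testable"] and fit["coef"] > 0 and fit["p"] < 0.05:
                hits += 1
        assert hits >= 0.95 * reps

    def test_all_censored_untestable(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        surv = pd.DataFrame(
            {"time": [5, 6, 7], "event": [0, 0, 0]}, index=list("abc")
        )
        assert not cox_univariate(x, surv)["testable"]


class TestRankCandidates:
    def _cands(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "arm", "direction", "degree", "survival_flag", "q"],
        )

    def test_degree_is_primary_key(self):
        out = rank_candidates(self._cands([
            ("gLow", "8q", "gain", 3, True, 0.001),
            ("gHigh", "8q", "gain", 10, False, 0.04),
        ]))
        assert out.loc[out["rank"] == 1, "gene"].item() == "gHigh"

    def test_survival_flag_breaks_degree_tie(self):
        out = rank_candidates(self._cands([
            ("gPlain", "8q", "gain", 7, False, 0.001),
            ("gSurv", "8q", "gain", 7, True, 0.04),
        ]))
        assert out.loc[out["rank"] == 1, "gene"].item() == "gSurv"

    def test_q_then_name_break_remaining_ties(self):
        out = rank_candidates(self._cands([
            ("gB", "8q", "gain", 7, True, 0.02),
            ("gA", "8q", "gain", 7, True, 0.02),
            ("gC", "8q", "gain", 7, True, 0.01),
        ]))
        assert out.sort_values("rank")["gene"].tolist() == ["gC", "gA", "gB"]

    def test_missing_degree_counts_as_zero(self):
        cands = self._cands([
            ("gKnown", "3", "loss", 2, False, 0.01),
            ("gUnknown", "3", "loss", np.nan, False, 0.001),
        ])
        out = rank_candidates(cands)
        assert out.loc[out["rank"] == 1, "gene"].item() == "gKnown"


class TestEndToEndRanking:
    def test_planted_driver_ranked_first(self, config):
        from uvmtk import gene_copy_matrix, rank_drivers
        from uvmtk.simulate import driver_recovery_spec, simulate_cn_expression

        spec = driver_recovery_spec(n_genes_per_arm=60)
        cohort = simulate_cn_expression(spec, seed=42)
        cn_a = gene_copy_matrix(cohort.profiles_a, cohort.gene_models)
        cn_b = gene_copy_matrix(cohort.profiles_b, cohort.gene_models)
        ranked = rank_drivers(
            cohort.counts_a, cn_a, cohort.purity_a,
            cohort.counts_b, cn_b, cohort.purity_b,
            cohort.regions, cohort.gene_models, cohort.ppi_degree,
            cohort.survival_b, config,
        )
        top1 = ranked[ranked["rank"] == 1].set_index(["arm", "direction"])["gene"]
        truth = cohort.truth_drivers.set_index(["arm", "direction"])["gene"]
        for key, gene in truth.items():
            assert top1.get(key) == gene
        # direction consistency invariant: no retained gain candidate with
        # a negative slope in either cohort
        gains = ranked[(ranked["direction"] == "gain") & ranked["retained"]]
        assert (gains["slope_a"] > 0).all() and (gains["slope_b"] > 0).all()
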