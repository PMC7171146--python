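import numpy as np
import pandas as pd
import pytest

from uvmtk import PipelineConfig
from uvmtk.signatures import (
    CHANNELS_96,
    build_96_vector,
    channel_of,
    filter_for_signatures,
    fit_signatures,
    strand_bias_table,
    strand_bias_test,
)
from uvmtk.simulate import simulate_mutation_catalog, synthetic_signature_set
from conftest import nnls_projected_gradient


def _variants(rows):
    cols = ["sample", "chrom", "pos", "ref", "alt", "tri_context",
            "gene_strand", "population_flag", "alt_support"]
    return pd.DataFrame(rows, columns=cols)


class TestFilter:
    def test_three_exclusion_rules(self, config):
        table = _variants([
            ("S", "1", 100, "C", "A", "ACA", "intergenic", False, 20),
            ("S", "X", 100, "C", "A", "ACA", "intergenic", False, 20),  # sex chrom
            ("S", "2", 100, "C", "T", "ACG", "transcribed", True, 20),  # population
            ("S", "3", 100, "T", "G", "ATA", "intergenic", False, 5),   # low support
            ("S", "4", 100, "T", "C", "CTG", "untranscribed", False, 10),  # boundary
            ("S", "5", 100, "G", "T", "TGT", "intergenic", False, 50),
        ])
        kept = filter_for_signatures(table, config)
        assert len(kept) == 3
        assert set(kept["chrom"]) == {"1", "4", "5"}

    def test_support_boundary_is_inclusive(self, config):
        nine = _variants([("S", "1", 1, "C", "A", "ACA", "intergenic", False, 9)])
        ten = _variants([("S", "1", 1, "C", "A", "ACA", "intergenic", False, 10)])
        assert len(filter_for_signatures(nine, config)) == 0
        assert len(filter_for_signatures(ten, config)) == 1


class TestBuild96:
    def test_pyrimidine_reference_direct(self):
        assert channel_of("C", "A", "ACA") == "A[C>A]A"

    def test_purine_reverse_complemented(self):
        # T[G>T]T on the purine strand is A[C>A]A on the pyrimidine strand
        assert channel_of("G", "T", "TGT") == "A[C>A]A"

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        sigs = synthetic_signature_set(2, seed=1)
        cat = simulate_mutation_catalog([0.5, 0.5], 500, sigs, seed=2)
        vec = build_96_vector(cat)
        assert vec.sum() == 500
        assert list(vec.index) == CHANNELS_96


class TestFitSignatures:
    def test_exact_representable_mixture_recovered(self):
        sigs = synthetic_signature_set(4, seed=3)
        w0 = np.array([10.0, 0.0, 5.0, 1.0])
        m = sigs.to_numpy() @ w0
        fit = fit_signatures(m, sigs)
        np.testing.assert_allclose(fit.absolute.values, w0, atol=1e-8)
        assert fit.residual == pytest.approx(0.0, abs=1e-8)

    def test_single_signature_one_hot(self):
        sigs = synthetic_signature_set(3, seed=4)
        m = 250.0 * sigs.iloc[:, 1].to_numpy()
        fit = fit_signatures(m, sigs)
        np.testing.assert_allclose(
            fit.relative.values, [0.0, 1.0, 0.0], atol=1e-9
        )

    def test_empty_catalog_is_error(self):
        sigs = synthetic_signature_set(3, seed=5)
        with pytest.raises(ValueError, match="empty catalog"):
            fit_signatures(np.zeros(96), sigs)

    def test_scaling_invariance(self):
        sigs = synthetic_signature_set(3, seed=6)
        m = np.random.default_rng(7).poisson(5.0, 96).astype(float) + 1
        f1 = fit_signatures(m, sigs)
        f3 = fit_signatures(3 * m, sigs)
        np.testing.assert_allclose(f3.absolute.values, 3 * f1.absolute.values,
                                   rtol=1e-8)
        np.testing.assert_allclose(f3.relative.values, f1.relative.values,
                                   rtol=1e-8)

    def test_matches_projected_gradient_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            S = rng.dirichlet(np.full(96, 0.1), size=10).T
            m = rng.poisson(3.0, 96).astype(float)
            fit = fit_signatures(m, pd.DataFrame(S, index=CHANNELS_96))
            w_pg, _ = nnls_projected_gradient(S, m)
            f_nnls = 0.5 * np.sum((S @ fit.absolute.values - m) ** 2)
            f_pg = 0.5 * np.sum((S @ w_pg - m) ** 2)
            assert abs(f_nnls - f_pg) < 1e-6
            assert f_nnls <= f_pg + 1e-9  # NNLS at least as good as oracle


class TestStrandBias:
    def test_symmetric_counts_give_one(self):
        assert strand_bias_test(10, 10) == pytest.approx(1.0)

    def test_15_vs_5_closed_form(self):
        # 2 * P(X >= 15 | n=20, p=1/2) = 2 * 21700 / 2^20
        from math import comb

        expected = 2 * sum(comb(20, k) for k in range(15, 21)) / 2**20
        assert strand_bias_test(15, 5) == pytest.approx(expected, rel=1e-9)
        assert strand_bias_test(15, 5) == pytest.approx(0.0414, abs=5e-5)

    def test_fully_one_sided_closed_form(self):
        assert strand_bias_test(0, 20) == pytest.approx(2 * 2**-20, rel=1e-9)

    def test_symmetric_under_swap(self):
        for x, y in [(3, 9), (0, 7), (12, 12)]:
            assert strand_bias_test(x, y) == pytest.approx(
                strand_bias_test(y, x), rel=1e-12
            )

    def test_both_zero_untestable(self):
        assert np.isnan(strand_bias_test(0, 0))

    def test_table_adjusts_across_classes(self, config):
        sigs = synthetic_signature_set(2, seed=9)
        cat = simulate_mutation_catalog(
            [0.7, 0.3], 2000, sigs, seed=10, transcribed_fraction=0.25
        )
        out = strand_bias_table(cat)
        testable = out.dropna(subset=["q"])
        assert (testable["q"] >= testable["p"] - 1e-12).all()
        # with a strong planted asymmetry, at least one class is significant
        assert (testable["q"] < 0.05).any()


class TestSummary:
    def test_contributions_below_display_threshold_suppressed(self):
        sigs = synthetic_signature_set(3, seed=11)
        m = sigs.to_numpy() @ np.array([70.0, 25.0, 5.0])
        fit = fit_signatures(m, sigs)
        from uvmtk.signatures import summarize_contributions

        summary = summarize_contributions(fit, display_threshold=0.30)
        assert list(summary.index) == ["SynthSig1"]
        # the full fit keeps every contribution
        assert (fit.relative > 0).sum() == 3
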