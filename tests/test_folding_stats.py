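"""Surface/HPLC classification, permutation concordance, chi-square, GSEA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cdpscreen.folding_stats import (
    HplcClass,
    SurfaceClass,
    SurfaceClassBoundary,
    bin_enrichment_ranks,
    chi_square_2x2,
    classify_hplc,
    classify_surface,
    concordance_permutation_test,
    fit_boundary,
    gsea_unweighted,
)


class TestClassifySurface:
    BOUNDARY = SurfaceClassBoundary(slope=-50.0, intercept=150.0)

    def test_direct_evaluation(self):
        s = pd.Series([1e4], index=["p"])
        t = pd.Series([100.0], index=["p"])
        out = classify_surface(s, t, self.BOUNDARY)
        assert out["p"] == SurfaceClass.HC_TR.value

    def test_point_on_line_is_hc_tr(self):
        # T = -50*log10(S) + 150 at S=100 gives T = 50 exactly
        s = pd.Series([100.0], index=["p"])
        t = pd.Series([50.0], index=["p"])
        assert classify_surface(s, t, self.BOUNDARY)["p"] == SurfaceClass.HC_TR.value

    def test_matches_sign_oracle(self, rng):
        s = pd.Series(10 ** rng.uniform(0, 5, 1000))
        t = pd.Series(rng.uniform(0, 200, 1000))
        out = classify_surface(s, t, self.BOUNDARY)
        for i in range(1000):
            margin = t[i] - (-50.0 * math.log10(s[i]) + 150.0)
            expect = SurfaceClass.HC_TR.value if margin >= 0 else SurfaceClass.LC_TS.value
            assert out[i] == expect

    def test_undefined_inputs_unclassified(self):
        s = pd.Series([np.nan, 100.0], index=["a", "b"])
        t = pd.Series([50.0, np.nan], index=["a", "b"])
        out = classify_surface(s, t, self.BOUNDARY)
        assert out["a"] is None and out["b"] is None

    def test_nonfinite_boundary_rejected(self):
        with pytest.raises(ValueError):
            SurfaceClassBoundary(slope=np.inf, intercept=0.0)

    def test_fit_boundary_recovers_reference_split(self, rng):
        truth = SurfaceClassBoundary(slope=-50.0, intercept=150.0)
        s = pd.Series(10 ** rng.uniform(1, 5, 500))
        t = pd.Series(rng.uniform(0, 200, 500))
        ref = classify_surface(s, t, truth)
        fitted = fit_boundary(s, t, ref)
        refit = classify_surface(s, t, fitted)
        assert (refit == ref).mean() >= 0.98


class TestClassifyHplc:
    def test_one_dominant_peak_both_conditions(self):
        assert classify_hplc([(5.0, 100.0)], [(6.0, 90.0)]) is HplcClass.PEAKS_1_2

    def test_dominant_plus_one_minor_ok(self):
        native = [(5.0, 80.0), (6.0, 20.0)]
        reduced = [(4.0, 95.0), (7.0, 5.0)]
        assert classify_hplc(native, reduced) is HplcClass.PEAKS_1_2

    def test_below_detection_floor_is_zero_peaks(self):
        assert (
            classify_hplc([(5.0, 0.5)], [(6.0, 90.0)], detection_floor=1.0)
            is HplcClass.PEAKS_0
        )

    def test_four_equal_peaks_is_3plus(self):
        native = [(i, 25.0) for i in range(4)]
        assert classify_hplc(native, [(5.0, 100.0)]) is HplcClass.PEAKS_3PLUS

    def test_two_minors_is_3plus(self):
        native = [(1, 80.0), (2, 10.0), (3, 10.0)]
        assert classify_hplc(native, [(5.0, 100.0)]) is HplcClass.PEAKS_3PLUS

    def test_reduced_condition_also_required(self):
        native = [(1, 100.0)]
        reduced = [(i, 25.0) for i in range(4)]
        assert classify_hplc(native, reduced) is HplcClass.PEAKS_3PLUS

    def test_invariant_to_area_scaling(self, rng):
        for _ in range(20):
            native = [(float(i), float(a)) for i, a in
                      enumerate(rng.uniform(1, 100, rng.integers(1, 5)))]
            reduced = [(float(i), float(a)) for i, a in
                       enumerate(rng.uniform(1, 100, rng.integers(1, 5)))]
            base = classify_hplc(native, reduced)
            scaled = classify_hplc(
                [(t, 1e3 * a) for t, a in native],
                [(t, 1e3 * a) for t, a in reduced],
            )
            assert base is scaled

    def test_missing_reduced_condition_rejected(self):
        with pytest.raises(ValueError):
            classify_hplc([(1.0, 50.0)], [])


def exhaustive_tail_fraction(a, b):
    """Brute-force oracle: exact tail fraction of the matched-fraction
    statistic over all distinct arrangements of b."""
    obs = np.mean(np.asarray(a) == np.asarray(b))
    perms = set(itertools.permutations(b))
    hits = sum(np.mean(np.asarray(a) == np.asarray(p)) >= obs - 1e-12
               for p in perms)
    return hits / len(perms)


class TestConcordancePermutation:
    def test_single_class_hplc_gives_p_one(self):
        a = np.array([True, False, True, False])
        b = np.ones(4, dtype=bool)
        with pytest.warns(UserWarning):
            res = concordance_permutation_test(a, b, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_exhaustive_matches_brute_force(self):
        a = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        for b in (a.copy(), np.array([1, 0, 1, 0, 1, 0], dtype=bool)):
            res = concordance_permutation_test(a, b, exhaustive=True)
            assert res.p_value == pytest.approx(exhaustive_tail_fraction(a, b))

    def test_perfect_concordance_exhaustive_p(self):
        # 3/3 balance, 20 distinct arrangements, only identity matches all
        a = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        res = concordance_permutation_test(a, a, exhaustive=True)
        assert res.observed == 1.0
        assert res.p_value == pytest.approx(1 / 20)

    def test_monte_carlo_approaches_exhaustive(self):
        rng = np.random.default_rng(5)
        a = rng.random(7) < 0.5
        b = rng.random(7) < 0.5
        exact = concordance_permutation_test(a, b, exhaustive=True).p_value
        mc = concordance_permutation_test(a, b, n_perm=200_000, seed=1).p_value
        assert mc == pytest.approx(exact, abs=0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        a = rng.random(50) < 0.5
        b = rng.random(50) < 0.5
        r1 = concordance_permutation_test(a, b, n_perm=999, seed=7)
        r2 = concordance_permutation_test(a, b, n_perm=999, seed=7)
        assert r1.p_value == r2.p_value

    def test_mcc_statistic_route(self):
        rng = np.random.default_rng(3)
        a = rng.random(40) < 0.5
        res = concordance_permutation_test(a, a, n_perm=199, seed=2,
                                           statistic="mcc")
        assert res.observed == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_super_uniform_under_null(self):
        # p-values under independent labels must not be anti-conservative
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(300):
            a = rng.random(200) < 0.5
            b = rng.random(200) < 0.5
            pvals.append(
                concordance_permutation_test(
                    a, b, n_perm=499, seed=int(rng.integers(2**31))
                ).p_value
            )
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1):
            se = math.sqrt(alpha * (1 - alpha) / len(pvals))
            assert (pvals <= alpha).mean() <= alpha + 3 * se


class TestChiSquare:
    def test_homogeneous_table(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_value(self):
        stat, p = chi_square_2x2([[20, 10], [10, 20]], yates=False)
        assert stat == pytest.approx(20 / 3, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(20 / 3, df=1), rel=1e-9)

    def test_closed_form_equivalence(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, 4)
            n = a + b + c + d
            closed = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            stat, _ = chi_square_2x2([[a, b], [c, d]], yates=False)
            assert stat == pytest.approx(closed, abs=1e-12, rel=1e-12)

    def test_row_and_column_swap_symmetry(self):
        stat0, _ = chi_square_2x2([[20, 10], [10, 20]])
        stat1, _ = chi_square_2x2([[10, 20], [20, 10]])
        stat2, _ = chi_square_2x2([[10, 20], [20, 10]][::-1])
        assert stat0 == pytest.approx(stat1) == pytest.approx(stat2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestBinEnrichment:
    def test_identical_frequencies_give_zero(self):
        r = pd.Series([10, 20, 30], index=list("abc"))
        out = bin_enrichment_ranks(r, r.copy(), pseudocount=0.5)
        assert np.allclose(out["log2_enrichment"], 0.0, atol=1e-12)

    def test_doubled_frequency_is_one(self):
        # p0's bin frequency is exactly double its input frequency
        # (0.2 vs 0.1) at counts large enough to swamp the pseudocount
        ids = [f"p{i}" for i in range(10)]
        base = pd.Series([100_000] * 10, index=ids)
        bin_reads = pd.Series([200_000] + [800_000 // 9] * 9, index=ids)
        out = bin_enrichment_ranks(bin_reads, base, pseudocount=0.5).set_index(
            "peptide_id"
        )
        assert out.loc["p0", "log2_enrichment"] == pytest.approx(1.0, abs=0.01)

    def test_zero_count_matches_formula_oracle(self):
        rb = pd.Series([0, 100], index=["z", "x"])
        ri = pd.Series([50, 50], index=["z", "x"])
        pc = 0.5
        out = bin_enrichment_ranks(rb, ri, pseudocount=pc).set_index("peptide_id")
        expect = math.log2(
            ((0 + pc) / (100 + pc * 2)) / ((50 + pc) / (100 + pc * 2))
        )
        assert out.loc["z", "log2_enrichment"] == pytest.approx(expect, rel=1e-12)

    def test_descending_order_with_id_tiebreak(self, rng):
        rb = pd.Series(rng.integers(0, 100, 30), index=[f"p{i:02d}" for i in range(30)])
        ri = pd.Series(rng.integers(1, 100, 30), index=rb.index)
        out = bin_enrichment_ranks(rb, ri)
        vals = out["log2_enrichment"].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_enrichment_ranks(pd.Series(dtype=float), pd.Series(dtype=float))


def brute_force_es(ranked, gene_set):
    """Oracle: evaluate the full running sum position by position."""
    n, g = len(ranked), len(gene_set)
    run, best = 0.0, 0.0
    for x in ranked:
        run += 1 / g if x in gene_set else -1 / (n - g)
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaUnweighted:
    def test_top_block_gives_plus_one(self):
        ids = [f"x{i}" for i in range(100)]
        res = gsea_unweighted(ids, set(ids[:10]), n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)
        assert set(res.leading_edge) == set(ids[:10])

    def test_bottom_block_gives_minus_one(self):
        ids = [f"x{i}" for i in range(100)]
        res = gsea_unweighted(ids, set(ids[-10:]), n_perm=50, seed=0)
        assert res.es == pytest.approx(-1.0)

    def test_matches_running_sum_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 120))
            ids = [f"x{i}" for i in range(n)]
            g = int(rng.integers(2, n // 2))
            gene_set = set(rng.choice(ids, size=g, replace=False))
            res = gsea_unweighted(ids, gene_set, n_perm=10, seed=0)
            assert res.es == pytest.approx(brute_force_es(ids, gene_set), rel=1e-12)

    def test_antisymmetric_under_reversal(self, rng):
        ids = [f"x{i}" for i in range(80)]
        gene_set = set(rng.choice(ids, size=15, replace=False))
        es_fwd = gsea_unweighted(ids, gene_set, n_perm=10, seed=0).es
        es_rev = gsea_unweighted(ids[::-1], gene_set, n_perm=10, seed=0).es
        assert es_rev == pytest.approx(-es_fwd, rel=1e-9)

    def test_null_p_values_roughly_uniform(self, rng):
        # random sets against a fixed ranking: p should be calibrated
        ids = [f"x{i}" for i in range(1000)]
        pvals = []
        for _ in range(200):
            gene_set = set(rng.choice(ids, size=100, replace=False))
            pvals.append(
                gsea_unweighted(
                    ids, gene_set, n_perm=2000, seed=int(rng.integers(2**31))
                ).p_value
            )
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_set_must_be_strict_subset(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError):
            gsea_unweighted(ids, set(ids), n_perm=10)
        with pytest.raises(ValueError):
            gsea_unweighted(ids, {"zz"}, n_perm=10)
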