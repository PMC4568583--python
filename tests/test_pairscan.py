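import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from epichi.gwas_io import GwasMatrix
from epichi.pairscan import (
    ContingencyTable,
    PairResult,
    ScanConfig,
    build_contingency,
    chi8_test,
    count_eligible_pairs,
    encode_pair,
    extract_significant,
    filter_univariate_insignificant,
    scan_all_pairs,
    scan_pairs_arrays,
    univariate_pvalues,
    univariate_test,
)

from conftest import pearson_oracle


class TestEncoding:
    @pytest.mark.parametrize("x,y,code", [(0, 0, 0), (2, 2, 8), (1, 2, 7)])
    def test_examples(self, x, y, code):
        assert encode_pair(x, y) == code

    def test_bijective_on_genotype_pairs(self):
        codes = {encode_pair(x, y) for x, y in itertools.product(range(3), repeat=2)}
        assert codes == set(range(9))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            encode_pair(3, 0)
        with pytest.raises(ValueError):
            encode_pair(0, -1)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=4, max_size=40),
           st.integers(1, 3))
    def test_role_swap_leaves_statistic_unchanged(self, pairs, n_cases):
        # swapping x and y permutes the 9 table columns; Pearson chi-square
        # is invariant under column permutation
        if n_cases >= len(pairs):
            n_cases = len(pairs) - 1
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        t_xy = build_contingency(x, y, n_cases)
        t_yx = build_contingency(y, x, n_cases)
        assert chi8_test(t_xy).statistic == pytest.approx(chi8_test(t_yx).statistic, rel=1e-12)


class TestContingency:
    def test_spec_forced_example(self):
        table = build_contingency(
            np.array([0, 1, 2, 0]), np.array([0, 0, 1, 2]), n_cases=2, pseudocount=1
        )
        assert table.counts[0].tolist() == [2, 2, 1, 1, 1, 1, 1, 1, 1]
        assert table.counts[1].tolist() == [1, 1, 1, 1, 1, 2, 2, 1, 1]
        assert table.counts.sum() == 4 + 18

    def test_zero_pseudocount_is_raw_histogram(self):
        table = build_contingency(np.array([0, 0]), np.array([0, 0]), n_cases=1, pseudocount=0)
        assert table.counts[0, 0] == 1 and table.counts[1, 0] == 1
        assert table.counts.sum() == 2

    def test_column_sums_bounded_below_by_pseudocounts(self, rng):
        x = rng.integers(0, 3, size=30)
        y = rng.integers(0, 3, size=30)
        table = build_contingency(x, y, n_cases=15, pseudocount=2)
        assert np.all(table.counts.sum(axis=0) >= 4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_contingency(np.zeros(3, dtype=int), np.zeros(4, dtype=int), n_cases=1)


class TestChi8Test:
    def test_identical_rows_give_null(self):
        counts = np.tile(np.arange(1, 10), (2, 1))
        result = chi8_test(ContingencyTable(counts=counts, pseudocount=1))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == 1.0
        assert result.df == 8

    def test_separated_classes_match_oracle(self):
        # 10 cases at code 0, 10 controls at code 8, plus pseudocounts
        counts = np.ones((2, 9), dtype=int)
        counts[0, 0] += 10
        counts[1, 8] += 10
        result = chi8_test(ContingencyTable(counts=counts, pseudocount=1))
        assert result.statistic == pytest.approx(pearson_oracle(counts), rel=1e-12)

    def test_doubling_counts_doubles_statistic(self, rng):
        counts = rng.integers(1, 20, size=(2, 9))
        s1 = chi8_test(ContingencyTable(counts=counts, pseudocount=1)).statistic
        s2 = chi8_test(ContingencyTable(counts=2 * counts, pseudocount=1)).statistic
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_zero_marginal_without_pseudocount_errors(self):
        counts = np.zeros((2, 9), dtype=int)
        counts[0, 0] = counts[1, 0] = 5
        with pytest.raises(ValueError):
            chi8_test(ContingencyTable(counts=counts, pseudocount=0))


class TestUnivariateTest:
    def test_identical_distribution_is_null(self):
        snp = np.array([0, 1, 2, 0, 1, 2])
        result = univariate_test(snp, n_cases=3)
        assert result.p_value == 1.0
        assert result.df == 2

    def test_full_separation_matches_oracle(self):
        snp = np.concatenate([np.zeros(8, dtype=int), np.full(8, 2)])
        result = univariate_test(snp, n_cases=8, pseudocount=1)
        counts = np.ones((2, 3), dtype=int)
        counts[0, 0] += 8
        counts[1, 2] += 8
        assert result.statistic == pytest.approx(pearson_oracle(counts), rel=1e-12)

    def test_p_decreases_with_separation(self):
        # move controls from genotype 0 to genotype 2, one subject at a time
        previous = 1.1
        for k in range(0, 9):
            snp = np.concatenate([np.zeros(8, dtype=int), np.full(k, 2), np.zeros(8 - k, dtype=int)])
            p = univariate_test(snp, n_cases=8).p_value
            assert p < previous
            previous = p

    def test_vectorized_pvalues_match_scalar(self, small_gwas):
        vec = univariate_pvalues(small_gwas)
        for c in range(small_gwas.n_snps):
            scalar = univariate_test(small_gwas.genotypes[:, c], small_gwas.n_cases)
            assert vec[c] == pytest.approx(scalar.p_value, rel=1e-12)


class TestScan:
    def test_pair_enumeration_ldwidth_zero(self, rng):
        G = rng.integers(0, 3, size=(8, 5)).astype(np.int8)
        results = list(scan_all_pairs(GwasMatrix(G, 4), ScanConfig(ldwidth=0)))
        assert len(results) == 10
        assert [(r.i, r.j) for r in results] == [
            (i, j) for i in range(5) for j in range(i + 1, 5)
        ]

    def test_pair_enumeration_ldwidth_two(self, rng):
        G = rng.integers(0, 3, size=(8, 5)).astype(np.int8)
        results = list(scan_all_pairs(GwasMatrix(G, 4), ScanConfig(ldwidth=2)))
        assert [(r.i, r.j) for r in results] == [(0, 3), (0, 4), (1, 4)]

    def test_no_eligible_pairs_errors(self, rng):
        G = rng.integers(0, 3, size=(8, 5)).astype(np.int8)
        with pytest.raises(ValueError, match="no eligible pairs"):
            list(scan_all_pairs(GwasMatrix(G, 4), ScanConfig(ldwidth=4)))

    def test_count_eligible_pairs(self):
        assert count_eligible_pairs(5, 0) == 10
        assert count_eligible_pairs(5, 2) == 3
        assert count_eligible_pairs(1000, 0) == 499500

    @pytest.mark.parametrize("ldwidth", [0, 1, 3])
    def test_matches_naive_double_loop(self, rng, ldwidth):
        # independent oracle: rebuild each table from scratch, test with scipy
        G = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
        gwas = GwasMatrix(G, 15)
        results = list(scan_all_pairs(gwas, ScanConfig(ldwidth=ldwidth)))
        expected = []
        for i in range(12):
            for j in range(i + 1, 12):
                if j - i > ldwidth:
                    table = build_contingency(G[:, i], G[:, j], 15, 1)
                    stat, p, df, _ = chi2_contingency(table.counts, correction=False)
                    assert df == 8
                    expected.append((i, j, stat, p))
        assert len(results) == len(expected)
        for r, (i, j, stat, p) in zip(results, expected):
            assert (r.i, r.j) == (i, j)
            assert r.statistic == pytest.approx(stat, rel=1e-10)
            assert r.p_value == pytest.approx(p, rel=1e-10)


class TestExtraction:
    def _pairs(self, pvals):
        return [PairResult(k, k + 1, 1.0, p) for k, p in enumerate(pvals)]

    def test_nothing_below_threshold(self):
        assert extract_significant(self._pairs([0.5, 0.9]), 1e-7) == []

    def test_sorted_ascending(self):
        out = extract_significant(self._pairs([1e-9, 1e-12, 0.2]), 1e-7)
        assert [r.p_value for r in out] == [1e-12, 1e-9]

    def test_strict_inequality_at_threshold(self):
        assert extract_significant(self._pairs([1e-7]), 1e-7) == []

    def test_ties_broken_by_indices(self):
        pairs = [PairResult(3, 4, 1.0, 1e-9), PairResult(0, 2, 1.0, 1e-9)]
        out = extract_significant(pairs, 1e-3)
        assert [(r.i, r.j) for r in out] == [(0, 2), (3, 4)]

    def test_equivalent_to_one_pass_filter(self, rng):
        pvals = rng.random(1000)
        pairs = self._pairs(pvals)
        tau = 0.3
        out = extract_significant(pairs, tau)
        assert {(r.i, r.j) for r in out} == {(p.i, p.j) for p in pairs if p.p_value < tau}

    def test_monotone_in_threshold(self, rng):
        pairs = self._pairs(rng.random(200))
        tight = {(r.i, r.j) for r in extract_significant(pairs, 0.05)}
        loose = {(r.i, r.j) for r in extract_significant(pairs, 0.2)}
        assert tight <= loose


class TestUnivariateFilter:
    def test_both_insignificant_kept(self):
        pair = PairResult(0, 1, 5.0, 1e-9)
        assert filter_univariate_insignificant([pair], {0: 0.3, 1: 0.7}, 5e-5) == [pair]

    def test_one_significant_dropped(self):
        pair = PairResult(0, 1, 5.0, 1e-9)
        assert filter_univariate_insignificant([pair], {0: 1e-9, 1: 0.7}, 5e-5) == []

    def test_zero_threshold_keeps_everything(self):
        pair = PairResult(0, 1, 5.0, 1e-9)
        assert filter_univariate_insignificant([pair], {0: 1e-300, 1: 1e-300}, 0.0) == [pair]

    def test_missing_pvalue_errors(self):
        pair = PairResult(0, 7, 5.0, 1e-9)
        with pytest.raises(ValueError, match="index 7"):
            filter_univariate_insignificant([pair], {0: 0.3}, 5e-5)


class TestNullCalibration:
    def test_pvalues_roughly_uniform_under_null(self, rng):
        # pairs within one dataset share SNPs, so pool several independent
        # null datasets to suppress the dependence noise of the KS statistic
        from scipy.stats import kstest

        pooled = []
        for _ in range(6):
            G = rng.integers(0, 3, size=(800, 100)).astype(np.int8)
            gwas = GwasMatrix(G, 400)
            pooled.append(scan_pairs_arrays(gwas, ScanConfig(ldwidth=0))[3])
        assert kstest(np.concatenate(pooled), "uniform").statistic < 0.05
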