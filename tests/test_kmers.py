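import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from readbias import (
    BiasSpec,
    ReferenceSequence,
    background_from_reads,
    background_from_reference,
    binomial_log10_pvalue,
    count_basecalls,
    count_kmers_by_position,
    generate_genome,
    generate_reads,
    log_factorial,
    position_trend_fit,
    stirling_log_factorial,
    test_positional_kmers as positional_kmer_tests,
)
from tests._oracles import exact_binomial_log10_tail, exact_log_factorial
from tests.conftest import make_read


class TestPositionalCounting:
    def test_single_read_windows(self):
        t = count_kmers_by_position([make_read("ACGT")], 2)
        assert t.count(1, "AC") == 1
        assert t.count(2, "CG") == 1
        assert t.count(3, "GT") == 1
        assert t.counts.sum() == 3

    def test_n_windows_are_skipped(self):
        t = count_kmers_by_position([make_read("ANGT")], 2)
        assert t.skipped.tolist() == [1, 1, 0]
        assert t.count(3, "GT") == 1

    def test_k1_reproduces_basecall_counts(self):
        reads = [make_read(s) for s in ["ACGT", "AANT", "GG"]]
        t = count_kmers_by_position(reads, 1)
        m = count_basecalls(reads)
        assert np.array_equal(t.counts, m.counts[:, :4])
        assert np.array_equal(t.skipped, m.counts[:, 4])

    def test_k_larger_than_all_reads_rejected(self):
        with pytest.raises(ValueError):
            count_kmers_by_position([make_read("ACG")], 5)

    @given(
        st.lists(
            st.text(alphabet="ACGTN", min_size=3, max_size=10), min_size=1, max_size=25
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_window_conservation_invariant(self, seqs):
        t = count_kmers_by_position([make_read(s) for s in seqs], 3)
        assert np.array_equal(t.counts.sum(axis=1) + t.skipped, t.n_windows)


class TestBackgroundModels:
    def test_reference_single_strand(self):
        bg = background_from_reference(ReferenceSequence("r", "AAAT"), 2, both_strands=False)
        assert bg.probability("AA") == pytest.approx(2 / 3)
        assert bg.probability("AT") == pytest.approx(1 / 3)

    def test_reference_both_strands_hand_enumeration(self):
        # forward windows AA,AA,AT; revcomp "ATTT" windows AT,TT,TT
        bg = background_from_reference(ReferenceSequence("r", "AAAT"), 2, both_strands=True)
        assert bg.n_sites == 6
        assert bg.probability("AA") == pytest.approx(2 / 6)
        assert bg.probability("TT") == pytest.approx(2 / 6)
        assert bg.probability("AT") == pytest.approx(2 / 6)

    def test_all_n_reference_rejected(self):
        with pytest.raises(ValueError, match="no valid windows"):
            background_from_reference(ReferenceSequence("r", "NNNN"), 2)

    def test_probabilities_sum_to_one(self, reference_background_k3):
        assert reference_background_k3.prob.sum() == pytest.approx(1.0, abs=1e-9)

    def test_read_pool_background(self):
        t = count_kmers_by_position([make_read("ACGT")], 2)
        bg = background_from_reads(t)
        for w in ("AC", "CG", "GT"):
            assert bg.probability(w) == pytest.approx(1 / 3)

    def test_pooled_background_approximates_reference(
        self, unbiased_table_k3, reference_background_k3
    ):
        pooled = background_from_reads(unbiased_table_k3)
        tv = 0.5 * np.abs(pooled.prob - reference_background_k3.prob).sum()
        assert tv < 0.01


class TestStirling:
    @pytest.mark.parametrize("n", [10, 100, 1_000, 10_000, 100_000, 1_000_000])
    def test_log_factorial_within_series_bound(self, n):
        assert abs(stirling_log_factorial(n) - exact_log_factorial(n)) < 1.0 / (12 * n)

    def test_exact_below_cutover(self):
        for n in range(0, 21):
            assert log_factorial(n) == pytest.approx(exact_log_factorial(n), abs=1e-12)


class TestBinomialPvalue:
    def test_all_successes_closed_form(self):
        lp, direction = binomial_log10_pvalue(10, 10, 0.5)
        assert direction == "over"
        assert lp == pytest.approx(10 * math.log10(0.5), rel=1e-9)

    def test_degenerate_p_zero(self):
        assert binomial_log10_pvalue(0, 1000, 0.0)[0] == 0.0

    def test_degenerate_p_one(self):
        assert binomial_log10_pvalue(50, 50, 1.0)[0] == 0.0

    def test_observed_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_log10_pvalue(11, 10, 0.5)

    def test_large_n_rare_kmer_against_oracle(self):
        lp, direction = binomial_log10_pvalue(200, 10**6, 1e-4)
        oracle = exact_binomial_log10_tail(200, 10**6, 1e-4, "over")
        assert direction == "over"
        assert abs(lp - oracle) <= 1e-3 * abs(oracle)

    def test_central_observation_not_extreme(self):
        n, p = 1000, 0.3
        lp, _ = binomial_log10_pvalue(int(n * p), n, p)
        assert lp > -1.0

    def test_monotone_in_deviation(self):
        n, p = 500, 0.2
        mean = n * p
        lps = {}
        for obs in range(0, n + 1):
            lp, _ = binomial_log10_pvalue(obs, n, p)
            lps[obs] = lp
        over = [lps[o] for o in range(int(mean) + 1, n + 1)]
        under = [lps[o] for o in range(int(mean), -1, -1)]
        assert all(a >= b - 1e-12 for a, b in zip(over, over[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(under, under[1:]))

    @pytest.mark.parametrize("p", [0.5, 0.1, 4.0**-6])
    @pytest.mark.parametrize("n", [10, 100, 1_000, 10_000])
    def test_relative_log_contract_on_grid(self, n, p):
        for obs in {int(round(n * f / 10)) for f in range(11)}:
            lp, direction = binomial_log10_pvalue(obs, n, p)
            oracle = exact_binomial_log10_tail(obs, n, p, direction)
            assert abs(lp - oracle) <= 1e-3 * max(abs(oracle), 1e-6), (n, p, obs)


class TestPositionalTest:
    def test_planted_start_motif_is_flagged(self, genome_100k):
        reads = generate_reads(
            genome_100k, 50_000, 36, BiasSpec(start_motif=("ACGTAC", 0.05)), seed=21
        )
        table = count_kmers_by_position(reads, 6)
        bg = background_from_reference(genome_100k, 6, both_strands=True)
        results = positional_kmer_tests(table, bg, positions="start")
        hit = next(r for r in results if r.kmer == "ACGTAC")
        assert hit.direction == "over"
        assert hit.log10_pvalue < -6

    def test_mismatched_k_rejected(self, unbiased_table_k3, genome_100k):
        bg = background_from_reference(genome_100k, 2)
        with pytest.raises(ValueError):
            positional_kmer_tests(unbiased_table_k3, bg)

    def test_null_fixture_bonferroni_calibration(
        self, unbiased_table_k3, reference_background_k3
    ):
        results = positional_kmer_tests(
            unbiased_table_k3, reference_background_k3, positions="all"
        )
        n_tests = len(results)
        flagged = sum(1 for r in results if r.bonferroni_log10 <= math.log10(0.01))
        assert flagged / n_tests <= 0.01 + 3 * math.sqrt(0.01 / n_tests)

    def test_expected_equals_n_times_p(self, unbiased_table_k3, reference_background_k3):
        results = positional_kmer_tests(
            unbiased_table_k3, reference_background_k3, positions=[5]
        )
        n = int(unbiased_table_k3.n_windows[4] - unbiased_table_k3.skipped[4])
        for r in results[:10]:
            assert r.expected == pytest.approx(
                n * max(reference_background_k3.probability(r.kmer), 1e-12)
            )


class TestTrendFit:
    def test_exact_cubic_recovered(self):
        t = count_kmers_by_position([make_read("A")], 1)  # shape donor
        x = np.arange(1, 21)
        t.counts = np.zeros((20, 4), dtype=np.int64)
        t.counts[:, 0] = 2 * x**3 - x + 5
        fit = position_trend_fit(t, "A", degree=3)
        assert fit.r2 == pytest.approx(1.0)
        assert not fit.degenerate

    def test_constant_counts_degenerate(self):
        t = count_kmers_by_position([make_read("A")], 1)
        t.counts = np.full((10, 4), 7, dtype=np.int64)
        fit = position_trend_fit(t, "A", degree=1)
        assert fit.degenerate
        assert fit.r2 == 0.0
        assert fit.pvalue == 1.0

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(8)
        n = 40
        x = np.arange(1, n + 1, dtype=float)
        y = np.round(10 * x + rng.normal(0, 5, n)).astype(np.int64)
        t = count_kmers_by_position([make_read("A")], 1)
        t.counts = np.zeros((n, 4), dtype=np.int64)
        t.counts[:, 0] = y
        fit = position_trend_fit(t, "A", degree=1)
        ols = sm.OLS(y.astype(float), sm.add_constant(x)).fit()
        assert fit.r2 == pytest.approx(ols.rsquared, abs=1e-9)
        assert fit.pvalue == pytest.approx(ols.f_pvalue, abs=1e-9)

    def test_unbiased_fixture_consistent_with_position_independence(
        self, unbiased_table_k3
    ):
        pvals = [
            position_trend_fit(unbiased_table_k3, kmer, degree=3).pvalue
            for kmer in ("".join(c) for c in __import__("itertools").product("ACGT", repeat=3))
        ]
        # the 1% nominal false-positive rate gets the same 3-sigma binomial
        # slack as the positional-test calibration check
        frac_quiet = sum(p > 0.01 for p in pvals) / len(pvals)
        assert frac_quiet >= 0.99 - 3 * math.sqrt(0.01 * 0.99 / len(pvals))
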