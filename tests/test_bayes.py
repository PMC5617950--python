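"""Naive Bayes posterior computation and predictor-set selection."""

import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reportminer import (
    BayesConfig,
    score_all_terms,
    select_predictors,
    smoothed_likelihood,
    term_posterior,
)
from reportminer.stats import CohortTermTable, TermScore


def _table(df_mut, df_wt, n_mut, n_wt, stem="t"):
    return CohortTermTable(
        n_mut=n_mut, n_wt=n_wt,
        df_mut={(stem, False): df_mut}, df_wt={(stem, False): df_wt},
    )


class TestSmoothedLikelihood:
    def test_formula(self):
        assert smoothed_likelihood(0, 10, alpha=1) == pytest.approx(1 / 12)
        assert smoothed_likelihood(5, 10, alpha=0) == 0.5

    def test_zero_count_without_smoothing_is_error(self):
        with pytest.raises(ValueError, match="smoothing"):
            smoothed_likelihood(0, 10, alpha=0)
        with pytest.raises(ValueError, match="smoothing"):
            smoothed_likelihood(10, 10, alpha=0)

    @given(st.integers(0, 50), st.integers(1, 50))
    def test_strictly_interior_with_smoothing(self, df, n):
        df = min(df, n)
        assert 0 < smoothed_likelihood(df, n, alpha=1) < 1


class TestTermPosterior:
    def test_symmetric_case_returns_prior(self):
        assert term_posterior(0.2, 0.2, 0.5) == pytest.approx(0.5)
        assert term_posterior(0.2, 0.2, 0.9) == pytest.approx(0.9)

    def test_hand_value(self):
        # (0.30 * 0.5) / (0.30 * 0.5 + 0.10 * 0.5) = 0.15 / 0.20
        assert term_posterior(0.30, 0.10, 0.5) == pytest.approx(0.75)

    def test_rejects_boundary_arguments(self):
        with pytest.raises(ValueError):
            term_posterior(0.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            term_posterior(0.5, 0.5, 1.0)


class TestScoreAllTerms:
    def test_balanced_equal_df_gives_half(self):
        scores = score_all_terms(_table(30, 30, 100, 100))
        assert scores[0].p_mut == pytest.approx(0.5)

    def test_mutant_only_term_bounded_by_smoothing(self):
        scores = score_all_terms(_table(40, 0, 100, 100))
        assert 0.5 < scores[0].p_mut < 1.0

    def test_composition_oracle(self):
        """Full scoring equals an independent re-composition of likelihoods
        and Bayes' rule on a random 20-term table."""
        rng = random.Random(23)
        n_mut, n_wt = 80, 120
        df_mut = {(f"t{i}", False): rng.randint(0, n_mut) for i in range(20)}
        df_wt = {(f"t{i}", False): rng.randint(1, n_wt) for i in range(20)}
        table = CohortTermTable(n_mut=n_mut, n_wt=n_wt, df_mut=df_mut, df_wt=df_wt)
        config = BayesConfig(prior_mode="empirical", alpha=1.0)
        scores = {s.stem: s for s in score_all_terms(table, config)}
        prior = n_mut / (n_mut + n_wt)
        for i in range(20):
            key = (f"t{i}", False)
            lm = (df_mut[key] + 1) / (n_mut + 2)
            lw = (df_wt[key] + 1) / (n_wt + 2)
            expected = lm * prior / (lm * prior + lw * (1 - prior))
            assert scores[f"t{i}"].p_mut == pytest.approx(expected, abs=1e-14)

    def test_normalization(self):
        rng = random.Random(5)
        table = CohortTermTable(
            n_mut=50, n_wt=70,
            df_mut={(f"t{i}", False): rng.randint(0, 50) for i in range(40)},
            df_wt={(f"t{i}", False): rng.randint(1, 70) for i in range(40)},
        )
        for s in score_all_terms(table):
            assert abs(s.p_mut + s.p_wt - 1.0) < 1e-12

    @given(st.integers(1, 60))
    def test_monotone_in_df_mut(self, n_mut):
        previous = -1.0
        for df in range(n_mut + 1):
            p = score_all_terms(_table(df, 10, n_mut, 40))[0].p_mut
            assert p >= previous
            previous = p

    def test_balanced_empirical_reduces_to_smoothed_frequency_ratio(self):
        table = _table(30, 12, 100, 100)
        p = score_all_terms(table)[0].p_mut
        fm, fw = 31 / 102, 13 / 102
        assert p == pytest.approx(fm / (fm + fw), abs=1e-14)


def _ts(stem, p_mut, df=10):
    return TermScore(
        stem=stem, negated=False, display=stem, df_mut=df, df_wt=df,
        f_mut=0.1, f_wt=0.1, pct_diff=1.0, p_mut=p_mut, p_wt=1 - p_mut,
    )


class TestSelectPredictors:
    def test_strict_threshold(self):
        scores = [_ts("at", 0.5), _ts("above", 0.63), _ts("below", 0.4)]
        mut, wt = select_predictors(scores, k_mut=5, k_wt=5)
        assert [t.stem for t in mut.terms] == ["above"]
        assert [t.stem for t in wt.terms] == ["below"]  # p_wt = 0.6 > 0.5

    def test_k_limits_set_size(self):
        scores = [_ts(f"t{i}", 0.55 + 0.01 * i) for i in range(8)]
        mut, wt = select_predictors(scores, k_mut=3, k_wt=3)
        assert len(mut) == 3 and len(wt) == 0
        assert [t.stem for t in mut.terms] == ["t7", "t6", "t5"]

    def test_sets_smaller_than_k_without_padding(self):
        scores = [_ts("only", 0.9)]
        mut, wt = select_predictors(scores, k_mut=6, k_wt=4)
        assert len(mut) == 1 and len(wt) == 0

    def test_ranking_equals_distance_from_half(self):
        """|p_mut − p_wt| = |2·p_mut − 1|, so ranking by absolute posterior
        difference matches ranking by distance from 0.5 (brute comparator)."""
        rng = np.random.default_rng(31)
        scores = [_ts(f"t{i:02d}", float(p)) for i, p in enumerate(rng.uniform(0.51, 0.99, 30))]
        mut, _ = select_predictors(scores, k_mut=30, k_wt=0)
        oracle = sorted(
            scores, key=lambda s: (-abs(2 * s.p_mut - 1), -(s.df_mut + s.df_wt), s.stem)
        )
        assert list(mut.terms) == oracle
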