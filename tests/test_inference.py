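"""Wilcoxon signed-rank exactness and predictor-group evaluation."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from reportminer import (
    MUTANT,
    evaluate_predictor_group,
    select_predictors,
    wilcoxon_signed_rank,
)
from reportminer.stats import TermScore


def enumeration_p(d, alternative):
    """Independent oracle: walk all 2^n sign assignments of the rank sum."""
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_plus - 1e-9
        le += w <= w_plus + 1e-9
    total = 2**n
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0 and r.n_used == 0

    def test_all_positive_ranks_one_sided(self):
        r = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0], "greater")
        assert r.p_value == pytest.approx(1 / 32, abs=1e-15)
        assert r.method == "exact" and r.statistic == 0.0

    def test_singleton_pair(self):
        r = wilcoxon_signed_rank([0.75], [0.25], "greater")
        assert r.n_used == 1 and r.p_value == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_exact_matches_enumeration(self, alternative):
        rng = np.random.default_rng(101)
        for n in range(1, 9):
            for _ in range(5):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                r = wilcoxon_signed_rank(x, y, alternative)
                assert r.method == "exact"
                assert r.p_value == pytest.approx(
                    enumeration_p(x - y, alternative), abs=1e-12
                )

    def test_exact_handles_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        r = wilcoxon_signed_rank(x, y, "greater")
        assert r.p_value == pytest.approx(enumeration_p(x - y, "greater"), abs=1e-12)

    @pytest.mark.parametrize("alt,scipy_alt", [
        ("two_sided", "two-sided"), ("greater", "greater"), ("less", "less"),
    ])
    def test_against_reference_implementation(self, alt, scipy_alt):
        """Dual route: tie-free exact p equals scipy's exact method."""
        rng = np.random.default_rng(7)
        for n in (4, 9, 15, 22):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            ours = wilcoxon_signed_rank(x, y, alt)
            ref = scipy_wilcoxon(x, y, alternative=scipy_alt, method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_beyond_cutoff(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0.2, 1.0, 40)
        y = rng.normal(0.0, 1.0, 40)
        ours = wilcoxon_signed_rank(x, y)
        assert ours.method == "normal_approx"
        ref = scipy_wilcoxon(x, y, correction=True, method="approx")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        # and close to the exact computation scipy can still do at n=40
        exact = scipy_wilcoxon(x, y, method="exact")
        assert ours.p_value == pytest.approx(exact.pvalue, abs=0.02)

    def test_exact_p_values_on_dyadic_grid(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = wilcoxon_signed_rank(x, y, "greater")
            assert (r.p_value * 2**r.n_used) == pytest.approx(
                round(r.p_value * 2**r.n_used), abs=1e-9
            )

    def test_shift_invariance(self):
        rng = np.random.default_rng(29)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = wilcoxon_signed_rank(x, y)
        shifted = wilcoxon_signed_rank(x + 5.0, y + 5.0)
        assert shifted.p_value == base.p_value
        assert shifted.statistic == base.statistic


def _ts(stem, p_mut):
    return TermScore(
        stem=stem, negated=False, display=stem, df_mut=10, df_wt=10,
        f_mut=0.1, f_wt=0.1, pct_diff=1.0, p_mut=p_mut, p_wt=1 - p_mut,
    )


class TestGroupEvaluation:
    def test_constant_differences(self):
        scores = [_ts(f"t{i}", 0.6) for i in range(5)]
        mut, _ = select_predictors(scores, k_mut=5, k_wt=0)
        ev = evaluate_predictor_group(mut, alternative="greater")
        assert ev.mean_own == pytest.approx(0.6)
        assert ev.mean_other == pytest.approx(0.4)
        # constant positive differences: p = (1/2)^n one-sided
        assert ev.result.p_value == pytest.approx(0.5**5)

    def test_singleton_set(self):
        mut, _ = select_predictors([_ts("only", 0.75)], k_mut=1, k_wt=0)
        ev = evaluate_predictor_group(mut, alternative="greater")
        assert ev.result.n_used == 1
        assert ev.result.p_value == pytest.approx(0.5)

    def test_own_mean_dominates(self):
        scores = [_ts(f"t{i}", p) for i, p in enumerate([0.55, 0.6, 0.72, 0.66])]
        mut, _ = select_predictors(scores, k_mut=4, k_wt=0)
        ev = evaluate_predictor_group(mut)
        assert ev.label == MUTANT
        assert ev.mean_own > ev.mean_other

    def test_empty_set_is_error(self):
        _, wt = select_predictors([_ts("t", 0.9)], k_mut=1, k_wt=4)
        with pytest.raises(ValueError):
            evaluate_predictor_group(wt)
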