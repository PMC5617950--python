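"""Wilcoxon signed-rank test and predictor-group evaluation.

The signed-rank test here follows the classic convention: zero differences
are dropped, absolute differences are ranked with midranks for ties, and
the reported statistic is min(W+, W−). For n ≤ 25 retained pairs the null
distribution of W+ is computed exactly by convolving the rank contributions
over all 2^n equiprobable sign assignments (midranks are doubled so the
convolution runs on integers); beyond that a normal approximation with tie
correction and a 0.5 continuity correction is used.

A predictor set is evaluated by pairing, per term, the posterior for the
set's own cohort with the posterior for the other cohort and testing the
paired differences. Because the two posteriors of a term are complementary,
all differences in a well-formed set share one sign, so the exact p-value
is driven by the set size — the test certifies the construction rather
than adding independent evidence, and is reported alongside the group
means for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .bayes import PredictorSet
from .corpus import MUTANT

EXACT_CUTOFF = 25

Alternative = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class WilcoxonResult:
    n_used: int
    statistic: float  # min(W+, W−) over the retained pairs
    p_value: float
    method: Literal["exact", "normal_approx"]
    alternative: Alternative


@dataclass(frozen=True)
class GroupEvaluation:
    label: str
    mean_own: float
    mean_other: float
    result: WilcoxonResult


def _exact_sf_cdf(doubled_ranks: np.ndarray, doubled_w: int) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) under the exact null, on doubled ranks."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted  # each pair keeps sign + or −: add rank r or 0
    n = len(doubled_ranks)
    denom = 2.0 ** n
    sf = counts[doubled_w:].sum() / denom
    cdf = counts[: doubled_w + 1].sum() / denom
    return sf, cdf


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two_sided",
) -> WilcoxonResult:
    """Paired signed-rank test of x against y.

    ``alternative="greater"`` tests for x tending to exceed y. All-zero
    differences give p = 1 with n_used = 0 (no evidence either way).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size == 0:
        raise ValueError("need at least one pair")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0, 0.0, 1.0, "exact", alternative)

    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if n <= EXACT_CUTOFF:
        doubled = np.rint(2 * ranks).astype(np.int64)
        dw = int(round(2 * w_plus))
        sf, cdf = _exact_sf_cdf(doubled, dw)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
        return WilcoxonResult(n, statistic, float(p), "exact", alternative)

    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts).sum())
    ) / 48.0
    sigma = float(np.sqrt(sigma2))
    dev = w_plus - mu
    if alternative == "greater":
        p = float(norm.sf((dev - 0.5) / sigma))
    elif alternative == "less":
        p = float(norm.cdf((dev + 0.5) / sigma))
    else:
        cc = 0.5 if dev > 0 else (-0.5 if dev < 0 else 0.0)
        z = (dev - cc) / sigma
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(n, statistic, p, "normal_approx", alternative)


def evaluate_predictor_group(
    predictor_set: PredictorSet,
    alternative: Alternative = "two_sided",
) -> GroupEvaluation:
    """Test whether a predictor set's own-cohort posteriors exceed the
    other-cohort posteriors across its terms, and summarize the means."""
    if len(predictor_set) == 0:
        raise ValueError("cannot evaluate an empty predictor set")
    own_is_mut = predictor_set.cohort == MUTANT
    own = [t.p_mut if own_is_mut else t.p_wt for t in predictor_set.terms]
    other = [t.p_wt if own_is_mut else t.p_mut for t in predictor_set.terms]
    result = wilcoxon_signed_rank(own, other, alternative=alternative)
    return GroupEvaluation(
        label=predictor_set.cohort,
        mean_own=float(np.mean(own)),
        mean_other=float(np.mean(other)),
        result=result,
    )
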