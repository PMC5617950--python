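"""Per-term naive Bayes posteriors and predictor-set selection.

For a term W and cohorts S (MUTANT) and H (WILDTYPE), the posterior that a
report containing W comes from the MUTANT cohort is

    P(S|W) = P(W|S)·P(S) / (P(W|S)·P(S) + P(W|H)·P(H))

with the per-cohort likelihoods P(W|·) estimated as add-α smoothed document
frequencies (df + α)/(N + 2α). Smoothing guards the zero-frequency case:
with α = 0 a term absent from one cohort gives a degenerate 0/1 posterior
and a term absent from both leaves the ratio undefined. Priors are either
empirical (cohort report shares) or a fixed value, the spam-filter
convention of P(S) = 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .corpus import MUTANT, WILDTYPE
from .stats import CohortTermTable, TermScore, percent_difference, report_frequency


@dataclass(frozen=True)
class BayesConfig:
    """Prior mode and smoothing pseudo-count for posterior computation."""

    prior_mode: Literal["empirical", "fixed"] = "empirical"
    fixed_prior_mut: float = 0.5
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.prior_mode not in ("empirical", "fixed"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if self.prior_mode == "fixed" and not 0 < self.fixed_prior_mut < 1:
            raise ValueError("fixed prior must lie strictly inside (0, 1)")
        if self.alpha < 0:
            raise ValueError("smoothing pseudo-count must be >= 0")

    def prior(self, n_mut: int, n_wt: int) -> float:
        if self.prior_mode == "fixed":
            return self.fixed_prior_mut
        return n_mut / (n_mut + n_wt)


@dataclass(frozen=True)
class PredictorSet:
    """The terms whose posterior for one cohort exceeds the threshold,
    ranked by absolute posterior difference (equivalently, distance of
    p_mut from 1/2, since the posteriors are complementary)."""

    cohort: str
    threshold: float
    terms: tuple[TermScore, ...]

    def __post_init__(self) -> None:
        for t in self.terms:
            own = t.p_mut if self.cohort == MUTANT else t.p_wt
            if not own > self.threshold:
                raise ValueError(
                    f"term {t.display!r} has posterior {own} <= threshold "
                    f"{self.threshold} for cohort {self.cohort}"
                )

    def __len__(self) -> int:
        return len(self.terms)


def smoothed_likelihood(df: int, n: int, alpha: float = 1.0) -> float:
    """Add-α estimate of P(term present | cohort): (df + α)/(N + 2α)."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= df <= n:
        raise ValueError(f"document frequency {df} outside [0, {n}]")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0 and df in (0, n):
        raise ValueError("zero likelihood requires smoothing (alpha > 0)")
    return (df + alpha) / (n + 2 * alpha)


def term_posterior(lik_mut: float, lik_wt: float, prior_mut: float) -> float:
    """Bayes' rule for the two-cohort case; the WILDTYPE posterior is the
    complement of the returned value."""
    for name, v in (("lik_mut", lik_mut), ("lik_wt", lik_wt), ("prior_mut", prior_mut)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {v}")
    joint_mut = lik_mut * prior_mut
    joint_wt = lik_wt * (1.0 - prior_mut)
    return joint_mut / (joint_mut + joint_wt)


def score_all_terms(
    table: CohortTermTable, config: BayesConfig | None = None
) -> list[TermScore]:
    """Score every table term: unsmoothed frequencies and percent difference
    for reporting, smoothed-likelihood posteriors for classification."""
    if config is None:
        config = BayesConfig()
    prior = config.prior(table.n_mut, table.n_wt)
    scores: list[TermScore] = []
    for key in table.terms:
        df_mut, df_wt = table.get(key)
        f_mut = report_frequency(df_mut, table.n_mut)
        f_wt = report_frequency(df_wt, table.n_wt)
        p_mut = term_posterior(
            smoothed_likelihood(df_mut, table.n_mut, config.alpha),
            smoothed_likelihood(df_wt, table.n_wt, config.alpha),
            prior,
        )
        scores.append(
            TermScore(
                stem=key[0],
                negated=key[1],
                display=table.display(key),
                df_mut=df_mut,
                df_wt=df_wt,
                f_mut=f_mut,
                f_wt=f_wt,
                pct_diff=percent_difference(f_mut, f_wt),
                p_mut=p_mut,
                p_wt=1.0 - p_mut,
            )
        )
    return scores


def select_predictors(
    scores: Iterable[TermScore],
    k_mut: int = 6,
    k_wt: int = 4,
    threshold: float = 0.5,
) -> tuple[PredictorSet, PredictorSet]:
    """Pick the top-k most cohort-discriminating terms for each cohort.

    A term qualifies for a cohort only if its posterior for that cohort
    *strictly* exceeds the threshold (a term sitting exactly at the
    threshold joins neither set); qualifying terms are ranked by
    ``|p_mut − p_wt|`` descending, ties broken toward higher total document
    frequency then lexicographic stem. Sets may come back smaller than k.
    """
    if k_mut < 0 or k_wt < 0:
        raise ValueError("set sizes must be >= 0")
    scores = list(scores)

    def top(own_of, k: int) -> tuple[TermScore, ...]:
        qualifying = [s for s in scores if own_of(s) > threshold]
        qualifying.sort(
            key=lambda s: (
                -s.abs_posterior_diff, -(s.df_mut + s.df_wt), s.stem, s.negated,
            )
        )
        return tuple(qualifying[:k])

    return (
        PredictorSet(MUTANT, threshold, top(lambda s: s.p_mut, k_mut)),
        PredictorSet(WILDTYPE, threshold, top(lambda s: s.p_wt, k_wt)),
    )
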