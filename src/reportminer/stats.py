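"""Per-cohort document-frequency tables and frequency statistics.

The central object is the ``CohortTermTable``: for every term, the number
of MUTANT reports and the number of WILDTYPE reports whose distinct-term
set contains it, together with the cohort report totals. Report frequency
is the unsmoothed ratio df/N (smoothing enters only in Bayes scoring, so
reported frequencies stay exact ratios of counts).

"Percent difference" between two cohort frequencies is the symmetric
mean-relative form 100·|a−b|/mean(a,b) by default; a max-relative variant
(100·|a−b|/max(a,b)) is available for sensitivity analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .corpus import MUTANT, WILDTYPE
from .text import Term

PctDiffMode = Literal["mean_relative", "max_relative"]


@dataclass
class CohortTermTable:
    """Document frequencies per term for both cohorts.

    ``df_mut``/``df_wt`` map ``(stem, negated)`` keys to counts; ``surfaces``
    maps the same keys to a Counter of raw surface forms, used to render a
    canonical display string (the most frequent surface, ties broken
    lexicographically).
    """

    n_mut: int
    n_wt: int
    df_mut: dict[tuple[str, bool], int] = field(default_factory=dict)
    df_wt: dict[tuple[str, bool], int] = field(default_factory=dict)
    surfaces: dict[tuple[str, bool], Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_mut <= 0 or self.n_wt <= 0:
            raise ValueError(
                f"both cohorts must be non-empty (N_mut={self.n_mut}, N_wt={self.n_wt})"
            )

    @property
    def terms(self) -> list[tuple[str, bool]]:
        keys = set(self.df_mut) | set(self.df_wt)
        return sorted(keys, key=lambda k: (k[0], k[1]))

    def display(self, key: tuple[str, bool]) -> str:
        """Canonical surface form: most frequent, then lexicographically first."""
        counter = self.surfaces.get(key)
        surface = (
            min(counter, key=lambda s: (-counter[s], s)) if counter else key[0]
        )
        return Term.render(surface, key[1])

    def get(self, key: tuple[str, bool]) -> tuple[int, int]:
        return self.df_mut.get(key, 0), self.df_wt.get(key, 0)


@dataclass(frozen=True)
class TermScore:
    """Frequencies, percent difference and Bayes posteriors for one term."""

    stem: str
    negated: bool
    display: str
    df_mut: int
    df_wt: int
    f_mut: float
    f_wt: float
    pct_diff: float
    p_mut: float
    p_wt: float

    @property
    def abs_posterior_diff(self) -> float:
        return abs(self.p_mut - self.p_wt)


def build_term_table(
    processed: Iterable[tuple[str, set[Term]]]
) -> CohortTermTable:
    """Count, per cohort, how many reports' term sets contain each term.

    ``processed`` yields ``(cohort, term_set)`` pairs, one per report; every
    report must have been processed with the same negation config. Raises if
    either cohort is empty (frequencies would be undefined).
    """
    df_mut: dict[tuple[str, bool], int] = {}
    df_wt: dict[tuple[str, bool], int] = {}
    surfaces: dict[tuple[str, bool], Counter] = {}
    n_mut = n_wt = 0
    for cohort, term_set in processed:
        if cohort == MUTANT:
            n_mut += 1
            target = df_mut
        elif cohort == WILDTYPE:
            n_wt += 1
            target = df_wt
        else:
            raise ValueError(f"unknown cohort label {cohort!r}")
        for term in term_set:
            key = (term.stem, term.negated)
            target[key] = target.get(key, 0) + 1
            surfaces.setdefault(key, Counter())[term.surface or term.stem] += 1
    return CohortTermTable(
        n_mut=n_mut, n_wt=n_wt, df_mut=df_mut, df_wt=df_wt, surfaces=surfaces
    )


def report_frequency(df: int, n: int) -> float:
    """Fraction of a cohort's reports containing the term: df/N exactly."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= df <= n:
        raise ValueError(f"document frequency {df} outside [0, {n}]")
    return df / n


def percent_difference(
    f_a: float, f_b: float, mode: PctDiffMode = "mean_relative"
) -> float:
    """Symmetric percent difference between two frequencies, in [0, 200].

    ``mean_relative`` (default): 100·|a−b| / ((a+b)/2).
    ``max_relative``: 100·|a−b| / max(a, b).
    Undefined (hard error) when both frequencies are zero.
    """
    if not (0 <= f_a <= 1 and 0 <= f_b <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if f_a == 0 and f_b == 0:
        raise ValueError("percent difference undefined when both frequencies are 0")
    if mode == "mean_relative":
        denom = (f_a + f_b) / 2
    elif mode == "max_relative":
        denom = max(f_a, f_b)
    else:
        raise ValueError(f"unknown percent-difference mode {mode!r}")
    return 100.0 * abs(f_a - f_b) / denom


def rank_terms(
    scores: Iterable[TermScore],
    min_df: int = 5,
    metric: Literal["pct_diff", "abs_posterior_diff"] = "pct_diff",
) -> list[TermScore]:
    """Rank scored terms by the chosen divergence metric, descending.

    Terms with total document frequency below ``min_df`` are dropped
    (one-off typo suppression). Ties break toward higher total document
    frequency, then lexicographic stem.
    """
    if min_df < 0:
        raise ValueError("min_df must be >= 0")
    eligible = [s for s in scores if s.df_mut + s.df_wt >= min_df]
    keyfuncs = {
        "pct_diff": lambda s: s.pct_diff,
        "abs_posterior_diff": lambda s: s.abs_posterior_diff,
    }
    try:
        metric_of = keyfuncs[metric]
    except KeyError:
        raise ValueError(f"unknown ranking metric {metric!r}") from None
    return sorted(
        eligible,
        key=lambda s: (-metric_of(s), -(s.df_mut + s.df_wt), s.stem, s.negated),
    )


def scores_to_frame(scores: Iterable[TermScore]) -> pd.DataFrame:
    """Tabular export with the standard column set."""
    rows = [
        {
            "term_display": s.display,
            "stem": s.stem,
            "negated": s.negated,
            "df_mut": s.df_mut,
            "df_wt": s.df_wt,
            "f_mut": s.f_mut,
            "f_wt": s.f_wt,
            "pct_diff": s.pct_diff,
            "p_mut": s.p_mut,
            "p_wt": s.p_wt,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term_display", "stem", "negated", "df_mut", "df_wt",
            "f_mut", "f_wt", "pct_diff", "p_mut", "p_wt",
        ],
    )


def table_to_frame(table: CohortTermTable) -> pd.DataFrame:
    """Raw count table export: one row per term with df and N columns."""
    rows = []
    for key in table.terms:
        df_mut, df_wt = table.get(key)
        rows.append(
            {
                "term_display": table.display(key),
                "stem": key[0],
                "negated": key[1],
                "df_mut": df_mut,
                "df_wt": df_wt,
                "N_mut": table.n_mut,
                "N_wt": table.n_wt,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["term_display", "stem", "negated", "df_mut", "df_wt", "N_mut", "N_wt"],
    )
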