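"""Two-cohort synthetic report corpora with planted marker terms.

The institutional report corpora this kind of analysis runs on are not
publicly available, so validation uses generated corpora whose true
per-term posteriors are known analytically. Each report independently
includes each *marker* word with its cohort's inclusion probability
(a Bernoulli per report — presence/absence is all that matters to
document-frequency counting); markers flagged as negated-context are
embedded as "no <word>." phrases so negation tagging is exercised.
Background noise words are pronounceable nonsense strings (consonant–vowel
syllables) drawn uniformly from a fixed vocabulary; their construction
guarantees they stem to themselves and cannot collide with marker stems.

For a marker with inclusion probabilities (q_mut, q_wt) and cohort prior
ρ = n_mut/(n_mut + n_wt), the analytic posterior that a report containing
the marker is from the MUTANT cohort is q_mut·ρ / (q_mut·ρ + q_wt·(1−ρ)) —
the population image of the per-term Bayes posterior the pipeline
estimates from counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, MUTANT, Report, WILDTYPE
from .stemming import stem

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


@dataclass(frozen=True)
class MarkerSpec:
    """One planted discriminative word and its per-cohort inclusion rates."""

    word: str
    q_mut: float
    q_wt: float
    negated_context: bool = False

    def __post_init__(self) -> None:
        if not self.word.isalpha() or self.word != self.word.lower():
            raise ValueError(f"marker word must be lowercase alphabetic: {self.word!r}")
        for name, q in (("q_mut", self.q_mut), ("q_wt", self.q_wt)):
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {q}")

    @property
    def term_key(self) -> tuple[str, bool]:
        """The (stem, negated) key under which the pipeline will count this marker."""
        return stem(self.word), self.negated_context


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of a synthetic two-cohort corpus.

    Defaults follow the validation scenario used throughout the test
    suite: two cohorts of 2,000 reports, two MUTANT-enriched markers, one
    WILDTYPE-enriched negated marker, and 500 background noise words at a
    mean of 20 per report.
    """

    n_mut: int = 2000
    n_wt: int = 2000
    markers: tuple[MarkerSpec, ...] = (
        MarkerSpec("innumerable", q_mut=0.30, q_wt=0.10),
        MarkerSpec("confluent", q_mut=0.25, q_wt=0.12),
        MarkerSpec("discrete", q_mut=0.10, q_wt=0.30, negated_context=True),
    )
    background_vocab_size: int = 500
    background_words_per_report: float = 20.0
    sentence_templates: tuple[str, ...] = ("{words}.",)
    words_per_sentence: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mut <= 0 or self.n_wt <= 0:
            raise ValueError("cohort sizes n_mut and n_wt must be positive")
        if not self.markers:
            raise ValueError("at least one marker is required")
        if self.background_vocab_size < 1:
            raise ValueError("background_vocab_size must be positive")
        if self.background_words_per_report <= 0:
            raise ValueError("background_words_per_report must be positive")
        if any("{words}" not in t for t in self.sentence_templates):
            raise ValueError("every sentence template needs a {words} slot")

    @property
    def prior_mut(self) -> float:
        return self.n_mut / (self.n_mut + self.n_wt)


@dataclass(frozen=True)
class GroundTruth:
    """Per-marker generative rates and analytic posteriors."""

    prior_mut: float
    markers: tuple[MarkerSpec, ...]
    posteriors: dict[tuple[str, bool], float] = field(hash=False)

    def to_dict(self) -> dict:
        return {
            "prior_mut": self.prior_mut,
            "markers": [
                {
                    "word": m.word,
                    "negated_context": m.negated_context,
                    "q_mut": m.q_mut,
                    "q_wt": m.q_wt,
                    "stem": m.term_key[0],
                    "analytic_posterior_mut": self.posteriors[m.term_key],
                }
                for m in self.markers
            ],
        }


def analytic_posterior(q_mut: float, q_wt: float, rho: float) -> float:
    """Population Bayes posterior for a marker with the given inclusion rates."""
    if not 0 < rho < 1:
        raise ValueError("prior must lie strictly inside (0, 1)")
    if q_mut == 0 and q_wt == 0:
        raise ValueError("posterior undefined when both inclusion rates are 0")
    joint_mut = q_mut * rho
    return joint_mut / (joint_mut + q_wt * (1.0 - rho))


def background_vocabulary(size: int) -> list[str]:
    """Deterministic nonsense vocabulary: three consonant–vowel syllables.

    Words are fixed points of the stemmer (they end in vowels and carry no
    strippable suffix), so background terms never merge with each other or
    with marker stems.
    """
    if size > len(_SYLLABLES) ** 3:
        raise ValueError(f"background_vocab_size must be <= {len(_SYLLABLES)**3}")
    words = []
    n = len(_SYLLABLES)
    for i in range(size):
        a, rem = divmod(i, n * n)
        b, c = divmod(rem, n)
        words.append(_SYLLABLES[a] + _SYLLABLES[b] + _SYLLABLES[c])
    return words


def _render_report(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    vocab: list[str],
    marker_included: np.ndarray,
) -> str:
    sentences: list[str] = []
    for marker, included in zip(spec.markers, marker_included):
        if included:
            if marker.negated_context:
                sentences.append(f"no {marker.word}.")
            else:
                sentences.append(f"{marker.word}.")
    n_bg = max(1, int(rng.poisson(spec.background_words_per_report)))
    bg = rng.choice(len(vocab), size=n_bg, replace=True)
    for start in range(0, n_bg, spec.words_per_sentence):
        chunk = " ".join(vocab[j] for j in bg[start : start + spec.words_per_sentence])
        template = spec.sentence_templates[
            int(rng.integers(len(spec.sentence_templates)))
        ]
        sentences.append(template.format(words=chunk))
    return " ".join(sentences)


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a labelled corpus and its analytic ground truth.

    Fully reproducible: one pseudo-random stream (numpy PCG64) seeded from
    ``spec.seed``, cohort order fixed (all MUTANT then all WILDTYPE).
    """
    vocab = background_vocabulary(spec.background_vocab_size)
    marker_stems = {m.term_key[0] for m in spec.markers}
    collisions = marker_stems & set(vocab)
    if collisions:
        raise ValueError(f"marker stems collide with background vocabulary: {collisions}")

    rng = np.random.default_rng(spec.seed)
    reports: list[Report] = []
    for cohort, count, tag in ((MUTANT, spec.n_mut, "M"), (WILDTYPE, spec.n_wt, "W")):
        qs = np.array(
            [m.q_mut if cohort == MUTANT else m.q_wt for m in spec.markers]
        )
        for i in range(count):
            included = rng.random(len(spec.markers)) < qs
            text = _render_report(rng, spec, vocab, included)
            reports.append(
                Report(
                    report_id=f"{tag}{i:06d}",
                    patient_id=f"P{tag}{i:06d}",
                    cohort=cohort,
                    text=text,
                )
            )

    posteriors = {
        m.term_key: analytic_posterior(m.q_mut, m.q_wt, spec.prior_mut)
        for m in spec.markers
    }
    truth = GroundTruth(
        prior_mut=spec.prior_mut, markers=spec.markers, posteriors=posteriors
    )
    return Corpus(tuple(reports)), truth
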