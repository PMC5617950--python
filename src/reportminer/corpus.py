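"""Loading, validation and filtering of labelled radiology-report corpora.

A corpus is a manifest table (``report_id``, ``patient_id``, ``cohort``)
plus one plain-text file per report, named ``<report_id>.txt``. Cohort
labels are ``MUTANT`` (e.g. KRAS-mutated patients) and ``WILDTYPE``.
Reports — not patients — are the counting unit downstream; patient ids are
kept only to verify that no patient appears in both cohorts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

logger = logging.getLogger(__name__)

MUTANT = "MUTANT"
WILDTYPE = "WILDTYPE"
COHORTS = (MUTANT, WILDTYPE)


class CorpusError(ValueError):
    """Raised on malformed manifests or inconsistent corpora."""


@dataclass(frozen=True)
class Report:
    """One labelled free-text document, the unit of document-frequency counting."""

    report_id: str
    patient_id: str
    cohort: str
    text: str

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise CorpusError(
                f"unknown cohort label {self.cohort!r} for report "
                f"{self.report_id!r} (expected one of {COHORTS})"
            )


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of reports with per-cohort totals."""

    reports: tuple[Report, ...]

    def __post_init__(self) -> None:
        ids = Counter(r.report_id for r in self.reports)
        dupes = [i for i, c in ids.items() if c > 1]
        if dupes:
            raise CorpusError(f"duplicate report_id: {sorted(dupes)!r}")
        patient_cohorts: dict[str, str] = {}
        for r in self.reports:
            prev = patient_cohorts.setdefault(r.patient_id, r.cohort)
            if prev != r.cohort:
                raise CorpusError(
                    f"patient {r.patient_id!r} appears in both cohorts"
                )

    @property
    def n_mut(self) -> int:
        return sum(1 for r in self.reports if r.cohort == MUTANT)

    @property
    def n_wt(self) -> int:
        return sum(1 for r in self.reports if r.cohort == WILDTYPE)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)


@dataclass(frozen=True)
class ExclusionRules:
    """Case-insensitive substring patterns and a minimum-length guard.

    A report is excluded if its text contains any pattern (administrative
    documents such as billing statements) or is shorter than
    ``min_length`` characters (placeholder/empty documents).
    """

    patterns: tuple[str, ...] = ("billing", "charges", "scheduling")
    min_length: int = 50

    def __post_init__(self) -> None:
        if any(not p for p in self.patterns):
            raise CorpusError("exclusion patterns must be non-empty strings")
        if self.min_length < 0:
            raise CorpusError("min_length must be non-negative")


def load_manifest(manifest_path: Path | str) -> pd.DataFrame:
    """Read a manifest table, sniffing tab vs comma from the header line."""
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(manifest_path, sep=sep, dtype=str)
    required = {"report_id", "patient_id", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_corpus(manifest_path: Path | str, reports_dir: Path | str) -> Corpus:
    """Load every manifest row and its text file into a validated ``Corpus``.

    Text is decoded as UTF-8 with replacement of undecodable bytes. A
    missing text file, an unknown cohort label or a duplicated report id is
    a hard error naming the offending report.
    """
    reports_dir = Path(reports_dir)
    df = load_manifest(manifest_path)
    reports = []
    for row in df.itertuples(index=False):
        path = reports_dir / f"{row.report_id}.txt"
        if not path.is_file():
            raise CorpusError(
                f"report file missing for report_id {row.report_id!r}: {path}"
            )
        text = path.read_text(encoding="utf-8", errors="replace")
        reports.append(
            Report(
                report_id=str(row.report_id),
                patient_id=str(row.patient_id),
                cohort=str(row.cohort),
                text=text,
            )
        )
    corpus = Corpus(tuple(reports))
    logger.info(
        "loaded corpus: %d reports (%d MUTANT, %d WILDTYPE)",
        len(corpus), corpus.n_mut, corpus.n_wt,
    )
    return corpus


def filter_reports(
    corpus: Corpus, rules: ExclusionRules
) -> tuple[Corpus, dict[str, int]]:
    """Drop administrative and degenerate reports.

    Returns the filtered corpus together with an exclusion log mapping each
    pattern (and the pseudo-pattern ``<min_length>``) to the number of
    reports it removed. A report matching several patterns is charged to
    the first matching one. Filtering is idempotent.
    """
    lowered = [p.lower() for p in rules.patterns]
    kept = []
    excluded: dict[str, int] = {p: 0 for p in rules.patterns}
    excluded["<min_length>"] = 0
    for report in corpus:
        text_lc = report.text.lower()
        hit = next(
            (orig for orig, pat in zip(rules.patterns, lowered) if pat in text_lc),
            None,
        )
        if hit is not None:
            excluded[hit] += 1
        elif len(report.text) < rules.min_length:
            excluded["<min_length>"] += 1
        else:
            kept.append(report)
    for pattern, n in excluded.items():
        if n:
            logger.info("excluded %d reports matching %r", n, pattern)
    return Corpus(tuple(kept)), excluded


def write_manifest(corpus: Corpus, manifest_path: Path | str, sep: str = "\t") -> None:
    """Write the corpus manifest back in tabular form (text files untouched)."""
    df = pd.DataFrame(
        {
            "report_id": [r.report_id for r in corpus],
            "patient_id": [r.patient_id for r in corpus],
            "cohort": [r.cohort for r in corpus],
        }
    )
    df.to_csv(manifest_path, sep=sep, index=False)


def write_corpus(corpus: Corpus, manifest_path: Path | str, reports_dir: Path | str) -> None:
    """Serialize a corpus as manifest + one UTF-8 text file per report."""
    reports_dir = Path(reports_dir)
    reports_dir.mkdir(parents=True, exist_ok=True)
    for report in corpus:
        (reports_dir / f"{report.report_id}.txt").write_text(
            report.text, encoding="utf-8"
        )
    write_manifest(corpus, manifest_path)
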