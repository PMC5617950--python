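"""Shared fixtures: a tiny hand-checkable corpus on disk and small synthetic specs."""

from __future__ import annotations

import pytest

from reportminer import MarkerSpec, SyntheticSpec

# Four reports: three clinical (two MUTANT, one WILDTYPE) plus one billing
# document that the default exclusion patterns must remove. The expected
# term table for the three clinical reports is derived by hand in
# tests/test_pipeline.py.
TINY_REPORTS = {
    "R1": ("P1", "MUTANT", "Innumerable hepatic lesions. No discrete mass."),
    "R2": ("P2", "MUTANT", "Numerous lesions again seen; no abnormal enhancement."),
    "R3": ("P3", "WILDTYPE",
           "Few scattered lesions. No discrete nodule but discrete calcification."),
    "R4": ("P4", "MUTANT", "STATEMENT OF CHARGES - billing code 1234"),
}


@pytest.fixture
def tiny_corpus_dir(tmp_path):
    """Write the tiny corpus as manifest + text files; returns (manifest, reports_dir)."""
    reports_dir = tmp_path / "reports"
    reports_dir.mkdir()
    lines = ["report_id\tpatient_id\tcohort"]
    for rid, (pid, cohort, text) in TINY_REPORTS.items():
        (reports_dir / f"{rid}.txt").write_text(text, encoding="utf-8")
        lines.append(f"{rid}\t{pid}\t{cohort}")
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest, reports_dir


@pytest.fixture
def small_spec():
    """A fast synthetic spec (50 reports) for counting-oracle style tests."""
    return SyntheticSpec(
        n_mut=25,
        n_wt=25,
        markers=(
            MarkerSpec("innumerable", q_mut=0.6, q_wt=0.2),
            MarkerSpec("discrete", q_mut=0.2, q_wt=0.6, negated_context=True),
        ),
        background_vocab_size=60,
        background_words_per_report=8.0,
        seed=11,
    )
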