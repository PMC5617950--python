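"""Run configuration: one YAML/JSON file driving the whole pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .bayes import BayesConfig
from .corpus import ExclusionRules
from .inference import Alternative
from .synthetic import MarkerSpec, SyntheticSpec
from .text import NegationConfig


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, with the package defaults filled in."""

    manifest: Path | None = None
    reports_dir: Path | None = None
    out_dir: Path = Path("reportminer_out")
    exclusion: ExclusionRules = field(default_factory=ExclusionRules)
    negation: NegationConfig = field(default_factory=NegationConfig)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    min_df: int = 5
    ranking_metric: str = "abs_posterior_diff"
    k_mut: int = 6
    k_wt: int = 4
    threshold: float = 0.5
    alternative: Alternative = "two_sided"
    synthetic: SyntheticSpec | None = None
    seed: int | None = None

    def echo(self) -> dict:
        """JSON-serializable snapshot of the effective configuration."""
        d = asdict(self)
        for key in ("manifest", "reports_dir", "out_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def _sub(section: dict, cls, **renames):
    kwargs = {renames.get(k, k): v for k, v in section.items()}
    for key in ("patterns", "cues", "terminators", "sentence_templates"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: Path | str) -> RunConfig:
    """Parse a YAML (or JSON — a YAML subset) config file into a RunConfig."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    kwargs: dict = {}
    paths = raw.get("paths", {})
    if "manifest" in paths:
        kwargs["manifest"] = Path(paths["manifest"])
    if "reports_dir" in paths:
        kwargs["reports_dir"] = Path(paths["reports_dir"])
    if "out_dir" in paths:
        kwargs["out_dir"] = Path(paths["out_dir"])
    if "exclusion" in raw:
        kwargs["exclusion"] = _sub(raw["exclusion"], ExclusionRules)
    if "negation" in raw:
        kwargs["negation"] = _sub(raw["negation"], NegationConfig)
    if "bayes" in raw:
        kwargs["bayes"] = _sub(raw["bayes"], BayesConfig)
    for key in ("min_df", "ranking_metric", "k_mut", "k_wt", "threshold",
                "alternative", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "synthetic" in raw:
        section = dict(raw["synthetic"])
        markers = tuple(
            MarkerSpec(**m) for m in section.pop("markers", [])
        )
        if markers:
            section["markers"] = markers
        kwargs["synthetic"] = _sub(section, SyntheticSpec)
    return RunConfig(**kwargs)


def with_seed(config: RunConfig, seed: int | None) -> RunConfig:
    """Override the run seed (propagated into the synthetic spec, if any)."""
    if seed is None:
        return config
    synthetic = (
        replace(config.synthetic, seed=seed) if config.synthetic is not None else None
    )
    return replace(config, seed=seed, synthetic=synthetic)


def dump_config(config: RunConfig, path: Path | str) -> None:
    Path(path).write_text(
        json.dumps(config.echo(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
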