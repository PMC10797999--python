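"""YAML configuration for factors, replication and thresholds."""

from __future__ import annotations

from pathlib import Path

import yaml

from .design import Factor
from .screen import ClassifierThresholds

__all__ = ["load_factors", "dump_factors", "load_thresholds"]


def load_factors(path: str | Path) -> tuple[list[Factor], dict]:
    """Read factor definitions plus replication settings from YAML.

    Returns (factors, settings) where settings carries central_reps,
    outer_reps, bio_reps and seed if present.
    """
    doc = yaml.safe_load(Path(path).read_text())
    factors = [Factor(**entry) for entry in doc["factors"]]
    settings = {k: doc[k] for k in ("central_reps", "outer_reps", "bio_reps", "seed") if k in doc}
    return factors, settings


def dump_factors(factors: list[Factor], path: str | Path, **settings) -> None:
    doc = {
        "factors": [
            {k: v for k, v in vars(f).items() if v not in (None, "")}
            for f in factors
        ],
        **settings,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_thresholds(path: str | Path) -> ClassifierThresholds:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return ClassifierThresholds(**doc)
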