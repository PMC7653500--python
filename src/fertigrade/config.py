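"""Structured run configuration (YAML) for the command-line interface.

All randomness flows from a single ``seed`` fanned out per stage.  Every
field is optional; omitted fields fall back to the pipeline defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from .cohort import CleaningRule, default_cleaning_rules
from .errors import FertigradeError
from .system import BuildConfig


def _rules_from_config(entries: Mapping) -> list[CleaningRule]:
    rules = []
    for name, body in entries.items():
        rules.append(
            CleaningRule(
                indicator=name,
                minimum=float(body["min"]),
                maximum=float(body["max"]),
                action=body.get("action", "drop-record"),
                imputation=body.get("imputation", "mean"),
            )
        )
    return rules


def build_config_from_dict(doc: Mapping) -> BuildConfig:
    doc = dict(doc or {})
    kwargs: dict = {}
    if "cleaning_rules" in doc:
        kwargs["cleaning_rules"] = _rules_from_config(doc["cleaning_rules"])
    else:
        kwargs["cleaning_rules"] = default_cleaning_rules()
    for key in (
        "candidates",
        "forced",
        "alpha",
        "orientations",
        "max_intervals",
        "n_trees",
        "train_fraction",
        "rf_on_points",
        "n_grades",
        "seed",
        "allow_empty_intervals",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    try:
        return BuildConfig(**kwargs)
    except TypeError as exc:
        raise FertigradeError(f"bad config: {exc}") from exc


def load_run_config(path: str | Path | None) -> BuildConfig:
    """Load a YAML run config; ``None`` gives all defaults."""
    if path is None:
        return BuildConfig()
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if doc is None:
        return BuildConfig()
    if not isinstance(doc, Mapping):
        raise FertigradeError(f"{path}: config must be a mapping")
    return build_config_from_dict(doc)
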