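"""Configuration: column maps, vocabulary maps, synonym and drug-class tables.

All per-source column layouts and keyword maps have sensible defaults (the
public exports' layouts vary by version) and can be overridden through a
single YAML file with top-level keys ``columns`` (per source), ``disease_synonyms``
and ``drug_classes``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("mtbreport.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh) or {}


def default_disease_synonyms() -> dict[str, str]:
    """The shipped cancer-type synonym table (raw label -> canonical)."""
    return _load_packaged_yaml("disease_synonyms.yaml")


def default_drug_classes() -> dict[str, str]:
    """The shipped drug -> drug-class display table (lower-case keys)."""
    return {k.lower(): v for k, v in _load_packaged_yaml("drug_classes.yaml").items()}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a user YAML config, merged over the packaged defaults."""
    config: dict[str, Any] = {
        "columns": {},
        "disease_synonyms": default_disease_synonyms(),
        "drug_classes": default_drug_classes(),
    }
    if path is None:
        return config
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if "columns" in user:
        config["columns"].update(user["columns"])
    if "disease_synonyms" in user:
        config["disease_synonyms"].update(user["disease_synonyms"])
    if "drug_classes" in user:
        config["drug_classes"].update(
            {k.lower(): v for k, v in user["drug_classes"].items()}
        )
    return config
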