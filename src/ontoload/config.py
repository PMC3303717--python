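"""Runtime configuration."""
from __future__ import annotations

import os
from dataclasses import dataclass, field, fields
from typing import Optional

import yaml

from .errors import OntoloadError
from .rules import DEFAULT_INTRON_DONOR_TERMS


@dataclass
class Config:
    db_url: str = "ontoload.db"
    ontology_path: Optional[str] = None  # None -> bundled mini ontology fragment
    cache_dir: str = ".ontoload_cache"
    ledger_path: str = "jobs.ledger.json"
    workers: int = 2
    checkpoint_interval: int = 10
    intron_donor_terms: list[str] = field(
        default_factory=lambda: list(DEFAULT_INTRON_DONOR_TERMS)
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise OntoloadError("workers must be >= 1")
        if self.ontology_path is not None:
            self.ontology_path = os.path.abspath(self.ontology_path)

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise OntoloadError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
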