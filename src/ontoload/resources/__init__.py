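"""Bundled configuration tables (feature-key mapping, qualifier routing).

Both tables are data, not code: editing them re-routes the ETL without
touching any rule logic.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ir

__all__ = ["feature_key_table", "qualifier_routing_table"]


def _read_tsv(name: str) -> list[list[str]]:
    text = _ir.files(__package__).joinpath(name).read_text(encoding="utf-8")
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


@lru_cache(maxsize=None)
def feature_key_table() -> dict[str, tuple[str, str]]:
    """feature key -> (SO accession, SO term name)."""
    return {k: (acc, name) for k, acc, name in _read_tsv("feature_keys.tsv")}


@lru_cache(maxsize=None)
def qualifier_routing_table() -> dict[str, tuple[str, str]]:
    """qualifier name -> (route, target column or '-')."""
    return {q: (route, target) for q, route, target in _read_tsv("qualifier_routing.tsv")}
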