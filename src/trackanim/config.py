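"""Persistent key-value configuration: remembered header mappings per data
file, custom datetime formats, discarded columns, and saved legend layouts.

The store is a single YAML file so users can edit it by hand. A data file is
identified by its *source key* — file name plus a SHA-256 of the content —
so a renamed copy of the same CSV still resolves to its remembered mapping.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ConfigStore", "source_key"]


def source_key(path: str | Path) -> str:
    """File identity used to remember per-file settings: name + content hash."""
    path = Path(path)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return f"{path.name}:{digest}"


class ConfigStore:
    """YAML-backed settings store; writes through on every mutation."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._data: dict[str, Any] = {"header_mappings": {}, "legend_layouts": {}}
        if self.path.exists():
            loaded = yaml.safe_load(self.path.read_text()) or {}
            self._data.update(loaded)

    def _save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(yaml.safe_dump(self._data, sort_keys=True))

    # -- header mappings --------------------------------------------------

    def get_header_mapping(self, key: str) -> dict[str, Any] | None:
        return self._data["header_mappings"].get(key)

    def store_header_mapping(self, key: str, mapping: dict[str, Any]) -> None:
        self._data["header_mappings"][key] = mapping
        self._save()

    # -- legend layouts ---------------------------------------------------

    def get_legend_layout(self, name: str) -> dict[str, Any] | None:
        return self._data["legend_layouts"].get(name)

    def store_legend_layout(self, name: str, layout: dict[str, Any]) -> None:
        self._data["legend_layouts"][name] = layout
        self._save()
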