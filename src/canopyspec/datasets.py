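"""Accessors for the packaged reference tables (published partitions,
SPA band lists and performance metrics of the original greenhouse study)."""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_published_partitions", "load_published_metrics"]


def _load(name: str) -> dict:
    ref = resources.files("canopyspec.data").joinpath(name)
    return json.loads(ref.read_text())


def load_published_partitions() -> dict:
    """Per-experiment cal/val/test counts and SPA-selected wavelengths."""
    return _load("published_partitions.json")["experiments"]


def load_published_metrics() -> list[dict]:
    """Published per-model performance rows (accuracy %, P/R/F1/AUC)."""
    return _load("published_metrics.json")["rows"]
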