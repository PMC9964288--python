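"""Packaged reference tables and lexicon files.

The CSVs under ``waterscape/data`` mirror the published per-park tables
(indicator values, sentiment counts, thermal means, behavior records, and the
coupling tables) plus the published spatial level assignment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table", "load_terms", "load_sense_lexicon", "TABLES"]

TABLES = (
    "table3",
    "table4",
    "table5",
    "table7",
    "table8",
    "table9",
    "table10",
    "table11",
    "table12",
    "spatial_levels",
)


def _data_path(name: str):
    return resources.files("waterscape").joinpath("data", name)


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged reference table by short name (e.g. ``"table3"``)."""
    if name not in TABLES:
        raise KeyError(f"unknown table {name!r}; available: {TABLES}")
    with resources.as_file(_data_path(f"{name}.csv")) as path:
        return pd.read_csv(path)


def load_terms(filename: str) -> list[str]:
    """Load a plain-text term list (one term per line, '#' comments)."""
    text = _data_path(filename).read_text(encoding="utf-8")
    return [t.strip().lower() for t in text.splitlines() if t.strip() and not t.startswith("#")]


def load_sense_lexicon() -> dict[str, set[str]]:
    with resources.as_file(_data_path("sense_lexicon.csv")) as path:
        df = pd.read_csv(path)
    out: dict[str, set[str]] = {}
    for sense, term in zip(df["sense"], df["term"]):
        out.setdefault(sense, set()).add(str(term).lower())
    return out
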