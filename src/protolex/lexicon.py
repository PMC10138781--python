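"""Frequency-lexicon I/O: TSV with (form, freq_per_million, raw_count)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

COLUMNS = ["form", "freq_per_million", "raw_count"]


def read_lexicon(path: str | Path) -> pd.DataFrame:
    lex = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = set(COLUMNS) - set(lex.columns)
    if missing:
        raise ValueError(f"lexicon missing columns: {sorted(missing)}")
    if (lex["freq_per_million"] < 0).any():
        raise ValueError("negative frequencies in lexicon")
    return lex[COLUMNS]


def write_lexicon(lex: pd.DataFrame, path: str | Path) -> None:
    lex[COLUMNS].to_csv(path, sep="\t", index=False, encoding="utf-8")
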