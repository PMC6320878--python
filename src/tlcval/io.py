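"""Schema-checked CSV round trips for experiment tables.

All tables are UTF-8, comma-separated, dot-decimal CSV with a header row.
Loading validates the required columns and that every cell in a numeric
column parses, reporting the exact row/column of the first offender —
comma-decimal (locale) files are rejected with a pointed message rather
than silently mangled.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd


def load_table(
    path: str | Path,
    required_columns: Sequence[str] = (),
    numeric_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Load a tidy CSV, enforcing required columns and numeric cells."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            # ragged rows (e.g. comma-decimal cells) must fail, not truncate
            warnings.simplefilter("error", pd.errors.ParserWarning)
            df = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=False)
    except (pd.errors.ParserError, pd.errors.ParserWarning) as exc:
        raise ValueError(
            f"{path.name}: malformed CSV ({exc}); note that comma decimal "
            "separators are not supported — use dot-decimal CSV"
        ) from None
    for col in required_columns:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    numeric = list(numeric_columns) or [
        c for c in df.columns if c in required_columns
    ]
    for col in numeric:
        for row_idx, cell in enumerate(df[col]):
            try:
                float(cell)
            except (TypeError, ValueError):
                hint = ""
                if isinstance(cell, str) and "," in cell:
                    hint = (
                        " (comma decimal separators are not supported; "
                        "use dot-decimal CSV)"
                    )
                raise ValueError(
                    f"{path.name}: non-numeric value {cell!r} at row "
                    f"{row_idx + 2}, column {col!r}{hint}"
                ) from None
        df[col] = df[col].astype(float)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy table as dot-decimal, comma-separated, UTF-8 CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
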