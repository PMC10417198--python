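"""Profile-table column conventions and CSV round-tripping.

A profile table holds one row per sample with label columns
``sample_id, site, production, preparation`` followed by, for each element
``El``, a concentration column ``El_ppm`` and an instrument-error column
``El_err`` (both in ppm). All CSV output uses comma separation, UTF-8, a
header row, and the literal ``NA`` for missing values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

LABEL_COLUMNS = ("sample_id", "site", "production", "preparation")

PPM_SUFFIX = "_ppm"
ERR_SUFFIX = "_err"


def ppm_col(element: str) -> str:
    return f"{element}{PPM_SUFFIX}"


def err_col(element: str) -> str:
    return f"{element}{ERR_SUFFIX}"


def element_roster(table: pd.DataFrame) -> list[str]:
    """Elements present in a profile table, in column order."""
    return [c[: -len(PPM_SUFFIX)] for c in table.columns if c.endswith(PPM_SUFFIX)]


def concentrations(table: pd.DataFrame) -> pd.DataFrame:
    """Concentration matrix (columns named by bare element symbol)."""
    els = element_roster(table)
    out = table[[ppm_col(e) for e in els]].copy()
    out.columns = els
    return out


def errors(table: pd.DataFrame) -> pd.DataFrame:
    """Instrument-error matrix (columns named by bare element symbol)."""
    els = element_roster(table)
    out = table[[err_col(e) for e in els]].copy()
    out.columns = els
    return out


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, na_rep="NA")
    return path


def write_profile_csv(table: pd.DataFrame, path: str | Path) -> Path:
    return write_table(table, path)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"profile CSV missing label columns: {missing}")
    return table
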