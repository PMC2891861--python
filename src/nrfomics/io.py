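"""Tab-separated I/O for the pipeline's table dialects.

All tables travel as plain TSV with a header row.  Readers validate the
schema up front and convert parser failures into errors that name the
offending line, so that shell pipelines fail loudly on malformed input.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import RATIO_COLUMNS, validate_ratio_table
from .gel import SPOT_COLUMNS, validate_spot_table


class MalformedTableError(ValueError):
    """A TSV file that cannot be parsed into the expected dialect."""


def _read_tsv(path, required: list[str], dtypes: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise MalformedTableError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedTableError(f"{path}: missing columns {missing}")
    for col, typ in dtypes.items():
        try:
            df[col] = df[col].astype(typ)
        except ValueError as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            lineno = int(df.index[bad][0]) + 2  # header + 1-based
            raise MalformedTableError(
                f"{path}: line {lineno}: cannot parse column {col!r} "
                f"value {df.loc[df.index[bad][0], col]!r}") from exc
    return df


def read_ratio_table(path) -> pd.DataFrame:
    """Read a reporter-ratio table (accession, protein_name, genotype,
    animal_id, run_id, ratio) and validate its invariants."""
    df = _read_tsv(path, RATIO_COLUMNS, {"ratio": float})
    validate_ratio_table(df)
    return df[RATIO_COLUMNS]


def write_ratio_table(table: pd.DataFrame, path) -> None:
    table[RATIO_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spot_table(path) -> pd.DataFrame:
    """Read a 2DE spot table (gel_id, group, spot_id, intensity)."""
    df = _read_tsv(path, SPOT_COLUMNS, {"intensity": float})
    numeric_ids = pd.to_numeric(df["spot_id"], errors="coerce")
    if not numeric_ids.isna().any():
        df["spot_id"] = numeric_ids.astype(int)
    validate_spot_table(df)
    return df[SPOT_COLUMNS]


def write_spot_table(table: pd.DataFrame, path) -> None:
    table[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_alias_map(path) -> dict[str, str]:
    """Read an accession-alias map TSV with columns ``alias, canonical``."""
    df = _read_tsv(path, ["alias", "canonical"], {})
    return dict(zip(df["alias"], df["canonical"]))


def write_alias_map(alias_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"alias": list(alias_map), "canonical": list(alias_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_protein_list(path) -> list[str]:
    """Read a one-accession-per-line protein list (or first TSV column)."""
    items = []
    for line in Path(path).read_text().splitlines():
        field = line.split("\t")[0].strip()
        if field and field.lower() != "accession":
            items.append(field)
    return items
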