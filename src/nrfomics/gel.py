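"""Two-dimensional gel (2DE) spot-table statistics.

Spot volumes from scanned 2DE gels are comparable across gels only after
normalisation: each spot's intensity is expressed as a percentage of the
total intensity of all matched spots on its own gel.  Comparisons are
restricted to spots detected on every gel of at least one treatment group
(optionally both), and group differences are tested with the same
normality-gated t-test / Mann-Whitney machinery as the isobaric-tag data.

Spot tables are long-format DataFrames with columns ``gel_id, group,
spot_id, intensity`` where ``group`` is ``"WT"`` or ``"KO"``.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from . import diffstats

SPOT_COLUMNS = ["gel_id", "group", "spot_id", "intensity"]


def validate_spot_table(table: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot table is missing columns: {missing}")
    if (table["intensity"] < 0).any():
        raise ValueError("spot intensities must be non-negative")
    if table.duplicated(["gel_id", "spot_id"]).any():
        raise ValueError("duplicate (gel_id, spot_id) records")


def normalize_spots(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_intensity``: percent of total matched intensity per gel.

    Defined on the full matched spot set of each gel only -- re-normalising a
    row subset would silently change every remaining value, so callers must
    normalise before filtering.
    """
    validate_spot_table(table)
    totals = table.groupby("gel_id")["intensity"].transform("sum")
    zero = table.loc[totals == 0, "gel_id"].unique()
    if len(zero):
        raise ValueError(f"gel(s) with zero total intensity: {list(zero)}")
    out = table.copy()
    out["normalized_intensity"] = 100.0 * out["intensity"] / totals
    return out


def spot_inclusion(table: pd.DataFrame, require: str = "any") -> list:
    """Spot ids eligible for comparison.

    A spot qualifies when it is present on all gels of at least one group
    (``require="any"``), or on all gels of both groups (``require="both"``).
    """
    if require not in ("any", "both"):
        raise ValueError(f"require must be 'any' or 'both', got {require!r}")
    validate_spot_table(table)
    gels_per_group = table.groupby("group")["gel_id"].nunique()
    present = (
        table.groupby(["spot_id", "group"])["gel_id"].nunique().unstack(fill_value=0)
    )
    complete = present.eq(gels_per_group, axis=1)
    mask = complete.all(axis=1) if require == "both" else complete.any(axis=1)
    return sorted(complete.index[mask])


def spot_stats(
    table: pd.DataFrame, spot_id, alpha: float = 0.05
) -> dict:
    """Group statistics for one normalised spot.

    Returns per-group mean, SD and SEM of normalised intensities, the KO/WT
    fold change of group means (unrounded), the two-sided p-value and the
    test used.  The table must already carry ``normalized_intensity``.
    """
    if "normalized_intensity" not in table.columns:
        raise ValueError("normalize_spots must be applied before spot_stats")
    sub = table[table["spot_id"] == spot_id]
    wt = sub.loc[sub["group"] == "WT", "normalized_intensity"].to_numpy()
    ko = sub.loc[sub["group"] == "KO", "normalized_intensity"].to_numpy()
    if wt.size == 0 or ko.size == 0:
        raise ValueError(f"spot {spot_id!r} missing from one group entirely")
    res = {
        "spot_id": spot_id,
        "wt_mean": float(wt.mean()), "ko_mean": float(ko.mean()),
        "wt_sd": float(wt.std(ddof=1)) if wt.size > 1 else 0.0,
        "ko_sd": float(ko.std(ddof=1)) if ko.size > 1 else 0.0,
        "wt_sem": float(wt.std(ddof=1) / np.sqrt(wt.size)) if wt.size > 1 else 0.0,
        "ko_sem": float(ko.std(ddof=1) / np.sqrt(ko.size)) if ko.size > 1 else 0.0,
        "fold_change": float(ko.mean() / wt.mean()),
    }
    if wt.size >= 3 and ko.size >= 3:
        choice = diffstats.choose_test(wt, ko, alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # raw-intensity scale: percentages are already additive
            res["raw_p"] = diffstats.raw_p(wt, ko, choice.test, log_scale=False)
        res["test_used"] = choice.test
    else:
        res["raw_p"] = np.nan
        res["test_used"] = None
    return res


def gel_analysis(
    table: pd.DataFrame,
    require: str = "any",
    alpha: float = 0.05,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Normalise, filter and test every eligible spot.

    Returns one row per eligible spot with group means +/- SD and SEM (both
    dispersions are reported, explicitly labelled), fold change, p-value,
    test used and a ``significant`` flag at ``p < p_cut``.
    """
    norm = normalize_spots(table)
    eligible = spot_inclusion(table, require=require)
    rows = [spot_stats(norm, s, alpha=alpha) for s in eligible]
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["raw_p"] < p_cut
    return out
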