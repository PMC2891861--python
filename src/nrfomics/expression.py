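"""Reporter-ratio aggregation arithmetic.

Isobaric-tag (iTRAQ) experiments quantify each protein as a ratio of its
reporter-ion intensity in one animal to the intensity in a designated
reference wild-type animal.  Because these ratios are multiplicative
quantities, group location is summarised by the geometric mean and spread by
a confidence interval computed on the natural-log scale.  This module houses
that arithmetic: per-animal run averaging, complete-case filtering across the
animal panel, geometric means, log-normal confidence intervals and
knockout/wild-type fold changes.

Ratio tables are long-format :class:`pandas.DataFrame` objects with columns
``accession, protein_name, genotype, animal_id, run_id, ratio`` (one row per
protein x animal x run actually measured).  Genotype labels are ``"WT"`` and
``"KO"``.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RATIO_COLUMNS = ["accession", "protein_name", "genotype", "animal_id", "run_id", "ratio"]
GENOTYPES = ("WT", "KO")


def validate_ratio_table(table: pd.DataFrame) -> None:
    """Check the ratio-table invariants, raising ``ValueError`` on violation.

    Required: all schema columns present, ratios strictly positive, genotype
    labels in {WT, KO}, and (accession, animal_id, run_id) unique.
    """
    missing = [c for c in RATIO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratio table is missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("ratio table is empty")
    if not (table["ratio"] > 0).all():
        bad = table.loc[~(table["ratio"] > 0), "accession"].unique()
        raise ValueError(f"non-positive ratios for accessions: {list(bad)[:5]}")
    bad_geno = set(table["genotype"].unique()) - set(GENOTYPES)
    if bad_geno:
        raise ValueError(f"unknown genotype labels: {sorted(bad_geno)}")
    dup = table.duplicated(["accession", "animal_id", "run_id"])
    if dup.any():
        raise ValueError(
            "duplicate (accession, animal_id, run_id) records: "
            f"{table.loc[dup, ['accession', 'animal_id', 'run_id']].head().to_dict('records')}"
        )


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean exp(mean(ln v)) of strictly positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric_mean requires at least one value")
    if not (v > 0).all():
        idx = int(np.flatnonzero(~(v > 0))[0])
        raise ValueError(f"non-positive value at position {idx}: {v[idx]}")
    return float(np.exp(np.mean(np.log(v))))


def lognormal_ci(values: Sequence[float], z: float = 1.96) -> tuple[float, float]:
    """Normal-quantile confidence interval for the geometric mean.

    Computed on the log scale as ``exp(mean(ln v) +/- z * sd(ln v)/sqrt(n))``
    with the sample (n-1) standard deviation.  With the default ``z = 1.96``
    this is a 95% interval under log-normality.  A single value yields a
    degenerate interval at that value, with a warning.
    """
    v = np.asarray(values, dtype=float)
    if not (v > 0).all():
        raise ValueError("lognormal_ci requires strictly positive values")
    if v.size == 1:
        warnings.warn("confidence interval undefined for a single value; "
                      "returning a degenerate interval", stacklevel=2)
        return float(v[0]), float(v[0])
    logs = np.log(v)
    m = logs.mean()
    se = logs.std(ddof=1) / np.sqrt(v.size)
    return float(np.exp(m - z * se)), float(np.exp(m + z * se))


def fold_change(gm_ko: float, gm_wt: float) -> float:
    """Knockout/wild-type fold change from unrounded geometric means."""
    if gm_ko <= 0 or gm_wt <= 0:
        raise ValueError("fold_change requires positive geometric means")
    return gm_ko / gm_wt


def aggregate_runs(table: pd.DataFrame, method: str = "arithmetic") -> pd.DataFrame:
    """Collapse replicate runs to one expression value per (protein, animal).

    The per-animal value is the arithmetic mean of that animal's per-run
    ratios (``method="geometric"`` substitutes the geometric mean).  Returns
    columns ``accession, protein_name, genotype, animal_id, aggregated_ratio,
    n_runs``.
    """
    validate_ratio_table(table)
    if method not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown run-averaging method: {method!r}")
    agg = "mean" if method == "arithmetic" else geometric_mean
    grouped = (
        table.groupby(["accession", "protein_name", "genotype", "animal_id"], sort=True)["ratio"]
        .agg(aggregated_ratio=agg, n_runs="size")
        .reset_index()
    )
    return grouped


def complete_case_filter(
    animal_table: pd.DataFrame, required_animals: Iterable[str]
) -> pd.DataFrame:
    """Retain proteins with an aggregated value for every required animal."""
    required = set(required_animals)
    if not required:
        raise ValueError("required_animals must be non-empty")
    seen = animal_table.groupby("accession")["animal_id"].agg(set)
    keep = seen.index[seen.apply(lambda s: required <= s)]
    return animal_table[animal_table["accession"].isin(keep)].reset_index(drop=True)


def group_summary(animal_table: pd.DataFrame, z: float = 1.96) -> pd.DataFrame:
    """Per-(protein, genotype) geometric means with log-normal CIs.

    Input is per-animal expression (``aggregate_runs`` output or equivalent);
    output columns are ``accession, genotype, geometric_mean, ci_lower,
    ci_upper, n_animals``.
    """
    rows = []
    for (acc, geno), grp in animal_table.groupby(["accession", "genotype"], sort=True):
        v = grp["aggregated_ratio"].to_numpy()
        gm = geometric_mean(v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo, hi = lognormal_ci(v, z=z)
        rows.append({
            "accession": acc, "genotype": geno, "geometric_mean": gm,
            "ci_lower": lo, "ci_upper": hi, "n_animals": len(v),
        })
    return pd.DataFrame(rows)


def summarize_expression(
    table: pd.DataFrame,
    required_animals: Iterable[str] | None = None,
    z: float = 1.96,
    run_average: str = "arithmetic",
) -> pd.DataFrame:
    """Full aggregation path: runs -> animals -> genotype summaries -> fold.

    When ``required_animals`` is given, proteins lacking a value for any of
    those animals are dropped before summarisation (complete-case rule).
    Returns one row per protein with WT and KO geometric means, CI bounds and
    the KO/WT fold change, all computed on unrounded values.
    """
    animals = aggregate_runs(table, method=run_average)
    if required_animals is not None:
        animals = complete_case_filter(animals, required_animals)
    if len(animals) == 0:
        raise ValueError("no protein passes the complete-case filter")
    summ = group_summary(animals, z=z)
    wide = summ.pivot(index="accession", columns="genotype",
                      values=["geometric_mean", "ci_lower", "ci_upper", "n_animals"])
    wide.columns = [f"{geno.lower()}_{stat}" for stat, geno in wide.columns]
    wide = wide.reset_index()
    names = table[["accession", "protein_name"]].drop_duplicates("accession")
    wide = wide.merge(names, on="accession", how="left")
    wide["fold_change"] = wide.apply(
        lambda r: fold_change(r["ko_geometric_mean"], r["wt_geometric_mean"])
        if pd.notna(r.get("ko_geometric_mean")) and pd.notna(r.get("wt_geometric_mean"))
        else np.nan,
        axis=1,
    )
    lead = ["accession", "protein_name"]
    return wide[lead + [c for c in wide.columns if c not in lead]]
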