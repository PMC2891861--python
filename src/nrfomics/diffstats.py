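"""Per-protein inference and cross-analysis concordance.

Each protein's wild-type and knockout expression values are compared with a
normality-gated two-sample test: both groups are screened with Shapiro-Wilk
(and an F-test for variance equality is recorded); if both pass, an unpaired
Student's t-test is used, otherwise the Mann-Whitney rank test.  Raw p-values
across the protein panel are adjusted by the Benjamini-Hochberg step-up, and
a protein is accepted as differentially expressed when its raw p is below
``p_cut`` (default 0.05) *and* its adjusted value is at or below ``bh_cut``
(default 0.2) -- a deliberately permissive FDR ceiling that avoids discarding
co-regulated proteins.

``concordance`` intersects named significant lists (e.g. from independent
experiments) under an explicit accession-alias map and reports the proteins
recurring in at least ``k`` lists together with Venn-region counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import fold_change, geometric_mean

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class TestChoice:
    """Outcome of the normality gate for one protein."""

    test: str
    shapiro_p_wt: float
    shapiro_p_ko: float
    f_test_p: float


def f_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided F-test p-value for equality of variances."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = stats.f.sf(f, a.size - 1, b.size - 1)
    return float(min(1.0, 2 * min(p, 1 - p)))


def choose_test(
    values_wt: Sequence[float], values_ko: Sequence[float], alpha: float = 0.05
) -> TestChoice:
    """Route to the t-test when both groups look normal, else Mann-Whitney.

    Shapiro-Wilk needs at least three observations per group.  Groups with
    zero within-group variance cannot be assessed for normality and are sent
    to the rank test.
    """
    wt = np.asarray(values_wt, float)
    ko = np.asarray(values_ko, float)
    if wt.size < 3 or ko.size < 3:
        raise ValueError("normality screening requires >= 3 values per group")
    ps = []
    for grp in (wt, ko):
        if np.ptp(grp) == 0:
            ps.append(0.0)  # constant sample: normality not assessable
        else:
            ps.append(float(stats.shapiro(grp).pvalue))
    test = T_TEST if (ps[0] > alpha and ps[1] > alpha) else MANN_WHITNEY
    return TestChoice(test, ps[0], ps[1], f_test_p=f_test(wt, ko))


def raw_p(
    values_wt: Sequence[float],
    values_ko: Sequence[float],
    test: str,
    log_scale: bool = True,
    equal_var: bool = True,
) -> float:
    """Two-sided p-value from the chosen test.

    For the t-test, values are ln-transformed by default so that the null is
    on the same multiplicative scale as the geometric-mean summaries; the
    rank test is invariant to monotone transforms.  ``equal_var=False``
    switches to the Welch t-test.
    """
    wt = np.asarray(values_wt, float)
    ko = np.asarray(values_ko, float)
    if test == T_TEST:
        if log_scale:
            wt, ko = np.log(wt), np.log(ko)
        if np.ptp(wt) == 0 and np.ptp(ko) == 0:
            if wt.mean() == ko.mean():
                warnings.warn("zero variance in both groups; p set to 1", stacklevel=2)
                return 1.0
            warnings.warn("zero variance in both groups with unequal means; "
                          "t statistic undefined, p set to 0", stacklevel=2)
            return 0.0
        return float(stats.ttest_ind(wt, ko, equal_var=equal_var).pvalue)
    if test == MANN_WHITNEY:
        # exact null distribution for small samples without ties, otherwise
        # the tie-corrected normal approximation
        n = wt.size + ko.size
        has_ties = len(np.unique(np.concatenate([wt, ko]))) < n
        method = "exact" if (wt.size <= 8 and ko.size <= 8 and not has_ties) else "asymptotic"
        return float(stats.mannwhitneyu(wt, ko, alternative="two-sided", method=method).pvalue)
    raise ValueError(f"unknown test: {test!r}")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(
    results: pd.DataFrame, p_cut: float = 0.05, bh_cut: float = 0.2
) -> pd.DataFrame:
    """Flag proteins with raw_p < p_cut and bh_p <= bh_cut."""
    out = results.copy()
    out["significant"] = (out["raw_p"] < p_cut) & (out["bh_p"] <= bh_cut)
    return out


def differential_analysis(
    animal_table: pd.DataFrame,
    alpha: float = 0.05,
    p_cut: float = 0.05,
    bh_cut: float = 0.2,
    log_scale: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Run the full per-protein testing stage on per-animal expression.

    Input columns: ``accession, protein_name, genotype, animal_id,
    aggregated_ratio`` (see :func:`nrfomics.expression.aggregate_runs`).
    Output: one row per protein with fold change (ratio of geometric means),
    the chosen test, raw and BH-adjusted p-values and the significance flag.
    """
    rows = []
    for acc, grp in animal_table.groupby("accession", sort=True):
        wt = grp.loc[grp["genotype"] == "WT", "aggregated_ratio"].to_numpy()
        ko = grp.loc[grp["genotype"] == "KO", "aggregated_ratio"].to_numpy()
        if wt.size < 3 or ko.size < 3:
            continue
        choice = choose_test(wt, ko, alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = raw_p(wt, ko, choice.test, log_scale=log_scale, equal_var=equal_var)
        rows.append({
            "accession": acc,
            "protein_name": grp["protein_name"].iloc[0],
            "fold_change": fold_change(geometric_mean(ko), geometric_mean(wt)),
            "test_used": choice.test,
            "shapiro_p_wt": choice.shapiro_p_wt,
            "shapiro_p_ko": choice.shapiro_p_ko,
            "f_test_p": choice.f_test_p,
            "raw_p": p,
        })
    if not rows:
        raise ValueError("no protein had >= 3 values in both genotype groups")
    results = pd.DataFrame(rows)
    results["bh_p"] = bh_adjust(results["raw_p"].to_numpy())
    return select_significant(results, p_cut=p_cut, bh_cut=bh_cut)


@dataclass
class ConcordanceReport:
    """Cross-analysis overlap of significant protein lists."""

    membership: pd.DataFrame        # proteins x analyses boolean table
    selected: list[str]             # proteins present in >= k analyses
    k: int
    venn_counts: dict[str, int] = field(default_factory=dict)
    alias_map: dict[str, str] = field(default_factory=dict)


def _harmonize(names: Iterable[str], alias_map: Mapping[str, str]) -> list[str]:
    return [alias_map.get(n, n) for n in names]


def concordance(
    lists: Mapping[str, Iterable[str]],
    alias_map: Mapping[str, str] | None = None,
    k: int = 2,
) -> ConcordanceReport:
    """Proteins recurring in at least ``k`` of the named lists.

    ``alias_map`` resolves accession aliases (e.g. the same protein deposited
    under different accessions in different analyses) to a canonical id
    before intersection.  Duplicated canonical ids *within* one list are an
    error, since they would silently double-count.  Venn-region counts are
    reported for every non-empty combination of analyses.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alias_map = dict(alias_map or {})
    canon: dict[str, set[str]] = {}
    for name, members in lists.items():
        mapped = _harmonize(list(members), alias_map)
        dups = sorted({m for m in mapped if mapped.count(m) > 1})
        if dups:
            raise ValueError(f"list {name!r} contains duplicate ids after "
                             f"harmonization: {dups}")
        canon[name] = set(mapped)
    all_ids = sorted(set().union(*canon.values())) if canon else []
    membership = pd.DataFrame(
        {name: [i in s for i in all_ids] for name, s in canon.items()},
        index=pd.Index(all_ids, name="accession"),
    )
    counts = membership.sum(axis=1)
    selected = sorted(counts.index[counts >= k])
    venn: dict[str, int] = {}
    names = list(canon)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(canon[n] for n in combo))
            outside = set().union(*(canon[n] for n in names if n not in combo), set())
            venn["&".join(combo)] = len(inside - outside)
    return ConcordanceReport(membership=membership, selected=selected, k=k,
                             venn_counts=venn, alias_map=alias_map)
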