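"""Gene-set over-representation by the hypergeometric tail.

The probability that a gene set (pathway) of size K within a universe of N
quantified genes contains at least k of the n significant genes, under random
draws without replacement:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

Gene sets are supplied in GMT format (one set per line: name, description,
members...).  Members outside the declared universe are dropped before
testing, with the dropped count recorded per set.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


def read_gmt(source) -> dict[str, list[str]]:
    """Read gene sets from a GMT file into {set name: member list}."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected name, description "
                             "and at least one member")
        name, _desc, *members = fields
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = [m for m in members if m]
    return sets


def write_gmt(genesets: Mapping[str, Iterable[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in genesets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    significant: Iterable[str],
    universe: Iterable[str],
    genesets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Over-representation of each gene set in the significant list.

    Returns one row per set, sorted by ascending p, with columns
    ``set_name, set_size (K), n_significant (n), overlap (k),
    universe_size (N), dropped, p, neg_log10_p``.  ``dropped`` counts set
    members outside the universe (excluded from K).  Significant genes must
    all belong to the universe.
    """
    uni = set(universe)
    sig = set(significant)
    outside = sorted(sig - uni)
    if outside:
        raise ValueError(f"significant genes absent from universe: {outside[:10]}")
    N, n = len(uni), len(sig)
    rows = []
    for name, members in genesets.items():
        mem = set(members)
        in_uni = mem & uni
        K = len(in_uni)
        k = len(in_uni & sig)
        p = hypergeom_pvalue(N, K, n, k) if K else 1.0
        rows.append({
            "set_name": name, "set_size": K, "n_significant": n,
            "overlap": k, "universe_size": N, "dropped": len(mem) - K,
            "p": p, "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
        })
    out = pd.DataFrame(rows).sort_values(["p", "set_name"], kind="stable")
    return out.reset_index(drop=True)
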