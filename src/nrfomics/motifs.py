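"""Antioxidant-response-element (ARE) promoter scanning.

Two complementary detectors over upstream promoter sequences:

* a degenerate-consensus string search (every overlapping window tested for
  per-position membership in the pattern's allowed-base sets), and
* a position-specific scoring matrix (PSSM) scan in the patser tradition: a
  position probability matrix is converted to natural-log odds against a
  symmetric A/T vs C/G background, each window is scored by summing the
  weights of its bases, and windows exceeding a score threshold count as
  matrix matches.

Coordinates are negative offsets relative to the start codon: the base
immediately 5' of the start codon is position -1 and the first base of an
L-bp promoter is -L.  A hit spans inclusive offsets ``[start, end]`` with
``end - start + 1`` equal to the pattern/matrix width.  Minus-strand hits are
windows whose reverse complement matches; they are reported with plus-strand
coordinates and the plus-strand window sequence.

The default degenerate alphabet follows a published ARE consensus definition
in which R = G/C and B = G/C/T; ``alphabet="iupac"`` switches to the standard
IUPAC ambiguity codes (R = A/G, ...).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Degenerate letter -> allowed bases.  The "legacy" preset uses the
# non-standard R = G/C and B = G/C/T of the ARE consensus RTGABNNNGCA;
# "iupac" is the standard nucleotide ambiguity alphabet.
LEGACY_ARE_ALPHABET: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "GC", "B": "GCT", "N": "ACGT",
}
IUPAC_ALPHABET: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Named consensus presets: the same core ARE has circulated in several
# spellings; all three are provided without adjudicating between them.
CONSENSUS_PRESETS = {
    "are_gca": "RTGABNNNGCA",
    "are_tca": "RTGABNNNTCA",
    "are_short": "RTGABNNNGA",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePattern:
    """A consensus pattern with an explicit letter -> allowed-bases map."""

    pattern: str
    alphabet: Mapping[str, str]

    def __post_init__(self):
        for letter in self.pattern:
            allowed = self.alphabet.get(letter, "")
            if not allowed:
                raise ValueError(f"pattern letter {letter!r} has no allowed bases")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        """True when every base of ``window`` is allowed at its position.

        ``N`` in the *sequence* never matches any pattern letter.
        """
        if len(window) != len(self.pattern):
            return False
        return all(b in self.alphabet[l] for b, l in zip(window, self.pattern))


def make_pattern(pattern: str = CONSENSUS_PRESETS["are_gca"],
                 alphabet: str = "legacy") -> DegeneratePattern:
    """Build a pattern under the 'legacy' or 'iupac' degenerate alphabet."""
    if alphabet == "legacy":
        table = LEGACY_ARE_ALPHABET
    elif alphabet == "iupac":
        table = IUPAC_ALPHABET
    else:
        raise ValueError(f"alphabet must be 'legacy' or 'iupac', got {alphabet!r}")
    return DegeneratePattern(pattern.upper(), table)


# ---------------------------------------------------------------------------
# promoter I/O


def read_promoters(source) -> dict[str, str]:
    """Read promoters from FASTA into {gene id: upper-case sequence}.

    Accepts a path or an open text handle.  Mixed case is upper-cased; only
    A/C/G/T/N are permitted.  Duplicate ids and empty sequences are errors.
    """
    if isinstance(source, (str, Path)):
        records = list(SeqIO.parse(str(source), "fasta"))
    else:
        records = list(SeqIO.parse(source, "fasta"))
    promoters: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if rec.id in promoters:
            raise ValueError(f"duplicate promoter id: {rec.id}")
        if not seq:
            raise ValueError(f"empty sequence for promoter {rec.id}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter {rec.id} contains non-nucleotide "
                             f"characters: {sorted(bad)}")
        promoters[rec.id] = seq
    return promoters


def write_promoters(promoters: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# consensus scanning


def _iter_windows(seq: str, width: int):
    L = len(seq)
    for i in range(L - width + 1):
        yield i, seq[i:i + width]


def consensus_scan(
    promoters: Mapping[str, str],
    pattern: DegeneratePattern,
    strands: str = "both",
) -> pd.DataFrame:
    """All windows matching the degenerate pattern, overlaps included.

    Returns columns ``gene, strand, start, end, matched`` with inclusive
    negative offsets and the plus-strand window sequence.  Per-gene counts
    follow from ``hits.groupby("gene").size()`` (genes with zero hits simply
    absent) or :func:`per_gene_counts`.
    """
    if strands not in ("plus", "both"):
        raise ValueError(f"strands must be 'plus' or 'both', got {strands!r}")
    W = len(pattern)
    rows = []
    for gene, seq in promoters.items():
        L = len(seq)
        for i, window in _iter_windows(seq, W):
            if pattern.matches(window):
                rows.append((gene, "+", i - L, i + W - 1 - L, window))
            if strands == "both" and pattern.matches(reverse_complement(window)):
                rows.append((gene, "-", i - L, i + W - 1 - L, window))
    return pd.DataFrame(rows, columns=["gene", "strand", "start", "end", "matched"])


def per_gene_counts(hits: pd.DataFrame, genes: Iterable[str]) -> pd.Series:
    """Hit counts per gene, zero-filled for genes without hits."""
    counts = hits.groupby("gene").size() if len(hits) else pd.Series(dtype=int)
    return counts.reindex(list(genes), fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# PSSM construction and scanning


def background_frequencies(promoters: Mapping[str, str]) -> dict[str, float]:
    """Pooled strand-symmetric background base frequencies.

    A and T share the mean A/T frequency across all usable (non-N) bases of
    the promoter set; C and G share the mean C/G frequency.  The four values
    sum to 1.
    """
    counts = {b: 0 for b in BASES}
    for seq in promoters.values():
        for b in BASES:
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("promoter set contains no usable (A/C/G/T) bases")
    at = (counts["A"] + counts["T"]) / (2 * total)
    cg = (counts["C"] + counts["G"]) / (2 * total)
    return {"A": at, "T": at, "C": cg, "G": cg}


#: background preset matching the A/T 0.26, C/G 0.24 means reported for the
#: mouse promoter panel this pipeline was built around
MOUSE_PROMOTER_BACKGROUND = {"A": 0.26, "T": 0.26, "C": 0.24, "G": 0.24}


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Position probability matrix: rows A,C,G,T x columns 1..W."""

    probs: np.ndarray  # shape (4, W)
    name: str = "matrix"

    def __post_init__(self):
        p = np.asarray(self.probs, float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError("probability matrix must have shape (4, W)")
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        colsums = p.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"matrix columns must sum to 1, got {colsums}")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


def read_probability_matrix(source, name: str = "matrix") -> ProbabilityMatrix:
    """Read a whitespace-delimited matrix: rows A,C,G,T, optional header.

    Each data row is a base letter followed by W probabilities.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    rows: dict[str, list[float]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        fields = line.split()
        if not fields or fields[0].startswith("#"):
            continue
        key = fields[0].upper().rstrip(":|")
        if key in _BASE_INDEX:
            try:
                rows[key] = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric matrix entry") from exc
    if set(rows) != set(BASES):
        raise ValueError(f"matrix must provide rows for A, C, G and T; got {sorted(rows)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ValueError(f"matrix rows have unequal widths: {widths}")
    return ProbabilityMatrix(np.array([rows[b] for b in BASES]), name=name)


def write_probability_matrix(matrix: ProbabilityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("# position probability matrix; columns 1.." f"{matrix.width}\n")
        for b in BASES:
            vals = " ".join(f"{x:.6f}" for x in matrix.probs[_BASE_INDEX[b]])
            fh.write(f"{b} {vals}\n")


@dataclass(frozen=True)
class Pssm:
    """Log-odds scoring matrix w(b,i) = ln((f+eps) / ((1+4*eps) * p(b)))."""

    weights: np.ndarray  # shape (4, W), natural log units
    background: Mapping[str, float]
    pseudocount: float
    name: str = "pssm"

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def score(self, window: str) -> float:
        """Score one window; NaN when the window contains N."""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != width {self.width}")
        total = 0.0
        for i, b in enumerate(window):
            j = _BASE_INDEX.get(b)
            if j is None:
                return math.nan
            total += self.weights[j, i]
        return total


def build_pssm(
    matrix: ProbabilityMatrix,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 0.001,
) -> Pssm:
    """Convert a probability matrix to natural-log odds weights.

    A pseudocount ``eps`` regularises zero cells: the effective foreground
    probability is ``(f + eps) / (1 + 4*eps)`` (a proper distribution per
    column).  ``eps = 0`` is rejected whenever any cell or background entry
    is zero, since the weight would be infinite.
    """
    bg = dict(background) if background is not None else dict(MOUSE_PROMOTER_BACKGROUND)
    if not math.isclose(sum(bg.values()), 1.0, abs_tol=1e-6):
        raise ValueError(f"background must sum to 1, got {sum(bg.values())}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = np.array([bg[b] for b in BASES])[:, None]
    f = matrix.probs
    if pseudocount == 0 and ((f == 0).any() or (p == 0).any()):
        raise ValueError("pseudocount of 0 with zero probabilities would give "
                         "infinite weights")
    eff = (f + pseudocount) / (1.0 + 4.0 * pseudocount)
    weights = np.log(eff / p)
    if not np.isfinite(weights).all():
        raise ValueError("non-finite PSSM weights; increase the pseudocount")
    return Pssm(weights=weights, background=bg, pseudocount=pseudocount,
                name=matrix.name)


def render_site(seq: str, i: int, width: int, flank: int = 4) -> str:
    """Human-readable site: lower-case flanks around an upper-case core."""
    left = seq[max(0, i - flank):i].lower()
    core = seq[i:i + width].upper()
    right = seq[i + width:i + width + flank].lower()
    return left + core + right


def pssm_scan(
    promoters: Mapping[str, str],
    pssm: Pssm,
    threshold: float = 1.0,
    strands: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every window; report hits above threshold and per-gene summaries.

    Returns ``(hits, summary)``.  ``hits`` has columns ``gene, strand, start,
    end, matched, score``; minus-strand scores come from the window's reverse
    complement but are located by plus-strand coordinates.  ``summary`` has
    one row per gene: number of matches, highest score, mean and SD of hit
    scores, and the best hit's location and rendered sequence.  Windows
    containing N are skipped.  Promoters shorter than the matrix width yield
    a zero-match summary row.
    """
    if strands not in ("plus", "both"):
        raise ValueError(f"strands must be 'plus' or 'both', got {strands!r}")
    W = pssm.width
    hit_rows = []
    summary_rows = []
    for gene, seq in promoters.items():
        L = len(seq)
        gene_hits = []
        for i, window in _iter_windows(seq, W):
            s = pssm.score(window)
            if not math.isnan(s) and s > threshold:
                gene_hits.append((gene, "+", i - L, i + W - 1 - L, window, s, i))
            if strands == "both":
                s2 = pssm.score(reverse_complement(window))
                if not math.isnan(s2) and s2 > threshold:
                    gene_hits.append((gene, "-", i - L, i + W - 1 - L, window, s2, i))
        hit_rows.extend(h[:6] for h in gene_hits)
        if gene_hits:
            scores = np.array([h[5] for h in gene_hits])
            best = max(gene_hits, key=lambda h: h[5])
            summary_rows.append({
                "gene": gene, "n_matches": len(gene_hits),
                "highest_score": float(scores.max()),
                "mean_score": float(scores.mean()),
                "sd_score": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
                "best_strand": best[1], "best_start": best[2], "best_end": best[3],
                "best_site": render_site(seq, best[6], W),
            })
        else:
            summary_rows.append({
                "gene": gene, "n_matches": 0, "highest_score": np.nan,
                "mean_score": np.nan, "sd_score": np.nan,
                "best_strand": None, "best_start": None, "best_end": None,
                "best_site": None,
            })
    hits = pd.DataFrame(
        hit_rows, columns=["gene", "strand", "start", "end", "matched", "score"]
    )
    return hits, pd.DataFrame(summary_rows)


def panel_summary(
    gene_table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    columns: Sequence[str] = ("consensus_count", "n_matches", "highest_score", "mean_score"),
) -> pd.DataFrame:
    """Arithmetic means of per-gene statistics for declared gene groups.

    ``gene_table`` is indexed by or contains a ``gene`` column plus any of
    the statistic columns; empty groups are omitted with a warning.
    """
    import warnings as _warnings

    tbl = gene_table.set_index("gene") if "gene" in gene_table.columns else gene_table
    rows = []
    for name, genes in groups.items():
        present = [g for g in genes if g in tbl.index]
        if not present:
            _warnings.warn(f"gene group {name!r} is empty; omitted", stacklevel=2)
            continue
        sub = tbl.loc[present]
        row = {"group": name, "n_genes": len(present)}
        for col in columns:
            if col in sub.columns:
                row[col] = float(pd.to_numeric(sub[col], errors="coerce").mean())
        rows.append(row)
    return pd.DataFrame(rows)
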