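"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the three input families the pipeline consumes --
isobaric-tag reporter-ratio tables, 2DE spot-intensity tables and promoter
FASTA with planted motifs -- under the study design they were built to test:
two genotype groups (4 animals each by default), four replicate runs, and
ratios expressed against a reference wild-type animal.

Noise model: ratios are multiplicative log-normal.  For an animal of
genotype g, the measured ratio in one run is ``fold_g * exp(sigma * Z)``
with ``Z ~ N(0, 1)`` and ``sigma = sqrt(ln(1 + cv^2))``, so the stated
coefficient of variation applies on the ratio scale and the *geometric*
expectation (median) of the ratio equals the planted fold -- which makes
geometric-mean recovery the well-defined estimation target.  The reference
animal's ratio to itself is identically 1.  Missing data are introduced by
dropping whole (protein, run) combinations uniformly at random, reproducing
the run-to-run coverage variability of real multi-run designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import reverse_complement

DEFAULT_BASE_COMPOSITION = {"A": 0.26, "T": 0.26, "C": 0.24, "G": 0.24}


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic reporter-ratio experiment.

    true_fold_changes maps protein accession -> KO/WT multiplicative effect;
    proteins absent from the map get fold 1 (null).  ``cv`` is the
    coefficient of variation of the multiplicative noise; ``missing_run_rate``
    is the probability that a (protein, run) combination is dropped for all
    animals.
    """

    n_proteins: int = 769
    n_animals_per_group: int = 4
    n_runs: int = 4
    true_fold_changes: Mapping[str, float] = field(default_factory=dict)
    cv: float = 0.2
    missing_run_rate: float = 0.4
    seed: int = 0

    def __post_init__(self):
        for name in ("n_proteins", "n_animals_per_group", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if not 0 <= self.missing_run_rate <= 1:
            raise ValueError(
                f"missing_run_rate must be in [0, 1], got {self.missing_run_rate}")
        bad = {k: v for k, v in self.true_fold_changes.items() if v <= 0}
        if bad:
            raise ValueError(f"true_fold_changes must be positive, got {bad}")

    def accessions(self) -> list[str]:
        return [f"SIM{i:05d}" for i in range(self.n_proteins)]


def planted_folds(n_proteins: int, frac_changed: float = 0.1, fold: float = 2.0,
                  seed: int = 0) -> dict[str, float]:
    """Assign ``fold`` to a random fraction of proteins, 1.0 to the rest."""
    rng = np.random.default_rng(seed)
    acc = [f"SIM{i:05d}" for i in range(n_proteins)]
    n_changed = int(round(frac_changed * n_proteins))
    changed = rng.choice(n_proteins, size=n_changed, replace=False)
    folds = {a: 1.0 for a in acc}
    for i in changed:
        folds[acc[i]] = fold
    return folds


def simulate_itraq(config: SimulationConfig) -> pd.DataFrame:
    """Generate a long-format reporter-ratio table from the design.

    Columns: ``accession, protein_name, genotype, animal_id, run_id, ratio``.
    The reference animal is ``WT1`` (its ratio is exactly 1 in every run it
    appears in); runs dropped for a protein are dropped for all animals.
    """
    rng = np.random.default_rng(config.seed)
    sigma = _lognormal_sigma(config.cv)
    acc = config.accessions()
    animals = (
        [(f"WT{i+1}", "WT") for i in range(config.n_animals_per_group)]
        + [(f"KO{i+1}", "KO") for i in range(config.n_animals_per_group)]
    )
    runs = [f"run{r+1}" for r in range(config.n_runs)]
    # decide per-(protein, run) presence first so the noise stream is stable
    present = rng.random((config.n_proteins, config.n_runs)) >= config.missing_run_rate
    # guarantee each protein appears in at least one run: the generator's
    # output must be analysable, and real designs report proteins only when
    # seen somewhere
    for p in range(config.n_proteins):
        if not present[p].any():
            present[p, int(rng.integers(config.n_runs))] = True
    noise = rng.standard_normal((config.n_proteins, len(animals), config.n_runs))
    rows = []
    for p, a in enumerate(acc):
        f = config.true_fold_changes.get(a, 1.0)
        for j, (animal, geno) in enumerate(animals):
            truth = f if geno == "KO" else 1.0
            for r, run in enumerate(runs):
                if not present[p, r]:
                    continue
                if animal == "WT1":
                    ratio = 1.0  # reference animal against itself
                else:
                    ratio = truth * float(np.exp(sigma * noise[p, j, r]))
                rows.append((a, f"protein {a}", geno, animal, run, ratio))
    return pd.DataFrame(
        rows,
        columns=["accession", "protein_name", "genotype", "animal_id", "run_id", "ratio"],
    )


def simulate_spot_table(
    n_spots: int,
    n_gels_per_group: int,
    effects: Mapping[int, float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
    absences: Sequence[tuple[int, str]] = (),
) -> pd.DataFrame:
    """Generate a 2DE spot-intensity table with planted group effects.

    ``effects`` maps spot id (0-based) -> KO/WT multiplicative effect
    (default 1 everywhere).  ``noise`` is the CV of multiplicative log-normal
    noise on intensities.  ``absences`` lists (spot_id, gel_id) pairs removed
    from the output, to exercise the all-gels inclusion rule.
    """
    if n_spots < 1 or n_gels_per_group < 1:
        raise ValueError("n_spots and n_gels_per_group must be >= 1")
    if noise < 0:
        raise ValueError(f"noise must be >= 0, got {noise}")
    effects = dict(effects or {})
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(noise)
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n_spots)
    gels = [(f"WTg{i+1}", "WT") for i in range(n_gels_per_group)] + [
        (f"KOg{i+1}", "KO") for i in range(n_gels_per_group)
    ]
    drop = set(absences)
    rows = []
    for s in range(n_spots):
        eff = effects.get(s, 1.0)
        for gel, group in gels:
            if (s, gel) in drop:
                continue
            mu = base[s] * (eff if group == "KO" else 1.0)
            val = mu * float(np.exp(sigma * rng.standard_normal())) if sigma > 0 else mu
            rows.append((gel, group, s, val))
    return pd.DataFrame(rows, columns=["gel_id", "group", "spot_id", "intensity"])


@dataclass(frozen=True)
class PromoterTruth:
    """A motif planted into a synthetic promoter.

    ``position`` is the negative offset of the motif's first (5'-most)
    plus-strand base; on the minus strand the reverse complement of ``motif``
    is written into the sequence at that window.
    """

    gene: str
    motif: str
    position: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.position >= 0:
            raise ValueError("planted position must be a negative offset")


def simulate_promoters(
    n_genes: int,
    length: int = 2000,
    base_composition: Mapping[str, float] | None = None,
    planted: Sequence[PromoterTruth] = (),
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random promoters with motifs planted at known offsets.

    Returns ``(promoters, truth)`` where promoters maps ``gene000...`` ids to
    upper-case sequences and truth is a DataFrame echoing the planted sites
    (gene, motif, position, strand).  Background composition defaults to the
    A/T-rich profile typical of mammalian upstream regions (A/T 0.26 each,
    C/G 0.24 each).
    """
    comp = dict(base_composition or DEFAULT_BASE_COMPOSITION)
    if abs(sum(comp.values()) - 1.0) > 1e-6:
        raise ValueError(f"base composition must sum to 1, got {sum(comp.values())}")
    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    probs = [comp.get(b, 0.0) for b in bases]
    genes = [f"gene{i:03d}" for i in range(n_genes)]
    seqs = {
        g: "".join(rng.choice(bases, size=length, p=probs)) for g in genes
    }
    for t in planted:
        if t.gene not in seqs:
            raise ValueError(f"planted motif names unknown gene {t.gene!r}")
        start = t.position + length
        if start < 0 or start + len(t.motif) > length:
            raise ValueError(
                f"motif does not fit in promoter of gene {t.gene!r} at "
                f"position {t.position}")
        insert = t.motif.upper() if t.strand == "+" else reverse_complement(t.motif.upper())
        s = seqs[t.gene]
        seqs[t.gene] = s[:start] + insert + s[start + len(insert):]
    truth = pd.DataFrame(
        [(t.gene, t.motif.upper(), t.position, t.strand) for t in planted],
        columns=["gene", "motif", "position", "strand"],
    )
    return seqs, truth


def simulate_gene_sets(
    universe: Sequence[str],
    n_sets: int = 10,
    set_size: int = 20,
    enriched_in: Sequence[str] = (),
    n_enriched_sets: int = 0,
    enrichment_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets over a universe, optionally loaded with hits.

    The first ``n_enriched_sets`` sets draw ``enrichment_fraction`` of their
    members from ``enriched_in`` (e.g. a simulated significant list), the
    remainder uniformly from the universe.
    """
    rng = np.random.default_rng(seed)
    uni = list(universe)
    hits = [g for g in enriched_in if g in set(uni)]
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        if i < n_enriched_sets and hits:
            n_hit = min(len(hits), int(round(enrichment_fraction * set_size)))
            chosen = list(rng.choice(hits, size=n_hit, replace=False))
            rest = [g for g in uni if g not in set(chosen)]
            chosen += list(rng.choice(rest, size=set_size - n_hit, replace=False))
        else:
            chosen = list(rng.choice(uni, size=min(set_size, len(uni)), replace=False))
        sets[f"set{i:03d}"] = sorted(chosen)
    return sets
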