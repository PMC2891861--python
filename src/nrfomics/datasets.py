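"""Packaged reference tables from the Nrf2-null vs wild-type liver study.

Three small published tables ship with the package as TSV fixtures:

* ``itraq1_per_animal.tsv`` -- the 108 differentially expressed proteins of
  the first isobaric-tag analysis (4 WT + 4 KO mice, 4 replicate runs), with
  the printed per-animal relative-expression values (run averages, relative
  to reference animal WT1), geometric means, 95% CI bounds, fold changes and
  BH-adjusted p-values.
* ``itraq2_summary.tsv`` -- the 38 significant proteins of the validation
  cohort (6 + 6 mice): genotype geometric means, CIs, fold change, p.
* ``gel2de_spots.tsv`` -- the 8 differentially expressed 2DE gel spots:
  normalised-intensity group means with SD, fold change, p.  (The KO mean of
  spot 4b, 0.017, is transcribed verbatim although it is inconsistent in
  magnitude with the printed fold change of 0.57 -- most plausibly a typo
  for 0.17.  It is kept as printed, never corrected.)

``accession_aliases.tsv`` maps accession aliases across the analyses: major
urinary protein 6 appears as P02762 in the isobaric-tag table and P11588 in
the gel table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_ANIMALS_WT = ["wt1", "wt2", "wt3", "wt4"]
_ANIMALS_KO = ["ko1", "ko2", "ko3", "ko4"]


def _data_path(name: str):
    return resources.files("nrfomics.data").joinpath(name)


def load_itraq_reference() -> pd.DataFrame:
    """Per-animal table of the first (training) isobaric-tag analysis."""
    with resources.as_file(_data_path("itraq1_per_animal.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_itraq_validation() -> pd.DataFrame:
    """Summary table of the second (validation) isobaric-tag analysis."""
    with resources.as_file(_data_path("itraq2_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_gel_reference() -> pd.DataFrame:
    """2DE spot summary table (normalised-intensity means, SD, fold, p)."""
    with resources.as_file(_data_path("gel2de_spots.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"spot_id": str})


def load_accession_aliases() -> dict[str, str]:
    """Accession alias -> canonical accession map across the analyses."""
    with resources.as_file(_data_path("accession_aliases.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["alias"], df["canonical"]))


def itraq_reference_animal_values() -> pd.DataFrame:
    """Reshape the reference table to long per-animal expression.

    Output columns match :func:`nrfomics.expression.aggregate_runs`:
    ``accession, protein_name, genotype, animal_id, aggregated_ratio,
    n_runs`` -- each printed per-animal value is already the average over the
    runs in which the protein was observed.
    """
    wide = load_itraq_reference()
    rows = []
    for _, r in wide.iterrows():
        for cols, geno in ((_ANIMALS_WT, "WT"), (_ANIMALS_KO, "KO")):
            for col in cols:
                rows.append({
                    "accession": r["accession"],
                    "protein_name": r["protein_name"],
                    "genotype": geno,
                    "animal_id": col.upper(),
                    "aggregated_ratio": float(r[col]),
                    "n_runs": int(r["n_runs"]),
                })
    return pd.DataFrame(rows)


def significant_lists() -> dict[str, list[str]]:
    """The three published significant accession lists, keyed by analysis."""
    return {
        "itraq_1": sorted(load_itraq_reference()["accession"].unique()),
        "itraq_2": sorted(load_itraq_validation()["accession"].unique()),
        "gel_2de": sorted(load_gel_reference()["accession"].unique()),
    }
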