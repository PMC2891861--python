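"""Cross-analysis concordance: the 20-protein candidate-biomarker panel.

Intersects the three packaged significant lists (training iTRAQ cohort,
validation iTRAQ cohort, 2DE gel analysis) under the documented accession
alias map (major urinary protein 6 appears as P02762 and P11588) and prints
the proteins recurring in at least two of the three analyses.
"""

from nrfomics import datasets, diffstats

lists = datasets.significant_lists()
for name, members in lists.items():
    print(f"{name}: {len(members)} significant proteins")

report = diffstats.concordance(
    lists, alias_map=datasets.load_accession_aliases(), k=2)
print(f"\nproteins in >= 2 of 3 analyses: {len(report.selected)}")
print(", ".join(report.selected))
print("\nVenn region counts:")
for region, count in sorted(report.venn_counts.items()):
    print(f"  {region}: {count}")
# the 20 recurring proteins form the reproducible Nrf2-dependent panel;
# glutathione transferases mu and pi appear in all three analyses
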