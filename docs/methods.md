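# Methods

## Expression model

Reporter ratios are treated as multiplicative quantities: a protein's value
for one animal is its reporter-ion intensity divided by that of a designated
reference wild-type animal within the same run. Replicate runs are collapsed
per animal by the arithmetic mean of ratios (a geometric option exists
behind `aggregate_runs(method="geometric")`; for the CVs typical of this
data — around 0.2 — the two differ by well under the 2-decimal reporting
precision). The reference animal's self-ratio is identically 1 and is
included in wild-type summaries, matching how the reference tables tabulate
it.

Group location is the geometric mean and group spread a normal-quantile
interval on the natural-log scale,
`exp(mean(ln r) ± z·sd(ln r)/√n)` with the sample (n−1) standard deviation
and `z = 1.96` by default. This specific form was chosen because it exactly
reproduces the packaged reference table's printed 95% CI cells (e.g. major
urinary protein 6: WT 1.07–1.53, KO 0.32–0.63) where a t-quantile interval
does not; `z` is configurable. Fold changes are ratios of unrounded
geometric means. With 2-dp-rounded per-animal inputs, 90 of the 108
reference rows reproduce their printed fold change exactly at 2 dp; the
remaining 18 differ by one unit in the last digit, which is the attainable
precision given input rounding, and the same one-ulp effect touches a few
GM/CI cells. Tests and the acceptance checks therefore assert fold changes
exactly and GM/CI cells to within one ulp of the printed precision.

Complete-case filtering retains a protein only when every animal of the
panel has an aggregated value; because the generator (and, in the emulated
design, the instrument) drops whole (protein, run) combinations, a protein
with any surviving run is automatically complete.

## Testing stage

Normality is screened per group with Shapiro–Wilk at α = 0.05 (the
acquisition pipeline this emulates reported Shapiro–Wilk plus F-tests);
either group failing routes the protein to the Mann–Whitney test, otherwise
an unpaired, pooled-variance Student t-test is used (Welch behind
`equal_var=False`). The t-test runs on ln-ratios by default, coherent with
the geometric-mean summaries; a raw-scale option is retained since printed
p-values cannot adjudicate the choice (per-run raw data are not published).
The F-test p-value is recorded alongside for audit. Mann–Whitney uses the
exact null distribution for untied samples of ≤ 8 per group and the
tie-corrected normal approximation otherwise. Constant groups are treated
as non-assessable for normality (routed to the rank test); two constant
equal groups yield p = 1 with a warning.

Benjamini–Hochberg adjustment (statsmodels' step-up; validated in tests
against a literal implementation of the definition) is applied across all
tested proteins. Acceptance requires both raw `p < 0.05` and adjusted value
`≤ 0.2` — the deliberately permissive FDR ceiling keeps weakly but
consistently co-regulated proteins in downstream network analysis. Both
thresholds are configurable.

Measured operating characteristics (recomputed by the test suite, not
asserted from memory): on 1000 simulated null proteins at the study design
(4 vs 4 animals, CV 0.2) the raw rejection rate at p < 0.05 falls within
0.05 ± 0.02 — slightly conservative, because the rank test's exact null at
n = 4 cannot reach 0.05 and the reference animal's exact-1 ratio removes one
noise draw from the wild-type group. Across 200 replicates with 10% of
proteins at fold 2.0, the mean realized false-discovery proportion of the
accepted set stays at or below 0.25, consistent with the BH ceiling of 0.2.

## 2DE spot statistics

Per gel, each matched spot's volume is expressed as a percentage of the
gel's total matched volume, which cancels gel-wide loading and staining
factors (tested: rescaling one gel's intensities leaves every fold change
unchanged). Normalisation is defined only on the full matched set; the API
refuses to renormalise subsets. Eligibility requires presence on all gels of
at least one group by default (`require="both"` available). Reports carry
both SD and SEM, explicitly labelled, because upstream conventions differ.
One packaged gel-table cell (spot 4b, KO mean 0.017) is inconsistent in
magnitude with its own printed fold change and is shipped verbatim with a
note, never corrected; recomputation tests target only rows whose printed
group means reproduce the printed fold change (spot 4a, GST mu).

## Concordance

Lists are intersected after mapping accessions through an explicit,
user-editable alias table rather than fuzzy name matching — the packaged
example (P11588 vs P02762 for major urinary protein 6) shows why the map
must be auditable. Duplicate canonical ids within one list raise an error.
The packaged three lists with that single alias yield exactly the published
20-protein panel.

## Promoter scanning

Coordinates: inclusive negative offsets, −1 being the base immediately 5′ of
the start codon; a width-13 site printed as "−1935 to −1923" spans 13
positions, fixing the convention. Both strands are scanned by default; a
minus-strand hit is a window whose reverse complement matches, reported at
plus-strand coordinates. Overlapping matches all count; no masking.

The default degenerate alphabet follows the consensus definition the
reference analysis stated — R = G/C and B = G/C/T, which is *not* standard
IUPAC — with `alphabet="iupac"` as the escape hatch; three circulated
spellings of the ARE core (`RTGABNNNGCA`, `RTGABNNNTCA`, `RTGABNNNGA`) ship
as named presets without adjudicating between them. `N` in a *sequence*
never matches any pattern letter, and PSSM windows containing `N` are
skipped.

PSSM weights are natural-log odds `ln((f(b,i)+ε)/((1+4ε)·p(b)))` with
pseudocount ε = 0.001 by default (required only when the matrix or
background contains zeros; ε = 0 with zeros is an error). The background is
strand-symmetric: p(A) = p(T) = mean A/T frequency of the scanned promoter
set, p(C) = p(G) likewise; the preset `MOUSE_PROMOTER_BACKGROUND`
(A/T 0.26, C/G 0.24) matches the panel this pipeline was built around. The
match threshold ("score > 1") is interpreted in natural-log units, the
patser convention. The probability matrix itself is an input file — the
original core-ARE matrix is not published — so all numeric matrix tests use
synthetic matrices, and published per-gene scores are not reproduction
targets.

## Enrichment

The pathway p-value is read literally as the upper-tail hypergeometric
probability of the observed overlap given the quantified universe; no
multiple-testing correction is applied by default (adjusted values are
available via `bh_adjust`). The proprietary pathway collection behind the
original analysis is replaced by user-supplied GMT files, so printed pathway
p-values are not reproduction targets either.

## Synthetic data

The generators emulate the study design: 4 (or 6) animals per genotype,
4 replicate runs, ratios against reference animal WT1, CV 0.2
multiplicative noise, and whole (protein, run) combinations dropped at rate
0.4 — chosen to match the run-to-run coverage variability of the emulated
design, where roughly 60% of protein-run combinations carried full data.
Noise is log-normal with `σ = sqrt(ln(1+cv²))` and `E[ln ratio] = ln(fold)`,
so the planted fold is the *median* (geometric expectation) of the ratio and
geometric-mean recovery is unbiased; the reference animal's ratio is exactly
1, as in real relative quantification. Each protein is guaranteed at least
one surviving run so every generated table is analysable.

What the generator does not emulate: peptide-level roll-up variance (noise
is protein-level), label/tag bias (the emulated design controlled it by tag
swapping, a design feature rather than a computation), correlated
missingness between proteins, and gel image artefacts. Passing tests
therefore demonstrate correctness of the statistics under the stated noise
model, not robustness to those real-data effects.

## Problem sizes and numerics

Simulation-based checks use 1000 proteins (type-I error) and 200 replicates
of 60 proteins (false-discovery proportion), sizes at which Monte-Carlo
error is comfortably inside the asserted bands while the whole suite runs in
well under a minute. All computation is double precision; reports render 2
decimal places to match the tabulated convention, and test comparisons on
that scale use the printed precision. Degenerate inputs (single-value CIs,
constant groups, zero-total gels, promoters shorter than the matrix) are
defined behaviours — warning, p = 1, error naming the gel, and a zero-window
summary row respectively — rather than silent propagation.
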