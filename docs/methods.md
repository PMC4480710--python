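# Methods

`mdm2strat` implements a pharmacogenomic stratification analysis for MDM2
inhibitors in three layers: dose-response quantification, rule-based panel
curation, and two downstream inferences — a biomarker search with honest
cross-validation, and a copy-number cutoff for functionally relevant *MDM2*
amplification derived from mutual exclusivity with *TP53* mutation.  This
note records the models, the tunable parameters, the numerical conventions,
and what the synthetic fixtures do and do not establish.

## Dose-response model

Percent of control is POC = 100 · (compound-well relative cell count) /
mean(vehicle-well relative cell count); stimulation above 100 is preserved.
Response curves are fitted with the four-parameter logistic

    y = A + (B − A) / (1 + (C/x)^D)

with `A` the low-dose asymptote (POC), `B` the high-dose asymptote, `C` the
inflection concentration (μM) and `D` the Hill slope.  Fitting is
multi-start nonlinear least squares (`scipy.optimize.curve_fit`) with
data-driven starts (A = max POC, B = min POC, C = geometric-mean dose,
D ∈ {0.5, 1, 2}) and bounds A, B ∈ [0, 200], C ∈ [min dose/100,
max dose·100], D ∈ (0, 10].  A fit is declared non-converged when no start
succeeds or when it improves on the constant-mean model by less than a 1e-6
relative SSE margin, which classifies exactly-flat curves as degenerate.

The IC50 is the concentration at which the *fitted* curve crosses 50 POC,
solved in closed form: x = C·((B−50)/(50−A))^(−1/D).  It is reported only
when the curve *descends* through the level (A > 50 > B) and the crossing
lies in (0, max dose]; otherwise the IC50 is right-censored and carries the
top tested dose (rendered `>50` at the default 50 μM).  The descent
requirement matters in practice: least-squares fits of flat insensitive
curves can wander into upward-sloping parameterizations whose formal
crossing sits far below the tested range, and an inhibitory IC50 has no
meaning there.  IC50 equals `C` only in the symmetric case A = 100, B = 0.

The alternative response metric is a normalized AUC: the trapezoidal
integral of POC over log10(dose), divided by 100 times the log-dose range,
so a flat POC = 100 line scores 1 and complete inhibition scores 0.

Replicate QC fails a line when the untreated-replicate coefficient of
variation exceeds `cv_threshold` (default 0.3) or the replicate mean falls
below `min_count` (default 200 relative-count units).  Both defaults are
package choices — the rule is standard but no canonical values exist — and
both are exposed in configuration.

## Panel curation cascade

Lines are excluded at the first failing stage of a fixed-order cascade:
replicate QC → missing genomic DNA → misidentification → redundancy →
viral p53-inactivating sequence → *TP53* heterozygosity.  Membership in the
curated set is order-independent (a line failing several stages is excluded
under any order); only the *attribution* of the exclusion reason depends on
the order, and the audit ledger records stage and reason per line, with
survivors + Σ(per-stage counts) always equal to the input size.

**Identity resolution.**  Percent genotype match between two SNP call
vectors is 100 · matched / compared, counting only positions with a
definite call (AA/AB/BB) in both.  Within-panel pairs at or above
`match_threshold` (default 80%, configurable; conservative for
array-genotype concordance) form synonymous clusters by connected
components; the lexicographically smallest member is retained and the rest
are excluded as redundant.  A line is called misidentified when the
reference profile filed under its *own* name disagrees (self-match below
threshold) while some differently-named reference profile matches above
threshold.  Requiring the contradicting own-name reference — and giving
cluster membership precedence — keeps "misidentified" and "redundant"
disjoint; without the own-name requirement, every novel duplicate of a
referenced line would be double-counted as misidentified.

**Viral flags.**  Any detected HPV16/18/31/33/45 E6, SV40 large-T or
adenovirus E1B sequence excludes the line: such lines carry wild-type
*TP53* alleles but no functional p53 protein, so they would contaminate the
wild-type stratum.  E1B is supported but expected all-negative.

**TP53 functional classification.**  Truncating, frameshift, splice,
exon-level deletion and rearrangement calls are inactivating by
consequence.  Missense calls are interpreted through a packaged
transactivation lookup (an extract of systematic yeast reporter-assay
classifications): a transactivation-competent missense (e.g. Q331R) leaves
the line functionally wild-type.  Missense variants absent from the table
default to non-functional with a logged warning — the conservative choice
for the downstream exclusivity analysis, since it can only under-count
wild-type tumors, never misclassify a mutant as wild-type.  Silent variants
are benign unless listed in `splice_disrupting_silent` (default: T125T,
a known splice-disrupting synonymous change), which forces mutant status.
Any heterozygous inactivating call makes the line ambiguous and excludes
it.  Lines with no calls are wild-type.

**Low-expression reannotation.**  After the cascade, wild-type lines that
sit in the lowest `expr_quantile` (default 0.1) of *TP53* transcript
expression *and* fail to respond (censored IC50 by default; an IC50
threshold rule is available) are reannotated mutant.  This encodes cryptic
inactivation invisible to exon sequencing (aberrant splicing, intronic
rearrangement).  The quantile/censoring rule is a package choice: the
phenomenon is identified in practice as a spatially distinct cluster in
response-vs-expression space rather than by a stated rule.  The supporting
regression of response on expression is computed and reported
(`expression_association`) but is deliberately not the decision rule.

## Response stratification and biomarker search

`check_complete_separation` asserts the headline claim: every wild-type
IC50 strictly below every mutant IC50, censored values ranking at +∞.

Responders are lines with IC50 at or below the lower quartile of all IC50s
(linear-interpolation quantile; censored values rank above all numbers and
are never responders).  With >75% of values censored the quartile is
infinite and every uncensored line labels responder; this degenerate corner
is documented rather than special-cased.

Expression batches are combined by per-probe-set least-squares calibration
(intercept + slope mapping batch 2 onto batch 1) fitted on the shared lines
(20 by default; at least 2 required); shared lines keep their batch-1
values.

Feature selection ranks probe sets by the response-term p-value of an OLS
model of expression on the binary responder label plus tissue-of-origin
dummies (a two-factor ANOVA; single-df t-test equals the partial F).  The
binary label is the default response term; the continuous metric is
available by passing it instead.  Constant or otherwise untestable probe
sets get NaN and rank last; ties break deterministically by probe-set id.
Single-tissue inputs degrade to a one-way model.

The classifier is a logistic regression on the single top feature plus
tissue dummies, with an L2 (ridge) penalty λ/2·‖β‖² on non-intercept
coefficients (λ default 1.0).  The penalty guarantees a finite optimum
under complete separation, which is routine at n ≈ 30–60 with a selected
feature.  A line is predicted responder iff the fitted probability is
strictly greater than 0.5; a tissue unseen in training contributes only the
intercept and gene term.  The fit is an in-package Newton/IRLS solver —
the permutation machinery needs thousands of fits and per-call overhead
dominates at these sizes — and is verified in the tests against
scikit-learn's equivalent penalized fit and against direct minimization of
the penalized likelihood.

Leave-one-out cross-validation repeats *both* feature selection and model
fitting inside every fold, so selection bias cannot leak into the accuracy
estimate; performance is overall percent of correct calls.  Folds whose
training labels collapse to one class predict that class and are flagged.

The permutation null shuffles responder labels only *within* tissue,
preserving per-tissue class margins exactly (singleton strata are fixed),
and reruns the full LOO per permutation (default `n_perm` 199; the
acceptance checks use 99).  The observed percentile uses mid-rank tie
handling — permuted results equal to the observed count half — because LOO
accuracy is discrete at these sample sizes and a strict `<` rule is biased
low under ties, spoiling the null calibration that the procedure exists to
provide; `tie="strict"` is available for the conventional count.  An
optional restriction drops tissues lacking either class before the
analysis, addressing class imbalance.

Mutation association screens each gene with at least one mutant line by
one-way ANOVA of the response metric (default log10 IC50, censored values
placed one decade above the top dose; AUC available) on mutation status;
genes mutated in every line are untestable and dropped.  P-values are
Benjamini–Hochberg adjusted (statsmodels step-up) across the retained
genes.

## Amplification cutoff and incidence projection

Copy number converts to log2 ratio against a diploid baseline of 2 (forced
by the pairing of 9.5 copies with ratio 2.25: log2(9.5/2) = 2.248).  A
tumor is flagged as carrying a functional (inactivating) *TP53* mutation
under the same classification rules as the panel, so
transactivation-competent missense variants are corrected to wild-type; any
inactivating call, including heterozygous ones, sets the flag (a single hit
suffices in tumors).

The co-occurrence curve counts samples with (log2 ratio ≥ cutoff AND
inactivating mutation) over a grid — default [0, 4] in steps of 0.05 —
and also reports the rate among samples above the cutoff; both are emitted
because the published trend statistic does not state which was fitted.  The
count is non-increasing in the cutoff for any input.  The exclusivity
threshold is the smallest grid cutoff at which the count is zero *and stays
zero* at every larger cutoff, which is robust to non-monotone noise in
user-supplied rate curves; a trend R² (OLS of count on cutoff; 0 by
convention for constant curves) accompanies it.

The rate table counts amplified samples per tumor type at the threshold and
display-rounds the percentage (one decimal below 10%, whole percent above).
Projected annual U.S. cases are round(displayed rate% × annual incidence),
summed into a total.  Under this single rounding rule the packaged
per-type counts and incidence figures reproduce the reference projections
(3,200; 812; 1,942; 333; 600; 15; 26) and the total of 8,166 exactly —
except the Melanoma and Breast rows, which differ by one case under *any*
single rounding rule (532.7 and 705.09 both round against the published
values); their opposite-signed errors cancel in the total.  These two rows
are documented inconsistencies, not targets.

## Synthetic fixtures: what they emulate and what they do not

The generators are pure functions of (spec, seed).  The default screen
registry plants 260 lines with disjoint ground-truth categories matching
the published cascade composition — 26 QC failures (split between high CV,
constructed with *exact* sample CV so classification is seed-independent,
and low means), 1 line without DNA, 5 misidentified (panel profile matches
a reference-only phantom while the own-name reference disagrees), 22
redundant (duplicates of curated parents, with ids sorting after the parent
so the representative rule keeps the parent; a few clusters of three), 8
viral, 25 heterozygotes — leaving 173 curated lines: 62 sequence-wild-type
(58 + 4 planted low-expressers) and 111 sequence-mutant.  Wild-type IC50s
are log-uniform on [0.01, 5] μM; mutant, viral and planted low-expression
lines are censored at 50 μM, mirroring the printed 0.01 μM to >50 μM range;
the exact distributions are free parameters.  Dose series use a 10-point
3-fold titration from 50 μM with Gaussian POC noise (sd 5 POC units,
clipped at zero).  Genotypes are 400 independent SNPs at fixed call
frequencies (random-agreement baseline ≈ 39%, far below the 80% threshold)
with ~4% no-calls.

The tumor table draws 3856 samples with a type mix proportional to the
packaged per-type totals, an inactivating-mutation rate of 0.4, a 3%
functional-missense rate, and a diploid-bulk + amplification-tail copy
number mixture; the mutant amplification tail is uniform on [1.0, 2.248) so
it reaches — but never crosses — the planted 9.5-copy threshold, and
samples at or above that threshold never carry an inactivating mutation.
With ~6 expected mutant-amplified samples in the top grid bin, the derived
threshold lands on 2.25 in essentially every seed (40/40 in development
runs); the acceptance criterion requires 19/20 seeds within one grid step.

What the fixtures do *not* emulate: probe-level array data, linkage between
SNPs, realistic tumor-type-specific copy-number landscapes, STR profiles,
sequencing reads, or any correlation between expression biomarkers and
response (the expression fixture is deliberately null apart from the *TP53*
probe).  Passing tests therefore demonstrate that the *rules and machinery*
behave as specified on data with the assumed structure — not that the
biological claims would replicate on new experimental data.  In the same
spirit, the published cross-validation percentiles (13th/67th) are
data-dependent outcomes of the original screen and are not reproduction
targets; the tests verify instead that the LOO/permutation machinery is
unbiased and calibrated on null data, which is the property that made those
percentiles interpretable.

## Problem sizes and determinism

Default analyses run in seconds: the 260-line cascade in under a second,
the full pipeline with 4PL refits and a 199-permutation null in tens of
seconds, the tumor-table derivation at n = 3856 in well under a second.
Calibration checks in the test suite use reduced sizes (24–30 lines, 20–25
probe sets, 99 permutations, 50–100 seeds) chosen so the binomial/KS
assertions have adequate power while the suite stays fast.  Per-stage seeds
derive from the master seed by hashing the stage name (blake2s, folded
below 2³¹), so stages are independently reproducible and summaries are
byte-identical under a fixed (config, seed).

## Known limitations

* The transactivation lookup is a compact extract, not the full published
  assay table; unknown missense variants fall back to non-functional with a
  warning rather than a database query.
* Identity resolution is SNP-vector concordance only — no STR algebra, no
  contamination modelling, no partial-match (mixed-culture) calls.
* The logistic model uses the single top feature by design; no multi-gene
  models, no gene-set methods.
* Censored IC50s enter the association metric at a fixed offset (one decade
  above the top dose) rather than through a survival-style likelihood.
* Tumor purity, subclonality and segmentation noise are out of scope for
  the copy-number analysis; the SEG-like input is a per-sample summary
  ratio.
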