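# Methods

## Profile definitions and thresholds

A sample enters the analysis only if its barcode carries TCGA sample-type
03 (primary blood-derived cancer, peripheral blood); bone-marrow aliquots
(09) are excluded. NK-cell presence is proxied by NKp46/NCR1 positivity.
Positivity everywhere means *strictly greater than* a threshold τ on the
RSEM-normalized scale, with τ = 0 by default: RSEM normalized_results
report unexpressed features as exact zeros, so "any reported expression"
is the natural reading of positivity, and it is what makes *solitary*
expression of a single splice variant a well-defined event. τ is
configurable per analysis (`tau=` on the model, `--tau` on the CLI) for
data where a noise floor is suspected.

The NKp44-1 profile requires variant 1 positive with variants 2 and 3
non-positive. A sample whose three isoform values are all ≤ τ is
classified NKp44-negative **even if** the gene-level NCR2 value is
positive — gene- and isoform-level quantifications are estimated
separately by RSEM and can disagree near zero; the isoform table is
authoritative for a splice-variant analysis.

Splice-variant percentages use the isoform sum v₁+v₂+v₃ as denominator.
When the sum is zero the fractions are undefined (NaN), never 0 or
100/3 — group summaries use NaN-aware means so negative-profile samples
do not dilute fraction statistics.

The high/low split of the NKp44-1 group sorts on v₁/NCR1 (the ratio of
normalized counts; normalizing by NKp46 expression corrects for NK-cell
content differences between blood samples) descending, breaking ties by
barcode so reruns are reproducible. The top half is HIGH; with odd n the
middle sample goes to LOW, the conservative choice because it shrinks the
putative poor-prognosis subgroup.

## Survival statistics

`stats.km_estimate` is the product-limit estimator with right-censoring;
individuals censored exactly at an event time are counted in the risk set
at that time. `stats.logrank_test` is the k-sample Mantel–Cox test:
at each distinct event time the expected events per group are the
hypergeometric means d·nⱼ/n, the variance–covariance matrix uses the
finite-population tie correction (n−d)/(n−1) (taken as 0 when n = 1), and
the chi-square is the quadratic form over k−1 groups with df = k−1.
Pairwise comparisons are reported unadjusted — multiplicity correction is
deliberately off by default so the pairwise p-values have their marginal
interpretation; `pairwise_logrank(..., holm=True)` adds a Holm column.

Survival analysis runs in an *events-only* mode by default
(`events_only=True`): records without an observed death are dropped with
a count. This mirrors retrospective cohorts where only cases with a
recorded day of death are plotted. Censoring-aware analysis is fully
supported (`events_only=False`) and is used in the censored simulation
studies.

Pearson correlation converts r to a two-tailed p through
t = r·√((n−2)/(1−r²)) on n−2 df. The unpaired t-test defaults to the
pooled-variance Student form — the convention of the spreadsheet/Prism
era this kind of analysis is compared against — with Welch available via
`pooled=False`.

## qPCR and assay arithmetic

Relative expression is 2^−ΔCt with ΔCt = Ct(target) − Ct(reference);
no primer-efficiency correction is applied to expression values (the
efficiency formula E% = (10^(−1/slope) − 1)·100 is provided separately
for primer QC; typical assay efficiencies of 98–103% would change 2^−ΔCt
by only a few percent per cycle, and the plain 2^−ΔCt method ignores it
by definition). Variant percentages from qPCR default to the
sum-of-variants denominator, which guarantees a 100% simplex; the
measured-total denominator (total-NKp44 primer signal) is available and
then percentages need not total 100. Specific cytotoxicity is
(experimental − spontaneous)/(maximum − spontaneous)·100; values outside
[0, 100] are reported as-is with a warning because clipping would bias
averaged replicates.

## Synthetic cohort generator

The generator emulates the *structure* of a TCGA LAML-like
peripheral-blood cohort, not its biology. Per sample within a generating
group: splice-variant fractions from the group's Dirichlet; total NCR2
from a log-normal (default log-mean 3.4, log-SD 0.8, i.e. median ≈ 30
normalized units — plausible for an inducible receptor in a mixed blood
sample, chosen once as no empirical distribution is available);
gene-level NCR2 is the exact isoform sum before flooring; NCR1 from a
higher log-normal (log-mean 5.0) since NKp46 is constitutive on NK cells;
values below the detection floor (default 0.5 normalized units) are
emitted as 0, mimicking RSEM's reporting of near-zero isoforms.

Event times are Weibull under proportional hazards: with shape k and
baseline hazard λ (default 1/365 events/day, exponential at k = 1), group
hazard ratio h, T = (−ln U / (λᵏ·h))^(1/k). Censoring is a Bernoulli
indicator with probability `censor_rate`, independent of group; a
censored record's time is drawn uniformly within its latent event time.
Default censor_rate = 0 because the events-only analysis mode is the
primary target. Barcodes use a fixed dummy tissue-source site and plate
with zero-padded participant indices, sample type 03, analyte T.

The default NKp44-1 group Dirichlet is (15, 0.01, 0.01): the generating
notion of that profile is *solitary* variant-1 expression, so variants 2
and 3 are sub-detection in ≈99% of draws. The NKp44-2/3 group uses
(2, 0.7, 2) — co-dominant variants 1 and 3 with dull variant 2, the
pattern described for that profile. The NKp44-negative group has all
isoforms at 0 via `nkp44_expressed=False`.

What the generator does **not** model: cell-type mixture/deconvolution,
tumor purity, read-level noise or quantification uncertainty, dependence
between expression and survival beyond the group label, or informative
censoring. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and the calibration/power of its statistics under
clean generating assumptions — not robustness to the messiness of real
cohorts.

## Simulation study sizes

`calibration.logrank_type_i_error` uses two exchangeable Weibull groups
of 50 with 5000 replicates: the Monte-Carlo standard error on a
rejection rate near 0.05 is then ≈0.003, small against the width of the
0.04–0.06 calibration band. `calibration.pipeline_power` runs the full
model fit on 500 seeds at n = 100/group, hazard ratio 2 for the NKp44-1
group and 20% censoring. `classification_recovery` uses one 200-sample
cohort split across the three profiles. The permutation cross-check of
the log-rank p uses two groups of 8 with crossing hazards and 50,000
label permutations (permutation SE ≈ 0.002). These sizes are the
package's documented study conditions; all replicate seeds are spawned
from a single base seed.

## Numerical and degenerate-input choices

* Log-rank: the quadratic form solves the (k−1)×(k−1) system directly and
  falls back to a pseudo-inverse if singular; the statistic is clamped at 0.
* A log-rank call with every record censored, an empty group, or a single
  group is an error, not a NaN; inside the pipeline a pairwise comparison
  whose groups cannot be tested is reported as NA instead.
* Pearson requires n ≥ 3 and nonzero variance; |r| is clipped to 1 before
  the t transform and |r| = 1 returns p = 0.
* Equal-length zero-variance t-test inputs return t = 0, p = 1.
* Duplicate aliquots of one participant are collapsed keep-first by
  lexicographic barcode (configurable, or disabled) before classification.
* Samples with a classification but no clinical record are excluded from
  the survival stage with a warning and a count in the report.

## Known limitations

* The isoform-id → splice-variant alias table must be supplied for isoform
  files that do not use the RefSeq accessions of the NCR2 transcripts;
  there is no automatic id mapping.
* Only the RSEM normalized_results dialect is read (no raw counts, FPKM,
  or GDC downloads).
* No Cox regression or hazard-ratio estimation: group comparison is purely
  nonparametric, matching the analysis this package operationalizes.
* NKp30/NCR3 splice-variant columns are carried through untouched for
  user inspection; no functional scoring is attached to them.
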