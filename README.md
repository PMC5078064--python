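# nkp44var

NKp44/NCR2 splice-variant profiling and survival association for
RSEM-quantified RNA-seq cohorts.

## The problem

NKp44 (CD336, encoded by *NCR2*) is a natural-cytotoxicity receptor
expressed by activated NK cells. Its mRNA is alternatively spliced into
three variants: NKp44-1 carries a cytoplasmic ITIM (an inhibitory motif),
while NKp44-2 and NKp44-3 lack it. In AML cohorts, total NKp44 expression
carries no prognostic signal — but samples whose NK compartment expresses
**only NKp44-1** form a distinct profile associated with poorer survival.
This package implements that analysis end to end for anyone working with
TCGA-style bulk RNA-seq: the splice-variant fraction computation, the
profile classification, and the survival comparison, together with the
qPCR and functional-assay arithmetic used to validate such profiles at the
bench, and a synthetic cohort generator so the whole chain is testable
without any data download.

## Method

For each peripheral-blood sample (TCGA sample-type 03), with v₁, v₂, v₃
the RSEM-normalized expression of the three *NCR2* isoforms:

* **fractions** — fᵢ = 100 · vᵢ / (v₁+v₂+v₃), undefined when the total is 0;
* **profile** — samples failing the NKp46/NCR1 positivity filter are
  excluded; otherwise *NKp44-1 profile* iff v₁ > τ and v₂, v₃ ≤ τ,
  *NKp44-2/3 profile* iff v₂ > τ or v₃ > τ (with or without NKp44-1),
  *NKp44-negative* otherwise (default τ = 0: any reported expression counts);
* **high/low split** — the NKp44-1 profile group is median-split on
  v₁/NCR1 into HIGH and LOW subgroups;
* **survival** — Kaplan–Meier product-limit curves per group,
  Ŝ(t) = ∏_{tᵢ≤t} (1 − dᵢ/nᵢ), compared with the k-sample log-rank
  (Mantel–Cox) test with the (n−d)/(n−1) tie correction, pairwise and
  unadjusted (a Holm option exists);
* **correlations / group contrasts** — Pearson r with the two-tailed
  t-transform p, and the unpaired two-tailed t-test (pooled variance by
  default).

The survival statistics are implemented from first principles in
`nkp44var.stats` and are checked in the test suite against brute-force,
permutation and lifelines oracles. Assay arithmetic (2^−ΔCt expression,
qPCR variant percentages, dilution-slope primer efficiency, specific
cytotoxicity, control-normalized readouts, synapse F-actin MFI ratios)
lives in `nkp44var.assays`.

## Worked example

Simulate a cohort with the study-like group structure (24 NKp44-1 /
12 NKp44-2/3 / 60 NKp44-negative samples, hazard ratio 2 for the NKp44-1
group) and run the full analysis:

```sh
nkp44var simulate --seed 11 --out demo
nkp44var report --expr demo --out demo/report
```

which prints (abbreviated):

```
Profile groups:
  NKP44_1              n=24   mean %variants (1/2/3) = 100.0/0.0/0.0
  NKP44_2_3            n=12   mean %variants (1/2/3) = 48.8/19.7/31.4
  NKP44_NEG            n=60   fractions undefined
  NKp44+ share of NKp46+ samples: 38%

Overall log-rank (Mantel-Cox): chi2=2.453 df=2 p=0.2932
Pairwise log-rank, NKp44-1 high/low split:
  NKP44_1_HIGH   vs NKP44_1_LOW    (n=12/12)  p=0.0133
  ...
Corr. summed isoforms vs gene-level NCR2: r=1.0000 p=9.325e-129 n=36
```

The classification recovers the generating profiles exactly (the NKp44-1
group shows solitary variant-1 expression, f₁ = 100); the summed-isoform
vs gene-level correlation is r = 1 because the generator builds gene-level
*NCR2* as the isoform sum; and at this cohort size a hazard ratio of 2 on
a 24-sample group is detected in the high/low contrast but not reliably in
every pairwise comparison — power at n = 100/group is quantified by
`nkp44var.calibration.pipeline_power`.

The same analysis runs on real RSEM `*.rsem.genes.normalized_results` /
`*.rsem.isoforms.normalized_results` file sets through the library API:

```python
from nkp44var import Nkp44SurvivalStudy
res = Nkp44SurvivalStudy.from_directory("expr/", "clinical.tsv").fit()
print(res.summary())
res.to_tsv("out/")
```

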