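# budsig

Derivation and evaluation of a **tumor-budding gene signature (TBS)** from
segment-level spatial transcriptomics, with projection to bulk and
single-cell RNA-seq.

Tumor budding — single tumor cells or small clusters detaching at the
invasion front — is a strong adverse prognostic feature in head and neck
squamous cell carcinoma, but it is scored visually on H&E slides.  `budsig`
implements the computational route from digital spatial profiling counts to
a molecular budding score: segment QC and background (LOQ) filtering,
upper-quartile normalization, paired/unpaired Wilcoxon differential
expression with an intersection-based signature definition, signature
scoring on spatial, bulk and single-cell matrices, gene-set enrichment,
differential co-expression networks with a permutation null, and
ROC / survival / drug-response evaluation.  A synthetic-data module
generates inputs with the statistical structure the analysis assumes, so
the whole pipeline is testable without any download.

The package is aimed at computational biologists who want either the
individual building blocks (each stage is an importable function on pandas
DataFrames) or the one-command pipeline.

## The statistics at the core

* **Limit of quantification.** Each segment carries negative-control
  probes; with NegGeoMean and NegGeoSD their geometric mean and geometric
  standard deviation, a gene is detected when its count reaches
  `LOQ = max(2, NegGeoMean · NegGeoSD²)`.  Segments detecting < 5% of genes
  and genes detected in < 10% of segments are removed.
* **Q3 normalization.** Every segment is rescaled so its 75th-percentile
  gene count equals the geometric mean of all segments' raw Q3 values.
* **Signature derivation.** Six Wilcoxon contrasts compare tumor buds
  against every other (segment type, compartment) group — signed-rank when
  paired within cases, rank-sum otherwise — each BH-adjusted at FDR 5% with
  an absolute fold-change gate of 1.5.  The up-signature is the
  intersection of the "up" calls of all six contrasts.
* **Scoring.** `TBS(sample) = mean_i log2(x_i + 1)` over the signature
  genes `i` (log-normalized single-cell values are averaged as-is).  The
  fixed 15-gene pEMT program (SERPINE1 … VIM) is scored the same way.
* **Enrichment.** Fold change of percentages `FC = (n/K)/(k/N)` for an
  overlap `n` between a `K`-gene query and a `k`-gene set in an `N`-gene
  universe, with a one-sided Fisher exact test.
* **Differential correlation.** Spearman ρ per gene pair and condition;
  candidates need |ρ| > 0.8 (FDR 1%) in at least one condition; the
  Fisher-Z difference `ΔZ = atanh(ρ_A) − atanh(ρ_B)` is tested against a
  case-label permutation null and gated at |ΔZ| ≥ 1.4.
* **Evaluation.** Rank-based AUC with DeLong 95% CI; Kaplan-Meier /
  log-rank and Cox proportional hazards; a CutoffFinder-style log-rank
  scan over score cutoffs; per-compound Spearman screens of score vs
  viability log-fold change at FDR 5%.

## Worked example

`examples/02_derive_signature.py` simulates the reference cohort design — 24 budding
and 19 non-budding cases, 28 genes overexpressed 2.5× in bud segments —
and re-derives the signature:

```
bud_vs_bud_stroma                   (paired): 26 genes up in buds
bud_vs_bulk_budding                 (paired): 26 genes up in buds
...
bud_vs_immune                       (unpaired): 26 genes up in buds

intersection signature: 26 genes (26 of the 28 planted; genes dropped
earlier by the LOQ filter cannot be recovered)
```

All 26 derived genes are planted ones — two planted genes drew a low
baseline expression and fell to the LOQ detection filter, so no method
could recover them.  `examples/06_survival_and_roc.py` then evaluates a
signature on a simulated 300-patient cohort (true hazard ratio 1.5, 30%
censoring):

```
score separates budding from non-budding samples: AUC = 0.88 (95% CI 0.84-0.92)
median-split log-rank p = 0.00671
Cox HR for the latent high state = 1.59 (95% CI 1.19-2.12; simulated truth is 1.5)
```

The remaining scripts in `examples/` cover single-cell scoring with the
bimodal mixture cutoff, enrichment, differential correlation networks, the
drug screen, and the full pipeline
(`budsig run --config examples/pipeline_config.yaml`), which writes every
stage's outputs plus a checksummed `manifest.json` that reproduces byte for
byte under a fixed seed.

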