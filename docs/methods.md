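# Methods

This note records the models, numerical conventions and design choices
behind `budsig`, and what its synthetic-data tests do and do not establish
about real data.

## Segment QC and LOQ filtering

Digital spatial profiling yields one expression profile per segment (an
ROI/AOI combination), each with a handful of negative-control probes.
Sequencing-level filters remove segments with < 40,000 deduplicated reads,
< 80% stitched reads, < 70% aligned reads, < 50% saturation, or > 1,000
no-template-control counts.  All comparisons are inclusive at the boundary
(a segment exactly at a "minimum" passes), and a missing metric is an
error rather than a silent pass.

The per-segment limit of quantification is
`LOQ = max(2, NegGeoMean · NegGeoSD²)`, i.e. two geometric standard
deviations above the negative-control geometric mean, clamped at 2 counts.
Geometric statistics are computed on natural logs with sample (ddof = 1)
standard deviation; zero counts are replaced by 0.5 before the log
(positive counts are untouched, so all-equal negatives give
`LOQ = max(2, count)`).  "Detected above LOQ" is read inclusively
(count ≥ LOQ) to avoid knife-edge exclusion at the clamp value of 2.
Segments detecting < 5% of genes go first; genes detected in < 10% of the
remaining segments go second; the order is fixed and an empty result names
the stage that emptied it.

## Q3 normalization and case-level aggregation

Each segment is scaled so that its 75th-percentile gene count equals the
geometric mean of all segments' raw 75th percentiles.  Percentiles use
linear interpolation between order statistics.  Because the target is
itself the geometric mean of the per-segment Q3s, the operation is
idempotent.  Q3 is computed over all retained genes after the LOQ filters;
computing it pre-filter is possible by calling `q3_normalize` on the
unfiltered matrix.  Case-level matrices are arithmetic means of normalized
segment profiles within (case, segment type, compartment).

Matrices written to TSV use `%.17g` formatting and are read back with
round-trip float parsing; score computations pin the array layout before
reducing.  Together these make every pipeline output bit-reproducible
whether a stage ran from memory or resumed from disk.

## Differential expression and the signature

Contrasts operate on case-level values: Wilcoxon signed-rank for paired
(within-case) comparisons — exact p when n ≤ 25 without ties, normal
approximation with continuity correction otherwise, zero differences
dropped — and Mann-Whitney rank-sum for unpaired ones.  P-values are
BH-adjusted within each contrast.  A gene is differentially expressed when
q ≤ 0.05 **and** its absolute fold change strictly exceeds 1.5.  Fold
change is the ratio of per-group arithmetic means of Q3-normalized
case-level values with a pseudocount of 1 added to both means; this is the
most common convention for this platform and guards against near-zero
denominators.  The paired alternative (mean of per-case log2 ratios) gives
the same calls on the synthetic data and was not made the default.

The budding signature is the intersection of the "up" calls across the six
bud-versus-everything contrasts (bud vs adjacent stroma, budding bulk,
budding-bulk stroma — paired; vs non-budding bulk, non-budding-bulk
stroma, pooled immune — unpaired), in lexicographic gene order.

## Scoring

A signature score is the mean of `log2(x_i + 1)` over the signature genes
(pseudocount 1, configurable; single-cell log-normalized values averaged
directly; an unaveraged sum is available behind `statistic="sum"`).  The
mean rather than the sum is used so scores are comparable when signature
genes are missing from a matrix (missing genes are dropped and the mean
renormalizes; an error policy is available).  The 15-gene pEMT program
(SERPINE1, TGFBI, MMP10, LAMC2, P4HA2, PDPN, ITGA5, LAMA3, CDH13, TNC,
MMP2, EMP3, INHBA, LAMB3, VIM) is scored identically.

Single-cell preprocessing excludes cells with < 200 or > 8,000 detected
genes or > 10% mitochondrial UMIs (gene prefixes configurable; absence of
mitochondrial genes downgrades the filter to a recorded warning), drops
genes expressed in < 0.1% of remaining cells, and log-normalizes as
`log(1 + count/total · 10,000)`.

High/low classification uses a two-component Gaussian mixture (EM with 10
restarts at a fixed seed).  The cutoff is the root of
`w₁·N(x|μ₁,σ₁) = w₂·N(x|μ₂,σ₂)` between the component means.  The fit is
flagged non-bimodal unless (a) the two-component BIC beats one component,
(b) the means are > 0.5 pooled SDs apart, and (c) the fitted mixture
density actually dips between the means — condition (c) matters because a
two-component fit can win the BIC comparison on merely *skewed* unimodal
score distributions.  Scores at the cutoff classify low.  Histological
classes follow the fixed rule TB = 0 → non-budding, 0 < TB < 6 →
low-budding, TB ≥ 6 → high-budding.

## Enrichment

The fold change of percentages is `FC = (n/K)/(k/N)`: the fraction of the
K-gene query inside the k-gene set over the set's share of the N-gene
universe.  FC = 0 iff the overlap is empty and FC is maximal at full
containment.  A variable assignment that swaps n and k circulates in some
descriptions but shrinks with growing overlap and cannot reproduce the
magnitudes this score is meant to produce; it is available behind
`printed_form=True` for comparison and used nowhere.  Significance is a
one-sided Fisher exact test (enrichment direction) with BH across the
catalog only.  The universe defaults to the catalog union; overriding it
with the measured genes is supported and avoids inflating N with genes
that could never appear in a query.

## Differential correlation

For each compartment pairing, Spearman correlations are computed for all
gene pairs per condition (rank-transform then normalized inner product;
constant genes give missing values and leave downstream analysis).
Candidate pairs need |ρ| > 0.8 (strict) with BH q ≤ 0.01 within their
condition, in at least one condition.  For candidates, the observed
Fisher-Z difference (|ρ| clamped at 1 − 10⁻⁶ before `atanh`) is compared
with a null built by shuffling *case profiles* — the joint x/y rows of a
case — between the two conditions, preserving group sizes; the case, not
the segment, is the exchangeable unit.  Empirical p-values are per pair
from that pair's own permutation distribution with an add-one correction,
`p = (1 + #{|ΔZ*| ≥ |ΔZ|}) / (B + 1)`, BH-adjusted across candidates;
edges additionally require |ΔZ| ≥ 1.4 (inclusive).  BH is applied before
the |ΔZ| gate; the order does not change the kept set because the gate is
p-independent.  Edges labelled "gained" have the larger |ρ| in condition
A; sign flips keep that rule and carry a separate flag.  The default
permutation count is 100,000; tests and the demo pipeline use 300-1,000.
Networks key nodes by (gene, compartment), annotate TF/ligand/receptor
status case-insensitively, and partition components into > 8 members, 3-8,
and pairs.

## Evaluation

AUC uses the Mann-Whitney statistic with midrank tie handling; its 95% CI
is DeLong's placement-value variance (no installed package provides this;
it is ~20 lines and tested against pair enumeration).  The group
comparison p is the two-sided Wilcoxon on the same scores.  Kaplan-Meier,
log-rank and Cox fits delegate to lifelines; categorical covariates are
dummy-coded with a dropped reference level, and fewer than 10 events per
term warns.  The survival-optimized cutoff scans every observed score
value leaving ≥ 10% of samples per side and returns the log-rank-p
minimizer together with the full profile; the minimized p is descriptive
only, since scanning cutoffs biases it low.  A median split is provided
alongside.  The drug screen computes per-compound Spearman ρ of score vs
viability log-fold change over non-missing lines (≥ 10 required), BH
across compounds; negative ρ at q ≤ 0.05 flags sensitization.

## Synthetic data: what it emulates and what it does not

Counts are negative binomial via a gamma-Poisson mixture
(`var = μ + αμ²`, default dispersion α = 0.1) around
`library factor × gene mean`, with log-normal library sizes (σ = 0.3) and
log-normal gene means (natural-log mean 3, σ = 1).  Negative probes draw
from a segment-type-independent background (mean 3).  The default design
mirrors the reference cohort: 24 budding cases (bud, budding bulk, both
adjacent stromata, immune) and 19 non-budding cases (non-budding bulk,
stroma, immune), two segments per type.  Planted signature genes multiply
the mean by the configured fold (default 2.5) in bud tumor segments of
budding cases only.  QC failures are injected per metric as independent
Bernoulli events (default 5%) so each filter branch is exercised.

Correlation pairs share a per-case latent Gaussian factor applied on the
log-mean scale (σ = 1.5) in the gated condition only; the latent
correlation is inflated by the estimated count-noise-to-signal variance
ratio so the achieved case-level Spearman lands near the configured
target (measured ≈ 0.885 for a target of 0.9 at 20 cases).

Single-cell states draw from a two-component Gaussian mixture that scales
the signature genes' Poisson rates in malignant cells; low-coverage and
high-mitochondrial cells are injected at 2% / 3%.  Bulk cohorts couple a
uniform latent bud fraction to signature expression (log2 slope 2),
Poisson TB counts (log-rate slope 1.5), and exponential survival with
hazard `h₀ · HR^{high}` (h₀ = 0.02/month, high = latent fraction > 0.5);
administrative censoring is uniform on (0, t_max) with t_max solved
numerically to hit the requested censoring rate.  Drug panels set
`LFC = intercept + slope · latent + ε` per compound.

None of this emulates spatial autocorrelation between neighboring ROIs,
compartment segmentation errors, probe-level sequence biases, batch
effects, or immune contamination of stroma.  Passing tests therefore
establish that the *procedures* are implemented correctly and calibrated
under their own assumptions — not that the biological conclusions transfer
to any real cohort, which requires the accession data.

## Problem sizes and known limitations

Tests and the acceptance script run at the reference case counts (24 + 19)
with 40-300 genes, 200-1,000 permutations, 300-sample cohorts and
20-50 replicates — sizes chosen so the full suite completes in a few
minutes on one CPU while every statistical property remains measurable.

One check is left failing by design of the conditions it states: detecting
a planted Spearman change of 0.9 → 0 at 20 cases per condition with the
q ≤ 0.01 *and* |ΔZ| ≥ 1.4 rule in ≥ 80% of replicates.  The sampling
standard deviation of an estimated Fisher-Z difference at n = 20 is
≈ √2 · 1.03/√17 ≈ 0.35 while atanh(0.9) ≈ 1.47, so the |ΔZ| gate passes
roughly half of such replicates even for an ideally planted correlation;
≥ 80% detection would require a true correlation around 0.955.  The
measured detection rate (≈ 30-40%) is reported as-is by the acceptance
script.  With 24 paired cases the same arithmetic applies
to real data: single-pair correlation changes of this magnitude sit at the
edge of detectability, which is why the procedure screens many pairs
rather than any one.
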