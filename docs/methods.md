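# Methods

This note documents the models, parameter choices and limitations behind
`episig`. It complements the API docs; nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data model

The generator (`episig.simulate`) emulates an Illumina EPIC-style
case/control methylation study with known planted structure.

**Beta distribution.** Each probe has a logit-scale baseline drawn from a
three-component mixture: 45% low-methylation (logit-normal around
β ≈ 0.1), 45% high (β ≈ 0.9) and 10% intermediate. This reproduces the
characteristic bimodality of array methylomes. Per-sample values are
logistic(baseline + ε) with ε ~ N(0, σ), σ = `noise_sd_logit` = 0.45
(natural-logit units), giving a beta-scale spread of roughly 0.02–0.04 at
the modes and up to ~0.1 mid-range — comparable to inter-individual spread
on real arrays. The default satisfies the design requirement that
non-signature probes show mean |Δβ| < 0.01 between case and control groups
at the default study size. Betas are clipped to (1e-6, 1−1e-6) so
M-values stay finite.

**Planted signature.** Signature probes (default 200 of 20,000) receive a
case-only beta-scale shift drawn from `delta_range` (default 0.05–0.15,
all hypomethylating — matching the typical effect sizes of
neurodevelopmental episignatures). Because the logistic is nonlinear, a
naive logit-shift would bias the realized beta difference (Jensen's
inequality); instead the case and control logit-means are solved by
Gauss–Hermite quadrature + bisection so the planted Δβ is exact in
expectation. About 30% of the signature is planted as contiguous clusters
of ~6 densely spaced probes (all inter-probe gaps ≤ 900 bp) starting from
near-saturated baselines — emulating coherent regional methylation loss so
that region-level callers have true regions to find; the rest is
scattered. Probe spacing itself is bimodal (dense CpG clusters within
open-sea stretches).

**Samples.** Roles: discovery cases, outlier cases (carry *zero* planted
delta — they model clinically suspected cases without the episignature),
validation cases and one VUS carrier (both carry the full delta), a
control pool, and `n_other_cohorts` "other disorder" cohorts, each with
its own signature sharing a small Jaccard overlap (default 0.05) with the
primary one. Sexes are allocated deterministically balanced within each
role, which guarantees that exact sex/array-stratified matching from the
default 100-control pool is feasible by design. Ages are uniform 2–60;
six blood-cell fractions come from a Dirichlet centred on adult whole
blood (granulocytes ≈ 55%); an optional parameter correlates one cell
fraction with case status to exercise covariate adjustment (off by
default). Detection p-values are ~U(0, 0.01) with a 1e-4 per-measurement
failure rate (failures ~U(0.1, 1)).

**What the generator does not emulate:** probe type I/II chemistry bias,
age- or batch-related drift, genotype artifacts behind the SNP flags, or
cell-composition differences between disorders. Passing tests therefore
demonstrate correctness of the *pipeline logic and statistics* under a
realistic signal/noise regime, not performance on any particular real
dataset.

## Preprocessing

Probes are removed if they fail detection (p > 0.1) in **any** retained
sample — the any-sample reading of the detection rule, applied after
sample QC (samples with > 5%, strictly, failed probes are dropped first)
— or lie on chrX/Y, overlap SNPs, or are cross-reactive. Per-rule tallies
and the unique union are both reported. Matching is exact on sex and
array and greedy nearest-neighbour on age, processing cases in descending
age order with seeded tie-breaks; it is a reproducible stand-in for
propensity matching, which is not identifiable from the method
description alone. The default ratio is 1:3 (the realized design of the
reference study — 60 controls for 20 cases — although 1:5 is also quoted;
both are supported). PCA coordinates are exposed as a batch/outlier
diagnostic with no decision rule attached.

## Differential methylation

Per-probe OLS on M-values with the group indicator and covariates
(categoricals dummy-encoded dropping the first level). Five of the six
cell-composition columns enter the model; the sixth is dropped because
the fractions sum to one and would be collinear with the intercept.
Variance moderation fits a scaled inverse-chi-square prior by the
closed-form moments-of-log-variance method (digamma/trigamma moment
matching with Newton inversion of the trigamma), chosen over iterative ML
for determinism and testability. When the observed variances are
(near-)identical the prior degrees of freedom diverge: they are capped at
1e6 and the prior scale set to the geometric mean of the variances, so
the posterior variances equal the observed common value. `df_prior = 0`
disables moderation (moderated t ≡ ordinary t). Multiple testing uses
Benjamini–Hochberg FDR; the reference workflow reports only "adjusted
p-values" with ranges (up to ~0.44) that imply an FDR-style rather than
Bonferroni adjustment, so BH is assumed and stated here.

## Probe selection

The three ranking steps operate on a candidate set restricted by a DMP
evidence floor — BH p < 0.01 **and** |Δβ| ≥ 0.05 (both configurable,
`None` disables). The floor matches the DMP definition used for cohort
comparison and mirrors the practice of selecting from a
differentially-methylated-probe list; without it, a fixed top-k2 would
pad the candidate ranks with null probes whenever the true signal
comprises fewer than k2 probes, and the selected set would not be
interpretable as an episignature. The steps themselves are pure top-k
filters: k1 = 1000 (product of |Δβ| and −log₁₀ p; zero p floored at the
smallest positive normal float; ties by smaller p then probe id),
k2 = 500 (folded Mann–Whitney AUC; ties by probe id), then greedy
decorrelation at |r| > 0.60 scanning in descending step-2 AUC order —
the AUC is the most recent ranking criterion, and the scan order is
otherwise unspecified. Correlations are computed on beta values across
all training samples; −log base 10 is used in step 1 (the choice is
rank-invariant for that step). Moderated p-values feed step 1.

## Diagnostics and cross-validation

Hierarchical clustering is Ward on Euclidean distance over the selected
probes, cut at two clusters; purity is majority-label agreement (an exact
50/50 cluster is credited to the case label — a documented tie-break that
cannot change two-cluster purity). MDS is classical Torgerson scaling
(double-centred squared distances, top eigenvectors) rather than SMACOF,
with the residual stress reported. Leave-25%-out CV partitions cases into
four folds per cycle so every case is held out exactly once every four
rounds (default rounds = 4); an equal fraction of controls is held out
alongside. Each round re-runs the differential-methylation fit and the
full selection on the training split only, then assigns held-out samples
to the nearer of the training case/control centroids on the selected
probes — a decision rule standing in for the visual co-clustering used in
practice. A case is flagged as an outlier when its MVP score is below 0.5
*and* it lands with the controls in at least half of its held-out rounds;
flagging iterates to a fixed point because removing one outlier sharpens
the signature and can expose another.

## MVP classifier

A linear SVM (C = 1) on raw beta values of the selected probes — unscaled
so the weights stay interpretable on the methylation scale — trained as
carrier vs everything else, with 75% of controls and of each other-disorder
cohort in training and the remainder held out for specificity checks.
The decision value is mapped to [0,1] by Platt sigmoid calibration with
the usual regularized targets, fitted on the training decision values; the
slope is parametrised as −exp(a), making the MVP score strictly increasing
in the decision value by construction. The binary one-vs-rest design
follows the per-disorder score plots of published evaluations; a
multi-class production classifier is out of scope. The VUS thresholds
(negative < 0.25, positive > 0.75) are reporting policy, not biology, and
are configurable.

## DMR calling

"Within 1 kb" is interpreted as a consecutive-significant-probe gap of at
most 1,000 bp on 1-based positions. Member significance defaults to BH
p < 0.05 and |Δβ| ≥ 0.05 (configurable); region statistics are the mean
member Δβ and the Fisher combination −2Σln p ~ χ²(2k). The Gaussian-kernel
smoothing of kernel-based region callers is deliberately not reproduced —
this caller implements the stated acceptance criteria exactly and is
validated against a brute-force chain enumerator; equivalence with any
kernel-based implementation is not claimed. BED export converts to
0-based half-open coordinates.

## Cohort annotation and comparison

CGI context: island (distance 0), shore (≤ 2 kb from an island boundary),
shelf (2–4 kb), inter-CGI. Gene context with precedence
promoter (≤ 1 kb upstream of a TSS) > promoter+ (1–5 kb) > gene body >
intergenic; the precedence for probes hitting multiple annotations is
artifact policy. The cohort DMP definition (|Δβ| ≥ 0.05, BH p < 0.01) is
consistent with the selection floor. Overlap matrices are row-normalized
percentages (asymmetric). Cohort trees use the union of per-cohort top-500
DMPs (by p-value; all DMPs when fewer), per-probe median beta across each
cohort's cases as the profile (beta, rather than M or Δβ, is assumed),
Euclidean distance and average linkage, exported as Newick.

## Problem sizes and determinism

The default study (20,000 probes, 200-probe signature, 20 + 2 + 9 + 1
cases, 100 controls, 3 × 10 other-disorder samples) is a scaled-down EPIC
array: it preserves the signal-to-background ratio regimes that matter
(1% of probes carry signal) while keeping a full discovery +
validation + null analysis fast enough to run many times over. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seed and design give bit-identical
datasets, selections, models and scores.

## Known limitations

- The evidence floor makes the selected-set *size* depend on study power;
  with very weak signals the signature can be empty (by design — an empty
  signature on null data is the correct answer).
- The outlier rule needs the outlier to fail both the classifier and the
  co-clustering gate; a case with a partial signature may legitimately
  remain in training.
- HGVS handling in the cohort module is a minimal rule set sufficient for
  the packaged table, not a general parser.
- The matching is greedy nearest-neighbour, not optimal assignment; with
  hostile age distributions it can be beaten on total age discrepancy.
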