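# episig

DNA methylation **episignature** discovery, validation and variant scoring
for rare-disorder cohorts, with a synthetic EPIC-like data generator that
plants known signatures so every stage can be verified against ground truth.

Episignatures are reproducible sets of CpG probes whose methylation pattern
separates carriers of pathogenic variants in a gene (here modelled on the
*TRIP12* / Clark–Baraitser syndrome cohort workflow) from matched controls.
They are used both as diagnostic biomarkers and to reclassify variants of
uncertain significance (VUS): if a VUS carrier's blood methylome matches the
episignature, that is functional evidence the variant disrupts the gene.

`episig` is a library first — import it and drive it from Python (see
`examples/`) — with a thin `episig` CLI for shell-driven runs.

## The method

Starting from a beta-value matrix B (probes × samples, β ∈ [0,1]) with
detection p-values, a sample sheet (age, sex, array, blood-cell
proportions) and a probe manifest:

1. **QC** — drop samples with > 5% failed probes (detection p > 0.1), then
   probes failing detection in any sample, on chrX/Y, SNP-overlapping or
   cross-reactive. Controls are matched 1:*k* per case, exactly on sex and
   array, nearest-neighbour on age (default *k* = 3).
2. **Differential methylation** — M = log2(β/(1−β)); per probe OLS
   `M ~ group + cell proportions`; residual variances shrunk by the
   empirical-Bayes moderated-t scheme
   (s²₍post₎ = (d₀s₀² + d s²)/(d₀ + d), prior fitted in closed form from
   the log-variance moments); BH-adjusted p-values; Δβ reported on the beta
   scale.
3. **Probe selection** — from the DMPs (BH p < 0.01, |Δβ| ≥ 0.05):
   top-1000 by |Δβ|·(−log₁₀p), top-500 by folded per-probe ROC AUC
   (Mann–Whitney U / n₁n₂), then greedy pruning of pairs with Pearson
   |r| > 0.60.
4. **Diagnostics** — Ward/Euclidean hierarchical clustering, classical MDS,
   and leave-25%-out cross-validation in which the full selection is re-run
   per round and held-out samples are assigned to the nearer training
   centroid. Cases that score low and co-cluster with controls are flagged
   as outliers and excluded from training.
5. **Classification** — linear SVM (case vs controls + other disorders,
   75% of non-cases for training) with Platt-calibrated output: the
   **MVP score** (methylation variant pathogenicity) in [0,1].
6. **Regions & comparison** — DMRs = runs of ≥ 5 significant CpGs within
   1 kb, mean |Δβ| ≥ 5%, Fisher combined p (−2Σln p ~ χ²₂ₖ) < 0.01;
   CGI/gene-context annotation; cross-cohort percent-overlap matrices and
   average-linkage similarity trees over median methylation profiles.

## Worked example

```bash
python examples/02_discover_episignature.py
```

```
probes after QC filtering : 17085
matched controls          : 66
selected episignature     : 112 probes
precision vs planted truth: 0.991
outliers flagged          : ['outlier_01', 'outlier_02']
CV held-out co-clustering : 1.00
hierarchical purity       : 1.00
```

A simulated study (20,000 probes, 20 discovery cases carrying a 200-probe
hypomethylation signature of 5–15% Δβ, 2 signature-free outlier cases, a
100-control pool) is taken through the full discovery workflow. 112 probes
are selected, 99.1% of them genuinely planted; the two cases that carry no
signature are flagged as outliers exactly as designed; every held-out case
co-clusters with the training cases during cross-validation, and the
two-cluster cut of the dendrogram separates cases from controls perfectly.
`examples/03_validate_and_score_vus.py` continues to validation and VUS
scoring (the planted VUS carrier gets MVP ≈ 0.97, call "positive"), and
`examples/06_cohort_table.py` reproduces the packaged 32-case cohort table
counts.

## Layout

- `src/episig/simulate.py` — synthetic EPIC-like generator (planted truth)
- `src/episig/preprocess.py` — QC filters, logit transform, control matching
- `src/episig/dmp.py` — moderated differential methylation
- `src/episig/selection.py` — three-step probe selection, clustering/MDS/CV
- `src/episig/classify.py` — linear-SVM MVP scoring and VUS calls
- `src/episig/dmr.py` — region caller (Fisher-combined chains)
- `src/episig/annotate.py` — CGI/gene context, cohort overlap and trees
- `src/episig/cohort.py` — packaged case-table fixtures and variant parsing
- `src/episig/pipeline.py` — end-to-end drivers and configuration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
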