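# Methods

This note documents the models and procedures implemented in
`methpanel`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical choices
that affect results.

## Data model and filtering

A cohort is a probe × sample matrix of beta values β ∈ [0, 1] (the
fraction of methylated signal at a CpG probe), a sample sheet
(project, tissue class ∈ {tumor, normal, metastasis, cfdna}, dataset ∈
{identification, verification}, FFPE flag), and a probe annotation
(chromosome). Before any analysis:

* probes on X or Y are removed (sex confounding);
* probes with **any** missing value anywhere in the loaded matrix are
  removed — the strictest reading of "probes with missing data were
  removed", chosen because it is deterministic and dataset-independent;
* all copies of a duplicated probe id are removed — the copies cannot
  be disambiguated without array-level metadata;
* FFPE-flagged samples are excluded via the sample sheet (no detection
  logic; the flag is an input).

Retained beta values are never altered (bitwise identity is asserted
in tests). Projects can be relabelled before grouping (e.g. merging
colon and rectum into one colorectal project); the merge is idempotent.

## Recursively partitioned beta-mixture clustering

Each project's tumors (normals are never clustered) are clustered on
the k = 5000 most variable probes (sample variance across the
project's tumors; ties broken lexicographically; k clamps to the probe
count). The matrix is clamped to [1e-4, 1 − 1e-4] because the beta
log-density diverges at 0 and 1.

Recursive binary splitting: at each node a 2-class mixture is fitted
in which, conditional on class, probes are independent beta variables.

* **Initialization**: fuzzy c-means (Euclidean distance, fuzzifier 2,
  centers seeded deterministically from the node's own samples). No
  installed library provides fuzzy c-means, so the standard algorithm
  is implemented here (~40 lines) behind `fuzzy_init`.
* **M-step**: weighted method of moments per class and probe —
  a = μ(μ(1−μ)/v − 1), b = (1−μ)(μ(1−μ)/v − 1) from the weighted mean
  μ and variance v, with v floored at 1e-6 and capped below μ(1−μ) so
  both shapes stay positive. Moment estimation is a stable closed form
  but not the exact maximum-likelihood M-step, so EM ascent is not
  guaranteed in theory; the fit keeps the best parameters seen and
  stops if the log-likelihood would decrease, making the reported
  trajectory non-decreasing by construction.
* **E-step**: responsibilities from the joint log-densities via
  log-sum-exp. EM stops at a log-likelihood gain < 1e-6 or 100
  iterations.
* **Split criterion**: BIC = −2 logL + p ln(n) for the 1-class parent
  (p = 2 × probes) versus the 2-class split (p = 4 × probes + 1), each
  carrying the level weight 2^(−depth) of the node under
  consideration. The split is accepted iff the weighted split BIC is
  lower *and* both children hold ≥ `min_cluster_size` (default 5)
  samples. Applying one common level weight makes the decision at a
  node equivalent to the plain BIC comparison; the weighting is kept
  explicit (and isolated in `level_weighted_bic`) because the
  alternative reading — children weighted at the next level's
  2^(−depth−1) — would accept every split with positive BIC,
  including on homogeneous data, and is therefore rejected.
* **Depth**: default `max_depth` = 4 (≤ 16 leaves). Depth 3 cannot
  represent 5–7 clusters when the split sequence is unbalanced (a
  caterpillar tree at depth 3 has only 4 leaves); the BIC, not the
  depth cap, governs the realized cluster count, which lands in the
  observed 4–7 range on the default synthetic roster.

Leaves are relabelled MC1..MCn by decreasing mean beta over the
clustering probe set; ties break by leaf size (descending), then by
the original leaf index. The whole procedure is deterministic under a
fixed seed (per-node seeds are spawned along the tree structure).
Projects with fewer than 2 × `min_cluster_size` tumors return a
single-cluster assignment rather than an error.

## Differential methylation and candidate selection

For a group pair (g1 = target, g2 = comparator), each probe gets the
mean difference Δ = mean(g1) − mean(g2) and a two-sided Wilcoxon
rank-sum p-value: exact enumeration when both groups have ≤ 12 values
and no ties, otherwise the normal approximation with tie and
continuity correction (scipy's `mannwhitneyu`; the all-tied degenerate
case is defined as p = 1). p-values are Benjamini–Hochberg adjusted
**within one comparison** — the per-analysis adjustment matching how
such pipelines run each comparison independently; a pooled family
across all comparisons would couple unrelated analyses. Significant ⇔
|Δ| ≥ 0.2 and adjusted p ≤ 0.05.

The comparison plan runs all group pairs (tumor and normal project
groups; in the clustered approach, methylation clusters and normal
groups, excluding pairs of clusters from the same cancer). On the
default seven-project roster this yields 91 (non-clustered) and ~790
(clustered) comparisons.

Selection per target (a cancer's tumor group, or one MC): intersect
the probes significant with Δ > 0 in **every** comparison against the
other cancers' groups, then apply

* **strict**: Δ > 0.3 against every comparator and every comparator
  mean < 0.1;
* **relaxed**: Δ > 0.2 **and** comparator mean < 0.15. The source
  criterion reads "and/or"; AND was chosen as the conservative,
  reproducible resolution, with an OR mode behind
  `SelectionThresholds(relaxed_mode="or")`.

The pipeline uses the strict tier and falls back to the relaxed tier
for a target when fewer than `relaxed_fallback_min` (default 2) strict
candidates survive, mirroring the practice of loosening criteria only
where few or no probes are found. In the clustered approach,
candidates are selected per cluster, merged per cancer, and each probe
records `n_target_mcs`, the number of that cancer's clusters that
selected it.

Candidates are then annotated against normal tissue (nothing is
removed): if the target's paired-normal mean is below the 0.3 call
cutoff the probe is `normal_discriminating`, otherwise
`shared_with_normal` — the pancreatic-cancer-like case where a marker
separates cancers from each other but not tumor from adjacent tissue.
The 0.3 threshold is the call cutoff reused for internal consistency;
the source describes the verification step qualitatively.

## Panels and evaluation

A sample is called positive when its **maximum** beta over the panel's
probes strictly exceeds the cutoff (default 0.3; a value of exactly
0.3 is negative, matching "β > 0.3" column semantics).

Greedy builder: candidates ranked by (`n_target_mcs` desc, target mean
desc, probe id); at each step the feasible candidate with the largest
sensitivity gain is added, where feasible means paired-normal
specificity ≥ 90% (not enforced when the pool contains only
`shared_with_normal` probes — such non-discriminating panels are
allowed and reported) and all-samples specificity not dropping more
than 2 points below its current value; the search stops when no
addition detects at least one new target sample; the result is the
shortest prefix of the selection order achieving the final
sensitivity. The objective is this package's concrete interpretation
of "the smallest possible number of probes with the highest
sensitivity and highest specificity"; an exhaustive subset search is
available for pools of ≤ 12 candidates and is used as the optimality
oracle in tests (greedy stays within 5 sensitivity points under the
same paired-normal constraint).

Five statistics are reported with their raw counts: sensitivity
(target tumors called), cancer specificity (target's paired normals
negative), tumor-samples specificity (all non-target tumors negative),
all-samples specificity (all non-target samples negative, including
the target's normals), and accuracy = (target positives + non-target
negatives) / all samples — the only accuracy definition consistent
with the published counts. Percentages are rounded half-up to one
decimal (exact decimal arithmetic, not binary-float rounding). Zero
denominators yield "not applicable" (`None`), never a crash.

The metastasis variant replaces the compartments: sensitivity over the
target's metastases, metastasis specificity over other cancers'
metastases, tumor-samples specificity over primaries plus other
metastases, all-samples specificity and accuracy over everything but
the target metastases. cfDNA evaluation reports per-sample probe
betas, the max beta and the call — no aggregate rates, since real
cfDNA cohorts here are a handful of samples.

### Published-count reproduction

The published evaluation tables for seven adenocarcinoma panels (TCGA
identification cohort, 2853 samples; GEO verification cohort, 782
samples; 31 liver metastases) print the confusion counts next to the
percentages. `methpanel.published` stores those counts, and
`metrics_from_counts` reproduces **every arithmetically
self-consistent printed percentage exactly** (104 cells). Four printed
cells disagree with their own printed counts (transcription slips) and
are excluded and flagged: LIHC/GEO/non-clustered tumor-samples
specificity (83.3 vs 253/304 = 83.2), CRC/GEO/clustered accuracy (94.6
vs 94.9), STAD/TCGA/non-clustered tumor-samples specificity (94.1 vs
2016/2214 = 91.1), BRCA/TCGA/non-clustered all-samples specificity
(94.7 vs 1964/2077 = 94.6). For the metastasis rows only the
metastasis sensitivity/specificity cells are asserted because the
other printed denominators are off by small constants from the stated
cohort sizes.

## The synthetic cohort generator

All values are drawn from a beta distribution parameterized by mean
and concentration φ (shapes μφ, (1−μ)φ); φ defaults to 30, giving a
within-group sd ≈ 0.08 at intermediate means — a realistic per-probe
spread for array data. Means are clamped to [1e-3, 1−1e-3] before
drawing; draws stay inside (0, 1).

Default roster (the conditions all desk-scale results refer to):
seven projects (BRCA, CHOL, CRC, LIHC, LUAD, PAAD, STAD), 40 tumors +
10 normals each, 2000 background probes, 50 sex-chromosome probes, 5
duplicated probe ids, 0.5% of probes carrying missing cells, 50
planted markers per cancer (target-tumor mean 0.7, mean 0.05
everywhere else — effect Δ = 0.65), 5 probes each for PAAD and LUAD
hypermethylated in tumor *and* paired normal, 4–7 methylation
clusters per project ({BRCA 7, CHOL 4, CRC 4, LIHC 6, LUAD 5, PAAD 5,
STAD 6}), 5 liver metastases each from PAAD and BRCA (conservation
noise ± 0.05 on the source column's betas), and 9 cfDNA samples (3
healthy donors at tumor fraction f = 0, 3 CRC and 3 BRCA patients at
f = 0.6).

Structure choices:

* **Background probes** draw their base means from a bimodal mixture
  (low ≈ 0.1, high ≈ 0.8 modes shared across projects), reflecting
  genome-wide methylation bimodality and making "most variable probes"
  selection meaningful.
* **Methylation subtypes**: half of the background probes are
  cluster-informative. Within a project, cluster c has an overall
  level L_c, evenly spaced from 0.65 (MC1) down to 0.25, and each
  informative probe gets its own per-cluster mean drawn around L_c
  (sd 0.2, clipped to [0.05, 0.95]). Probe-specific subtype patterns
  are both more realistic than a single shared level and necessary for
  recoverability: with one shared level the per-probe between-cluster
  signal is too small for the BIC to support 4–7 clusters at 40
  tumors/project (the per-probe per-sample log-likelihood gain of a
  correct split must exceed the 2-parameters-per-probe penalty).
  Because every project's clusters span the same level range, tumor
  project means stay exchangeable across projects and informative
  probes can never satisfy the comparator-mean bounds of the selection
  tiers — background false positives are structurally excluded, which
  the tests confirm empirically (zero observed).
* **Missing values** are assigned per probe (0.5% of probes get 1–3
  missing cells): under the any-missing filter rule a per-cell rate
  would eliminate nearly every probe at cohort width. Missingness is
  part of the noise model, so the noise-free limit (φ = 1e6) also sets
  the missing fraction to 0.
* **Metastases** reuse the source primary's realized betas as means,
  perturbed by a uniform ± 0.05 and redrawn — the conservation level
  is a free choice (no quantitative value is published) and is flagged
  as such.
* **cfDNA** columns mix a tumor profile with a leukocyte-like
  background (planted probes at 0.05, background probes at their base
  means) as per-probe mean f·tumor + (1−f)·background. The patient
  positive-call *rate* is measured at the generator's contract point —
  marker loci fully methylated in the shedding tumor (0.8), f = 0.6 —
  where a single-probe panel calls ≈ 99% of draws; at the cohort
  default marker mean 0.7 the mixture mean is 0.44 and a single probe
  calls ≈ 94% of draws, which is why the nine cohort cfDNA samples are
  reported as individual calls rather than a rate.

What the generator does **not** emulate: array chemistry and probe
design biases, copy-number and purity effects, correlated probes
within CpG islands, batch effects, cell-composition variation in
normals, and read-level cfDNA fragmentation. Consequently, passing
tests demonstrate that the pipeline's logic is correct and recovers
planted truth under realistic noise — not that the specific published
probes would be re-discovered from real arrays.

Panels discovered on the synthetic roster are typically single-probe:
every planted marker alone detects essentially all target tumors, so
the greedy builder stops immediately. Real cohorts are heterogeneous
(markers cover subsets of tumors), which is what the multi-probe
published panels reflect; the subset-coverage behaviour is exercised
by dedicated fixtures (markers planted in a subset of clusters,
disjoint-coverage candidates) rather than by the default roster.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; per-project and per-node
seeds are spawned deterministically. A run manifest records the
configuration, seed and input hashes; repeating a run with the same
manifest produces byte-identical outputs (asserted at file level in
tests).

Desk-scale problem sizes used by the analyses, tests and the
acceptance script: ~2400 probes × 369 samples per cohort, 91
non-clustered and ~790 clustered pairwise comparisons, a 200-tumor
five-cluster project for cluster recovery, and a few hundred simulated
cfDNA draws for the call-rate estimate. A full pipeline pass takes a
few seconds (non-clustered) to ~20 s (clustered) on one CPU.

## Known limitations

* The level-weighted BIC is one defensible reading of an unspecified
  criterion; it is isolated behind `level_weighted_bic` so an
  alternative weighting can be swapped in.
* Method-of-moments EM is an approximation to maximum likelihood;
  likelihood ascent is safeguarded, not guaranteed.
* Whether BH adjustment should pool across comparisons is not
  documented for the original pipeline; per-comparison adjustment was
  chosen (see above) and is the only mode implemented.
* The greedy panel objective is an interpretation; for small pools the
  exhaustive mode gives the exact optimum.
* Per-probe analysis only: no region-level merging of adjacent CpGs,
  no covariate adjustment, no cell-composition correction, no
  tumor-fraction estimation from cfDNA.
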