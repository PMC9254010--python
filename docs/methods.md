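# Methods

## The design and the decomposition model

The package analyzes a five-genotype knockout/replacement design built to
separate the expression effect of a single diffusible regulator (a
testis-expressed microRNA, miR-983, in the motivating system) from the
effect of the genomic context it operates in. The genotypes are: *D.
melanogaster* wild type (WT), *D. melanogaster* knockout (KO), a
replacement line carrying the *D. simulans* ortholog of the regulator in
the *D. melanogaster* background, *D. simulans* WT and *D. simulans* KO.

Three within-species contrasts are estimated per gene from replicated
RNA-seq counts:

- A = log2(sim WT / sim KO) — the regulator's effect in its own background,
- B = log2(replacement / mel KO) — the foreign regulator in the mel
  background,
- C = log2(mel WT / mel KO) — the native regulator in the mel background.

Because each comparison is against a KO with matching background, B − A
isolates the **context effect** (same regulator, different background) and
C − B the **regulator (trans) effect** (different regulator orthologs, same
background). Two pairwise tests (A vs B and B vs C, each at raw p < α,
α = 0.05 by default, deliberately without multiplicity correction so that
weak regulatory differences are not silenced) classify genes:

| category | pattern | reading |
|---|---|---|
| I | A = B, B ≠ C | regulator effect only |
| II | A ≠ B, B = C | context effect only |
| III | A ≠ B, B ≠ C, (A−B)(B−C) > 0 | both, same direction (enhancing) |
| IV | A ≠ B, B ≠ C, (A−B)(B−C) < 0 | both, opposite (compensating) |
| V | A = B, B = C | conserved |
| VI | — | a required genotype has no expression; inestimable |

Category VI is defined here as inestimability (a contrast whose numerator
or baseline group is entirely unexpressed has no meaningful fold change);
the four test outcomes are otherwise exhaustive.

## The DE engine

Counts are normalized with median-of-ratios size factors (reference genes
= rows with no zero; factors rescaled to geometric mean 1). Per-gene NB
dispersion uses the method of moments, φ = (s² − m)/m², pooled across the
two groups of a contrast with residual-df weights and floored at 1e−8.
The fold change is lfc = log2((m1 + c)/(m2 + c)) on normalized group means
with pseudocount c = 0.5, and its delta-method standard error is

    se² = (1/ln2)² · [ s1²/(n1 (m1+c)²) + s2²/(n2 (m2+c)²) ],

with s² the sample variance of normalized replicate counts; a group with
zero sample variance falls back to the NB model variance m + φm². This is
an unshrunk moment estimator: it will not numerically match any shrinkage
fitter, and is not meant to — what the pipeline needs is verifiable
calibration, which the simulation tests check directly. DE calls use the
conventional |lfc| > 1 and Benjamini–Hochberg FDR < 0.05 gates.

## Calibration of the classification tests

The pairwise tests use z = (lfc1 − lfc2)/√(se1² + se2²). Two refinements
to the naive normal-reference subtraction matter at realistic replicate
numbers (n = 3), and both were chosen on statistical grounds and verified
by simulation:

1. **Reference distribution.** Moment SEs from 3 replicates are noisy;
   against a normal reference the A-vs-B test rejects ~9% of null genes at
   the 5% level. `classify()` therefore refers each test to Student's t
   with the residual degrees of freedom of the replicate groups whose
   variance enters the statistic (e.g. df = 4 × (3−1) = 8 for A vs B).
2. **Shared baseline.** B and C share the mel KO group. The shared
   baseline cancels exactly in B − C, yet se_B² + se_C² counts its
   variance twice, making the naive B-vs-C test conservative by a factor
   ≈ √2 in the z-scale. With `shared_baseline=True` (default) the test
   drops the baseline variance components, making it exactly the
   replacement-vs-mel-WT comparison (df = 2 × (3−1) = 4).

Under the global-null simulation (2,000 genes, φ = 0.05, baseline 256,
n = 3) the defaults give marginal rejection rates of 4.6–5.8% for both
tests across seeds; the naive normal/double-counted version gives 8.9% and
3.4%. The low-level `diff_test` keeps the normal reference as its default
for use as a plain two-lfc comparison. Both behaviors are configurable
(`residual_df`, `shared_baseline`, finite `df`).

A consequence worth knowing: the two classification tests are dependent
(they share the replacement group), so joint probabilities (e.g. the
fraction of null genes landing in category V, ≈ 0.91) are close to, but
not exactly, the product of marginals.

## Synthetic data

The generator is the test bed for everything downstream and encodes the
study conditions: NB counts (var = μ + φμ²) for 5 genotypes × n
replicates, per-gene log2 baselines, a per-gene context shift k_g between
species backgrounds and a generative effect triple (a_g, b_g, c_g) that is
exactly what contrasts A, B, C estimate. KO genotypes are effect-free
baselines; the replacement line is the mel background plus b_g. Defaults:
3 replicates per genotype (whole-testis design; the stage panel uses 4–6),
dispersion φ = 0.05, baseline 256 normalized counts (log2 = 8). The
motivating study does not report library depth or dispersion; these
defaults are typical of bulk RNA-seq of pooled fly testes at moderate
depth, give the DE engine realistic power, and are fixed once here. An
optional per-genotype extra log-normal noise term emulates a noisier
genotype (used to study the shared-noise correlation artifact).

What the generator does *not* emulate: read-level artifacts, gene length
variation, cross-species mappability differences, correlated gene modules,
or secondary/cascade effects of the regulator. Passing recovery tests on
this generator therefore demonstrates the estimator and classification
logic, not robustness to alignment-level confounders.

A note on normalization bias baked into the tests: if a large,
direction-unbalanced fraction of genes carries a genotype effect,
median-of-ratios size factors absorb part of it (with *all* genes shifted,
all of it). Simulated architectures therefore balance effect signs or
keep affected genes a minority, as in real transcriptomes.

## Stage dynamics

Per-stage categories collapse to modes: S = {I, III} (regulation
consistent with directional/diversifying selection on the regulator),
N = {II, IV, V}; genes VI at any stage are dropped. Transitions are
counted between successive stages (SG → pSC → rST → eST). The turnover
test asks whether genes that just gained S lose it immediately: with the S
genes at stage t as the population (M), those losing S at t+1 as successes
(K) and the gained genes as the sample (n), p = P(X ≥ k) under
Hypergeometric(M, K, n). The sampling frame is configurable
(`population="all"`) because the verbal description of such tests is
ambiguous; the S-at-stage frame is the default as the more conservative
conditioning. Gain:loss ratio comparisons between gene sets use 2×2
chi-square tests with 1 df and no continuity correction (counts in
intended use are large).

Expression trajectories (per-gene stage means of FPKM-like abundance,
computed separately per species in the wild types) are standardized to
mean 0, sd 1 and clustered with fuzzy c-means: c = 4 clusters, fuzzifier
m = 1.25, tolerance 1e−6 on the objective, ≤ 1,000 iterations, k-means++-
style seeded initialization from data rows. Memberships follow the
standard FCM update u ∝ d^(−2/(m−1)) with exact-hit handling (zero
distance → membership 1); constant trajectories are removed beforehand.
Clusters are labeled by the stage of their centroid maximum (ties →
earliest stage); genes below maximum membership 0.7 stay unassigned. The
implementation is deterministic given the seed and its objective is
non-increasing, both asserted in tests. No attempt is made to match any
particular soft-clustering package numerically.

## Divergence and the selection scan

Global divergence is 1 − ρ (Spearman) per cross-species sample pair,
matched by stage and genotype class (WT with WT, KO with KO); all pairs
are reported rather than replicate averages. Per-gene divergence is
d = log2((mel mean + 0.5)/(sim mean + 0.5)) per genotype class — a
transparent stand-in for model-based interspecific DE fits; conclusions
that depend on it are validated by synthetic recovery, not by matching any
fitted posterior. The contribution of the regulator to a gene's
divergence is summarized as D = (|d_KO| − |d_WT|)/((|d_KO| + |d_WT|)/2)
(∈ [−2, 2]; 0 when both are 0), compared between gene sets with two-sample
KS tests.

The naive Pearson correlation between context (B − A) and regulator
(C − B) effects is biased negative because the estimated B enters both
variables with its sampling noise. The cross-replicate correction splits
the replacement replicates into balanced disjoint halves, estimates B
twice and correlates (B1 − A) with (C − B2); since the halves are
disjoint no noise is shared (the shared mel KO cancels identically in
C − B2). The estimate is averaged over all balanced splits. With
independent true effects and a 3×-inflated replacement noise the naive r
is ≈ −0.7 while the corrected r is within ±0.05 of zero (2,000 genes).

The selection scan resamples expressed genes' d_WT with replacement
(10,000 bootstrap replicates by default), records the 0.95 quantile of
each replicate, and calls a gene divergence-significant when its d_WT
exceeds the recorded quantile in ≥ 95% of replicates — a concrete
operationalization of "top 5% with bootstrap P < 0.05". Candidates are
the intersection with category III. The scan uses signed d_WT by default
(candidates are up-regulated on the mel side); `signed=False` scans
|d_WT|. Under exchangeable divergences the significant fraction stays at
or below ~5%, asserted in tests.

## Phenotype statistics

Within-male coefficient of variation of sperm length uses the sample
(n−1) standard deviation; males with one measurement are excluded.
Percent reduction is 100 · (ref − test)/ref. Competition scores are the
proportion of offspring sired by the test male per female (white-eyed
progeny), with females under 10 total progeny excluded; P1 records give
defense scores, P2 offense. Group comparisons use the Wilcoxon rank-sum
test — exact enumeration for tie-free samples up to n = 25 per group,
otherwise the normal approximation with tie correction and no continuity
correction (so identical samples give p = 1 exactly).

## Problem sizes and reproducibility

Simulation-based checks run at 2,000 genes (500 for shared fixtures),
which makes Monte-Carlo error on rates ≈ 0.5 percentage points and keeps
any single test under a few seconds. The bootstrap scan is exercised at
1,000 replicates in tests and 10,000 in the acceptance script. All
randomness flows through `numpy.random.default_rng` seeds; fixed seeds
give bit-identical counts, memberships and scan results, and the CLI
echoes the seed it used.

## Known limitations

- The moment DE engine has no dispersion shrinkage; per-gene SEs are noisy
  at n = 3 and the t-reference correction is an approximation (Welch-style
  df would vary per gene; the fixed residual df is slightly liberal when
  group variances are very unequal).
- Category VI's definition (inestimability) is one reading of an
  "ambiguous" class; a transitivity-failure definition would differ.
- The per-gene divergence estimator ignores replicate variance within
  genotype classes; it is a point estimate, adequate for rank-based
  scans.
- The hypergeometric turnover test conditions on observed margins; under
  strong gain/loss dependence between stages its p-values are
  conservative.
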