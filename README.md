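# regdecomp

Disentangling the expression effect of a **single trans-regulator** from
**genomic-context effects**, using a five-genotype knockout/replacement
design — the setting in which a young, adaptively evolving microRNA
(miR-983) was knocked out in *Drosophila melanogaster* and *D. simulans*
and replaced in *D. melanogaster* by its *D. simulans* ortholog. The
package is aimed at quantitative geneticists and evolutionary genomicists
who have replicated RNA-seq counts for such a design (whole tissue and/or
developmental stages) and want a tested, reproducible implementation of
the full analysis chain.

## What it computes

For each gene, three within-species log2 fold changes (with standard
errors) against background-matched knockouts:

    A = log2(sim WT / sim KO)        B = log2(replacement / mel KO)
    C = log2(mel WT / mel KO)

so that **B − A** is the genomic-context (cis-like) effect and **C − B**
the regulator (trans) effect. Pairwise tests of A vs B and B vs C at
raw p < 0.05 classify genes into six categories: I regulator-only, II
context-only, III enhancing (both effects, same direction), IV
compensating (opposite directions), V conserved, VI ambiguous
(inestimable). On top of this the package provides:

- a negative-binomial DE engine (median-of-ratios normalization, moment
  dispersion, delta-method lfc standard errors, BH-adjusted Wald calls at
  |log2FC| > 1, FDR < 0.05);
- stage-wise **S/N regulatory-mode dynamics** across spermatogenesis
  (SG, pSC, rST, eST): transition counts, hypergeometric turnover tests,
  chi-square gain/loss enrichment, and fuzzy c-means trajectory
  clustering (c = 4, m = 1.25, membership ≥ 0.7) by peak stage;
- interspecific expression **divergence**: global 1 − ρ (Spearman),
  per-gene log2 divergence with KO-vs-WT normalized differences and KS
  comparisons, effect–divergence Pearson correlations, and the
  **cross-replicate correction** that removes the spurious negative
  correlation between context and regulator effects caused by the shared
  B estimate;
- a **bootstrap selection scan** (10,000 resamples, 0.95 quantile):
  genes exceeding the bootstrap divergence quantile in ≥ 95% of
  replicates *and* classified as enhancing (category III) are candidate
  targets of diversifying selection;
- phenotype statistics: within-male CV of sperm length, percent length
  reduction, sperm-competition defense/offense scores with rank-sum
  comparisons;
- a **synthetic-data generator** that simulates the whole design (NB
  counts, context shifts, per-genotype regulator effects, stage panels,
  phenotype tables) with known ground truth, so every stage of the
  pipeline is testable without any sequencing data.

## Worked example

Simulate a 2,000-gene experiment whose generative category composition
mirrors a real testis transcriptome (178 regulator-only, 384
context-only, 33 enhancing, 132 compensating, 1,273 conserved; |effect|
= 2 log2 units, NB dispersion 0.05, 3 replicates per genotype), then
decompose and report:

```yaml
# config.yaml
seed: 1
simulate:
  n_genes: 2000
  n_replicates: 3
  baseline_log2_mean_range: [8, 8]
  dispersion: 0.05
  effect_size: 2.0
  architecture: {I: 178, II: 384, III: 33, IV: 132, V: 1273}
inputs:
  counts_mel: sim/counts_mel.tsv
  counts_sim: sim/counts_sim.tsv
  sheet: sim/samples.tsv
  orthologs: sim/orthologs.tsv
report:
  records: decomp/effect_records.tsv
```

```bash
regdecomp simulate  --config config.yaml --out sim
regdecomp decompose --config config.yaml --out decomp
regdecomp report    --config config.yaml --out report
```

prints

```
# seed: 1
# total classified genes: 2000
I	229	11.5%
II	442	22.1%
III	45	2.2%
IV	152	7.6%
V	1132	56.6%
VI	0	0.0%
```

Each line is a category, its gene count and its proportion of classified
genes. The recovered composition tracks the generative one, with the
expected drift: about 5% of truly conserved genes trip one of the two
α = 0.05 tests and land in categories I/II, which is why I and II read
slightly high and V slightly low — exactly the behavior the calibration
tests quantify. `decomp/effect_records.tsv` holds the per-gene contrasts,
effects, p-values and categories; the same library calls are available in
Python via `regdecomp.decomposition.build_contrasts` / `classify`.

The `dynamics`, `divergence`, `scan` and `phenotype` subcommands consume
the corresponding tables (per-stage records, abundance matrices, gene
divergence, sperm/competition tables); see `docs/methods.md` for the
statistical definitions and defaults.

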