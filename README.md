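# permdeg

Differential-expression analysis for bulk RNA-seq count matrices built
around an exact permutation test on quantile differences.  The pipeline:

1. **normalization** — TMM scaling factors (trimmed mean of M-values with
   precision weights, implemented from the published definition) and
   counts-per-million.
2. **quantile permutation test** — for each gene, the statistic
   `Y = |q(group1) − q(group2)|` at the lower quartile, median and upper
   quartile; the p-value is `P(Y ≥ y_obs)` over all `C(n1+n2, n1)` label
   assignments (full enumeration under a configurable budget, seeded
   Monte-Carlo sampling with the add-one estimator beyond it), with
   Benjamini–Hochberg adjustment.
3. **DEG calling** — a gene is differential when at some quantile level the
   adjusted p < 0.05, the absolute group-quantile gap is ≥ 10 cpm and the
   fold change is ≥ 1.5; includes sub-phenotype *unique* DEG sets
   (significant against one CT sub-phenotype and not the opposite one) and a
   descriptive confirmation-cohort direction-concordance check.
4. **signature analysis** — gene-set scores (default: the eight
   mitochondria-encoded genes MT-ND1/2/3/5, MT-CO1/2/3, MT-ATP6), rank-sum
   group comparison, hierarchical high/low clustering of the row-z-scored
   signature, Fisher exact 2×2 enrichment, Spearman and OLS associations,
   and qPCR ΔCt fold arithmetic (`2^|ΔCt|`, copy-number ratios).
5. **synthetic data** — a seeded negative-binomial cohort generator
   (log-normal baselines, gamma dispersions, unequal library sizes, spiked
   whole-distribution and upper-tail-only shifts, an elevated high-abundance
   gene block, and lung-function covariates linked to it) so every stage is
   testable end to end without access-controlled data.

## CLI

All stages are exposed as `permdeg` subcommands operating on plain TSV:

```sh
permdeg simulate --config config.yaml --seed 1 --out-prefix sim
permdeg normalize --counts sim.counts.tsv --out-cpm cpm.tsv --out-factors factors.tsv
permdeg test --cpm cpm.tsv --metadata sim.metadata.tsv \
    --group-a disease_status=control --group-b disease_status=case,subphenotype=E \
    --seed 1 --out results.tsv
permdeg deg-call --results results.tsv --out degs.tsv
permdeg deg-unique --ctl-vs-e e.tsv --ctl-vs-eex eex.tsv \
    --ctl-vs-a a.tsv --ctl-vs-aex aex.tsv --out-e unique_e.tsv --out-a unique_a.tsv
permdeg signature --cpm cpm.tsv --out scores.tsv
permdeg cluster --cpm cpm.tsv --metadata sim.metadata.tsv --fisher-label Eex --out clusters.tsv
permdeg assoc --cpm cpm.tsv --metadata sim.metadata.tsv --out assoc.tsv
permdeg qpcr --ct-table ct.tsv --out folds.tsv
```

Group selectors are comma-separated `key=value` filters over the metadata
columns (`disease_status`, `sex`, `subphenotype`, `cohort`); requesting
sub-phenotype `E` includes the extreme subset `Eex` (likewise `A`/`Aex`).

## Notes

- Counts are accepted as TSV (gene rows, sample columns) or MatrixMarket
  triplets with `.genes.txt` / `.samples.txt` side files.
- Gene identifiers keep their version suffix; lookups fall back to
  version-stripped matching.
- Controls are eligible for comparisons only with FEV1/FVC strictly above
  0.75 (`filter_eligible_controls`).
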