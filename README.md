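# snowballpipe

Integrative analysis of a driver mutation's transcriptional and epigenetic
consequences in a tumor cohort. Given gene expression, CpG methylation and
somatic mutation calls for the same samples, the pipeline:

1. labels samples mutant (e.g. `BRAF:V600E`) or pan-negative wild-type,
   excluding carriers of other known driver mutations;
2. ranks genes by the **Snowball** statistic — the aggregated association
   between their co-expression patterns and mutation status, measured by a
   distance-based pseudo-F over resampled gene subsets;
3. organises candidates into weighted co-expression modules (topological
   overlap + hierarchical clustering), tests each module's joint
   association with the mutation by permutation, and emits the union of
   significant modules as the up/down-regulated **target set**;
4. calls differentially methylated CpG loci on M-values with a beta-scale
   effect filter and summarizes global methylation loss;
5. evaluates the target set against functional read-outs: expression-matched
   background rank-sum tests, paired inhibitor-response contrasts, shRNA
   proliferation-screen contrasts, replication overlap, and a
   hypergeometric over-representation test.

It is written for computational biologists studying how a recurrent driver
mutation rewires expression and methylation, and ships a synthetic-cohort
generator with full planted ground truth so every stage is testable
end-to-end without restricted patient data.

## The core statistic

For a set of genes, let `D` be the Euclidean distance matrix between the
samples' standardized log2 expression profiles over those genes, and
`G = -1/2 J A J` its Gower-centered form (`A_ij = d_ij^2`, `J = I - 11'/n`).
With `H` the hat matrix of the two-group indicator design, the
PERMANOVA-style pseudo-F is

```
F = [tr(HGH) / (p - 1)] / [tr((I - H) G (I - H)) / (n - p)],   p = 2.
```

For a single gene this reduces exactly to the classical one-way ANOVA F
(tested to 1e-10). Snowball repeats, for `B` resampling rounds: partition
the genes into random disjoint subsets of size `k`, score each subset by
its pseudo-F, and credit the statistic to every member. A gene's score
`S_g` is the mean over rounds; its empirical p-value is the pooled tail
fraction of scores from `n_perm` repeats of the identical procedure on
label-permuted data, with Benjamini–Hochberg correction across genes.
Sharing one statistic across a subset amplifies weak but coordinated
signals — the point of the method for small driver-mutation cohorts.

## Worked example

`examples/06_full_pipeline.py` simulates the default cohort (30 mutant +
30 wild-type samples; 6 co-expression modules of 20 genes, 2 of them
mutation-responsive with a 1.5 log2 mean shift; 10,000 CpG loci with 100
planted hypomethylation effects of −0.25) and runs everything:

```
grouping     completed  {'n_mut': 30, 'n_wt': 30}
snowball     completed  {'n_genes': 300, 'n_candidates': 300}
modules      completed  {'power': 6, 'n_modules': 6, 'n_significant': 2}
targets      completed  {'n_targets': 40, 'n_up': 20, 'n_down': 20}
methylation  completed  {'n_tested': 10000, 'n_significant': 98, 'hypo_percent': '100.0'}
evaluation   completed  {'n_comparisons': 0}

targets: 40 (40/40 planted recovered)
significant methylation loci: 98 (100.0% hypomethylated)
```

Reading the output: all six planted modules are detected at soft power 6;
only the two mutation-responsive ones pass the permutation test, so the
final target set is exactly the 40 planted genes with correct up/down
labels. The methylation branch recovers 98 of the 100 planted loci with
no false positives, and every significant locus is hypomethylated in the
mutant group — a clean global-loss signature. The other examples exercise
each stage on its own (`examples/01`–`05`).

A thin CLI mirrors the library:
`snowballpipe simulate|snowball|modules|methylation|evaluate|run`.

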