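# Methods

## Sample grouping

Samples carrying the target protein change of the driver gene (default
`BRAF:V600E`; a leading `p.` prefix is stripped, then exact string match)
are labeled MUT. A sample is WT only if it is *pan-negative*: no mutation
in the driver gene nor in any of the exclusion genes (default NRAS,
CDKN2A, GNAQ, KIT, GNA11). Any exclusion-gene mutation — even alongside
the target variant — excludes the sample from both arms, as does a
non-target variant of the driver gene; reasons are recorded. A sample
with no record for a gene is treated as wild-type for that gene: mutation
tables list observed calls, not assayed negatives, so absence of evidence
is the only workable default. The pipeline operates on the samples present
in every supplied matrix; dropped ids are logged.

## Snowball scoring

Expression is transformed to log2(x+1) and standardized per gene
(mean 0, sd 1 across samples, ddof 1) before any distance is taken.
Constant genes standardize to zero rather than erroring: they contribute
no dispersion and sink to the bottom of the ranking.

The subset statistic is the PERMANOVA pseudo-F
`F = [tr(HGH)/(p−1)] / [tr((I−H)G(I−H))/(n−p)]` on the Gower-centered
kernel of Euclidean distances, p = 2 groups. Euclidean distance on
standardized expression was chosen so the univariate case collapses to
the classical ANOVA F, giving an exact oracle; with that metric the two
traces equal the between- and within-group sums of squares summed over
the subset's genes, so the implementation accumulates per-gene SSB/SSW
vectors and never materializes subset distance matrices. A test pins the
equality between this route and the explicit kernel route at 1e-10
relative tolerance.

Aggregation: each of `B` rounds draws a fresh random permutation of the
genes and chunks it into disjoint subsets of size `k` (a trailing
singleton is folded into its neighbor); every member inherits its
subset's F, and the score is the mean over rounds. Covering each gene
exactly once per round keeps cost linear in `B` and gives every gene the
same number of looks.

Calibration permutes the group labels over samples and repeats the whole
aggregation, pooling the `n_perm × n_genes` null scores into one
distribution; the empirical p is `(1 + #{null ≥ S_g}) / (1 + n_null)`.
Whole-procedure permutation preserves the gene–gene correlation structure
under the null, and pooling stabilizes the tail at desk-scale `n_perm`.
Note the consequence: the pooled null tests the *global* null, so when a
strong signal exists, genes that merely share subsets with signal genes
also reach small p — candidate sets are intentionally permissive, and the
module-association stage downstream is what restores specificity.
Benjamini–Hochberg is applied across genes; ranking ties break
lexicographically by gene id for determinism.

Defaults: `k=50`, `B=100`, `n_perm=199`, `alpha=0.05`. At the default
cohort size (300 genes × 60 samples) a full scoring run takes under a
second.

`permutation_pvalue` enumerates the exact null when the number of
distinct label assignments is at most `n_perm` (logged); otherwise it
draws `n_perm` shuffles and batches the trace computation using
`tr(GH) = q·(1/n1 + 1/n0)` with `q = b'Gb`, which for a centered kernel
equals the complementary group's quadratic form.

## Co-expression modules and targets

The network is unsigned, `a_ij = |cor(i,j)|^power` (Pearson, on
log2(x+1) expression): significant modules are expected to mix up- and
down-regulated genes, which a signed network would tear apart.
Topological overlap is
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, and
modules come from average-linkage clustering of `1 − TOM` with a static
cut (default height 0.85) — simpler and fully deterministic compared with
dynamic tree cutting, and adequate for planted-block recovery. Clusters
below `min_module_size` (default 10) are left unassigned (id 0); retained
modules are renumbered by decreasing size with ties broken by the
lexicographically smallest member, so labels do not depend on input
order.

Soft power: the smallest power whose scale-free fit R² reaches 0.8,
where the fit regresses log10 frequency on log10 binned connectivity
(10 equal-width bins) and counts only a negative slope. When no power
reaches the target the R² profile carries little information — on
factor-model data it drifts upward with power by noise alone, and
following the maximum leads to over-thresholding that splits genuine
modules — so the fallback is the sample-size-based default power for
unsigned networks (6 for ≥40 samples, 7 for 30–39, 8 for 20–29, 9
below), clipped to the candidate grid. The max-R² rule remains available
via `fallback="max_r2"`.

Each module's association with the mutation is the same permutation
pseudo-F on the module's standardized expression submatrix (default
`n_perm=199`). No correction is applied across modules (the selection
rule is permutation p < 0.05 per module); with a handful of null modules
this admits an occasional false module in a single cohort, which is why
the end-to-end recovery contract below is stated as a median across
cohorts. The target set is the union of significant modules' genes,
labeled up when mean log2(x+1) in MUT exceeds WT, down otherwise; an
exact zero fold change is labeled down and flagged (`zero_fc`), a
measure-zero event on real data kept deterministic.

## Differential methylation

Betas are clipped into `[ε, 1−ε]` (ε = 1e-3, bounding M-values near ±10,
in line with array practice) and transformed to `M = log2(β/(1−β))`. The
per-locus test is the pooled-variance two-group F-test on M-values with p
from F(1, n−2); the logit-like M scale is far closer to homoscedastic
Gaussian than bounded betas, and under the generator's 450K-like noise
the p-values are uniform to a KS check at n = 30+30. The effect filter
stays on the beta scale — a 0.2 threshold is only meaningful there — so a
locus is significant when raw p < 1e-3 **and** |Δβ| ≥ 0.2, with
Δβ = mean β(MUT) − mean β(WT). An M-scale effect threshold is available
via `effect_scale="m"` for users who prefer the model-coefficient
reading of the magnitude filter.

Missing betas are permitted: statistics are pairwise-complete per locus,
and loci with fewer than 3 observed values in either group are skipped
(logged; the floor is exposed as `min_obs_per_group`). Zero within-group
variance with a group difference yields p = 0 with a `zero_variance`
flag. The summary reports per-locus group medians (density-plot-ready),
|Δβ| > 0.1 labeling flags, and the count/fraction of significant loci
with Δβ < 0 — the global-loss read-out; with no significant loci the
fraction is reported as `NA` rather than a number.

## Target-set evaluation

Fold changes are differences of mean log2(x+1) (pseudocount 1
pipeline-wide). Rank-sum comparisons use the Mann–Whitney U with an exact
null when the smaller sample has ≤ 8 values and the pooled values are
tie-free, and the tie-corrected normal approximation otherwise; two
identical multisets return p = 1 at the null-mean U. Expression-matched
backgrounds draw uniformly from non-target genes whose median log2 level
lies within the targets' min–max range; a quantile-bin matching variant
sits behind `mode="bins"`, and a degenerate range (singleton target set)
falls back to the nearest non-targets by level. shRNA values are reduced
to gene level by the median over cell lines and probes, then compared
directionally: down-regulated targets vs controls with alternative
"greater" (silencing a suppressed gene should boost proliferation),
up-regulated targets "less". Inhibitor response compares |log2 fold
change| of targets against randomly drawn control genes (default 5000,
capped at availability with a warning), alternative "greater".
Replication overlap reports the raw percentage alongside the count
(rounded only for display), and the over-representation test is the
upper-tail hypergeometric — an open substitute for proprietary
pathway-enrichment scores.

## Synthetic cohorts

Expression is generated on the log2 scale as a single-latent-factor model
per module: gene value = `sqrt(within_module_corr) · factor + baseline +
shift·1[MUT] + noise`, then mapped to an RSEM-like scale by `2^x − 1`
(truncated at 0) so the pipeline's log2(x+1) transform approximately
inverts the generator. Factors are orthogonalized in-sample (centered QR,
unit variance), making the planted between-module correlation exactly
zero instead of O(1/√n); background genes get matched total variance so
expression spread does not reveal module membership. Responsive modules
alternate direction, half up and half down in the mutant group. With the
default `within_module_corr=0.8` and `noise_sd=0.5` the realized pairwise
within-module correlation is ≈ 0.76 (`ρ/(ρ+σ²)`).

Methylation betas are Beta-distributed per locus with the mean set by the
locus and a fixed concentration of 20 — 450K-like dispersion without
widening the configuration surface. Planted loci draw their wild-type
mean from U(0.4, 0.8) so the full `delta_beta_effect` fits inside [0, 1];
other loci from U(0.1, 0.9). The shRNA generator gives down-regulated
targets a mean log2 depletion ratio of `+effect`, up-regulated `−effect`,
nulls 0, with Gaussian noise per gene × cell line; the inhibitor
generator moves each target's expression back toward its wild-type level
by `reversal` log2 units. Both are exact in the noise-free limit (used as
trivial oracles in the tests).

Defaults are the study conditions used throughout the tests and the
acceptance script: `n_mut=n_wt=30`, 300 genes in 6 modules of 20 (2
responsive, `mean_shift=1.5`), 10,000 loci with 1% planted
hypomethylation at `delta_beta_effect=−0.25`. What the generator does
*not* emulate: batch effects, copy-number confounding, count-level
sequencing noise, probe cross-reactivity, or cell-composition shifts —
so passing recovery tests demonstrates correctness of the statistical
machinery under the stated model, not robustness to those artifacts on
real cohorts.

## Orchestration and determinism

Every stage's seed is `blake2b(global_seed:stage_name) mod 2^31`, so
adding a stage never perturbs earlier stages' randomness and each CLI
subcommand reproduces its slice of a full run. Reruns with identical
config and seed produce byte-identical output tables (checksummed in the
run manifest). A missing methylation input skips that branch (recorded as
skipped, not failed); the expression branch and evaluation proceed.

## Known limitations

- The resampling-aggregation scheme (disjoint partitions per round) is
  one consistent reading of "evaluating each gene in a group of other
  genes"; overlapping or neighborhood-grown subsets are plausible
  alternatives and would trade cost for per-gene look diversity.
- The pooled permutation null makes gene-level selection permissive by
  construction under strong global signal; interpret the candidate set
  together with the module stage, not alone.
- Module significance is uncorrected across modules by design; control
  the family-wise behavior through `module_alpha` if many modules are
  tested.
- Static tree cutting requires a sensible `cut_height` for the data at
  hand; the default 0.85 is tuned to unsigned TOM on cohorts of this
  size, not a universal constant.
- Covariate-adjusted designs (beyond two groups) and region-level (DMR)
  methylation calling are out of scope.
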