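"""Generate a synthetic driver-mutation cohort with planted ground truth.

The generator emulates a tumor cohort profiled for expression and DNA
methylation: correlated gene modules (two of which shift with mutation
status) and Beta-distributed CpG betas with planted hypomethylation in
the mutant group.
"""

from snowballpipe import SimulationConfig, simulate_cohort

config = SimulationConfig(seed=0)  # 30 MUT + 30 WT, 300 genes, 10,000 loci
expr, meth, groups, truth = simulate_cohort(config)

print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")
print(f"methylation matrix: {meth.shape[0]} loci x {meth.shape[1]} samples")
print(f"groups: {len(groups.mut_samples)} MUT, {len(groups.wt_samples)} WT")
print(f"planted responsive genes: {len(truth.responsive_genes)} "
      f"({len(truth.up_genes)} up, {len(truth.down_genes)} down in MUT)")
print(f"planted hypomethylated loci: {len(truth.hypo_loci)} "
      f"at delta beta {config.delta_beta_effect}")
# Every downstream stage is scored against this truth in the tests: the
# numbers above are the signals the pipeline is expected to recover.
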