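"""Run the whole pipeline in one call and inspect the stage summary.

run_analysis chains grouping, Snowball ranking, module detection, target
finalization, the methylation branch and the evaluation stage, deriving
each stage's seed from the global one.
"""

from snowballpipe import SimulationConfig, run_analysis, simulate_cohort

expr, meth, groups, truth = simulate_cohort(SimulationConfig(seed=0))
out = run_analysis(expr, groups, meth=meth, seed=7)

for stage in out["stages"]:
    info = {k: v for k, v in stage.items()
            if k not in ("stage", "status", "elapsed_s")}
    print(f"{stage['stage']:12s} {stage['status']:10s} {info}")

targets = out["target_set"]
planted = set(truth.responsive_genes)
recovered = len(set(targets.genes) & planted)
print(f"\ntargets: {len(targets.genes)} "
      f"({recovered}/{len(planted)} planted recovered)")
print(f"significant methylation loci: {out['methylation_summary'].n_significant} "
      f"({out['methylation_summary'].hypo_percent}% hypomethylated)")
print("\nresult tables:", ", ".join(sorted(out["tables"])))
# The same run is available from the shell:
#   snowballpipe run --config config.yaml --seed 7 --out-dir results/
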