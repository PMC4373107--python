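"""End-to-end orchestration: grouping -> Snowball -> modules -> targets,
with the methylation branch in parallel and the evaluation stage last.

Every stage draws its seed deterministically from the global seed and the
stage name, so adding a stage never perturbs the randomness of earlier
ones, and each stage run standalone (CLI subcommand) reproduces exactly
its slice of the full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .io import (
    DEFAULT_EXCLUSION_GENES,
    ExpressionMatrix,
    GeneSetCollection,
    MethylationMatrix,
    MutationTable,
    SampleGroups,
    assign_sample_groups,
    intersect_samples,
    read_expression_matrix,
    read_gene_sets,
    read_methylation_matrix,
    read_mutation_table,
    write_results,
)
from .snowball import SnowballParams, snowball_scores, select_candidates
from .network import (
    detect_modules,
    finalize_targets,
    module_association_test,
    pick_soft_threshold,
    tom_matrix,
)
from .methylation import (
    DEFAULT_EFFECT_THRESHOLD,
    DEFAULT_P_THRESHOLD,
    delta_beta,
    dmp_test,
    m_value_matrix,
    methylation_summary,
    select_dmps,
)
from .evaluation import (
    evaluate_external_sets,
    inhibitor_response_comparison,
    log2_fold_change,
    results_frame,
    shrna_comparison,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Inputs, parameters and seeds for a full run."""

    expr_path: str
    mutations_path: str | None = None
    groups_path: str | None = None
    methylation_path: str | None = None
    gene_sets_path: str | None = None
    shrna_path: str | None = None
    paired_response_path: str | None = None
    out_dir: str = "results"
    driver_gene: str = "BRAF"
    driver_change: str = "V600E"
    exclusion_genes: set[str] = field(default_factory=lambda: set(DEFAULT_EXCLUSION_GENES))
    snowball: dict[str, Any] = field(default_factory=dict)
    modules: dict[str, Any] = field(default_factory=dict)
    methylation: dict[str, Any] = field(default_factory=dict)
    evaluation: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "exclusion_genes" in raw:
            raw["exclusion_genes"] = set(raw["exclusion_genes"])
        config = cls(**raw)
        if config.mutations_path is None and config.groups_path is None:
            raise ValueError("config needs mutations_path or groups_path")
        return config


def run_analysis(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    meth: MethylationMatrix | None = None,
    gene_sets: GeneSetCollection | None = None,
    shrna: pd.DataFrame | None = None,
    paired_response: pd.DataFrame | None = None,
    snowball_kwargs: dict | None = None,
    module_kwargs: dict | None = None,
    methylation_kwargs: dict | None = None,
    evaluation_kwargs: dict | None = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Run the analysis on in-memory inputs; returns stage results.

    The returned dict carries the stage objects (``snowball_result``,
    ``module_assignment``, ``module_stats``, ``target_set``, ``dmps``,
    ``methylation_summary``, evaluation result lists), a ``tables`` dict
    of TSV-ready frames, and a ``stages`` status list.
    """
    snowball_kwargs = dict(snowball_kwargs or {})
    module_kwargs = dict(module_kwargs or {})
    methylation_kwargs = dict(methylation_kwargs or {})
    evaluation_kwargs = dict(evaluation_kwargs or {})

    out: dict[str, Any] = {"tables": {}, "stages": []}

    def _stage(name: str, status: str, t0: float, **info) -> None:
        out["stages"].append({"stage": name, "status": status,
                              "elapsed_s": round(time.perf_counter() - t0, 3), **info})
        logger.info("stage %s: %s (%.2fs) %s", name, status, time.perf_counter() - t0, info)

    # -- grouping / sample intersection ------------------------------------
    t0 = time.perf_counter()
    matrices = [m for m in (expr, meth) if m is not None]
    retained = intersect_samples(groups, *matrices)
    groups = SampleGroups(
        {s: groups.labels[s] for s in retained},
        dict(groups.excluded),
    )
    expr = expr.subset_samples([s for s in expr.sample_ids if s in groups.labels])
    if meth is not None:
        meth = meth.subset_samples([s for s in meth.sample_ids if s in groups.labels])
    out["groups"] = groups
    _stage("grouping", "completed", t0,
           n_mut=len(groups.mut_samples), n_wt=len(groups.wt_samples))

    # -- snowball -----------------------------------------------------------
    t0 = time.perf_counter()
    params = SnowballParams(seed=stage_seed(seed, "snowball"), **snowball_kwargs)
    sb = snowball_scores(expr, groups, params)
    candidates = select_candidates(sb)
    out["snowball_result"] = sb
    out["candidates"] = candidates
    out["tables"]["snowball_scores"] = sb.table
    _stage("snowball", "completed", t0, n_genes=len(sb.table), n_candidates=len(candidates))

    # -- co-expression modules + targets ------------------------------------
    t0 = time.perf_counter()
    min_module_size = module_kwargs.pop("min_module_size", 10)
    cut_height = module_kwargs.pop("cut_height", 0.85)
    module_alpha = module_kwargs.pop("module_alpha", 0.05)
    n_perm = module_kwargs.pop("n_perm", 199)
    powers = module_kwargs.pop("powers", range(1, 13))
    if len(candidates) >= max(min_module_size, 3):
        cand_expr = expr.subset_genes(candidates)
        power = pick_soft_threshold(cand_expr, powers)
        tom = tom_matrix(cand_expr, power)
        assignment = detect_modules(tom, min_module_size=min_module_size,
                                    cut_height=cut_height)
        module_pvalues: dict[int, float] = {}
        module_rows = []
        for module_id in assignment.module_ids:
            members = assignment.members(module_id)
            f_stat, p = module_association_test(
                expr, members, groups, n_perm=n_perm,
                seed=stage_seed(seed, f"module:{module_id}"),
            )
            module_pvalues[module_id] = p
            module_rows.append({"module": module_id, "n_genes": len(members),
                                "pseudo_F": f_stat, "p": p})
        out["module_assignment"] = assignment
        out["module_stats"] = pd.DataFrame(
            module_rows, columns=["module", "n_genes", "pseudo_F", "p"])
        out["module_pvalues"] = module_pvalues
        out["soft_power"] = power
        out["tables"]["module_assignment"] = assignment.to_frame()
        out["tables"]["module_stats"] = out["module_stats"]
        _stage("modules", "completed", t0, power=power,
               n_modules=len(assignment.module_ids),
               n_significant=sum(p < module_alpha for p in module_pvalues.values()))

        t0 = time.perf_counter()
        targets = finalize_targets(assignment, module_pvalues, expr, groups,
                                   module_alpha=module_alpha)
        out["target_set"] = targets
        out["tables"]["targets"] = targets.table
        _stage("targets", "completed", t0, n_targets=len(targets.table),
               n_up=len(targets.up_genes), n_down=len(targets.down_genes))
    else:
        out["target_set"] = None
        _stage("modules", "skipped: too few candidates", t0,
               n_candidates=len(candidates))
        _stage("targets", "skipped: no modules", time.perf_counter())

    # -- methylation branch ---------------------------------------------------
    t0 = time.perf_counter()
    if meth is not None:
        p_threshold = methylation_kwargs.pop("p_threshold", DEFAULT_P_THRESHOLD)
        effect_threshold = methylation_kwargs.pop(
            "effect_threshold", DEFAULT_EFFECT_THRESHOLD)
        m = m_value_matrix(meth)
        tests = dmp_test(m, groups, **methylation_kwargs)
        deltas = delta_beta(meth, groups)
        dmps = select_dmps(tests, deltas, p_threshold=p_threshold,
                           effect_threshold=effect_threshold)
        summary = methylation_summary(meth, groups, dmps)
        out["dmps"] = dmps
        out["methylation_summary"] = summary
        out["tables"]["dmps"] = dmps
        out["tables"]["methylation_medians"] = summary.per_locus
        _stage("methylation", "completed", t0,
               n_tested=len(dmps), n_significant=summary.n_significant,
               hypo_percent=summary.hypo_percent)
    else:
        _stage("methylation", "skipped: no methylation input", t0)

    # -- evaluation -----------------------------------------------------------
    t0 = time.perf_counter()
    fc = log2_fold_change(expr, groups)
    out["fold_changes"] = fc
    out["tables"]["fold_changes"] = fc.reset_index()
    eval_results = []
    n_background = evaluation_kwargs.pop("n_background", 1000)
    n_controls = evaluation_kwargs.pop("n_controls", 5000)
    if gene_sets is not None:
        eval_results += evaluate_external_sets(
            fc, expr, groups, gene_sets, n_background=n_background,
            seed=stage_seed(seed, "evaluate:sets"))
    targets = out.get("target_set")
    if shrna is not None and targets is not None:
        eval_results += shrna_comparison(
            shrna, set(targets.down_genes), set(targets.up_genes),
            n_controls=n_controls, seed=stage_seed(seed, "evaluate:shrna"))
    if paired_response is not None and targets is not None:
        target_sets = GeneSetCollection({"targets": set(targets.genes)}) \
            if targets.genes else None
        if target_sets is not None:
            eval_results += inhibitor_response_comparison(
                paired_response, target_sets, n_controls=n_controls,
                seed=stage_seed(seed, "evaluate:inhibitor"))
    out["set_comparisons"] = eval_results
    out["tables"]["set_comparisons"] = results_frame(eval_results) if eval_results \
        else pd.DataFrame(columns=["name", "n_set", "n_background", "U", "p",
                                   "direction", "status"])
    _stage("evaluation", "completed", t0, n_comparisons=len(eval_results))
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """File-driven full run; writes result tables and a checksummed manifest."""
    expr = read_expression_matrix(config.expr_path)
    if config.groups_path:
        groups = SampleGroups.from_frame(pd.read_csv(config.groups_path, sep="\t"))
    elif config.mutations_path:
        mutations = read_mutation_table(config.mutations_path)
        groups = assign_sample_groups(
            mutations, expr.sample_ids, config.driver_gene, config.driver_change,
            frozenset(config.exclusion_genes))
    else:
        raise ValueError("config needs mutations_path or groups_path")
    meth = read_methylation_matrix(config.methylation_path) \
        if config.methylation_path else None
    gene_sets = read_gene_sets(config.gene_sets_path) if config.gene_sets_path else None
    shrna = pd.read_csv(config.shrna_path, sep="\t") if config.shrna_path else None
    paired = pd.read_csv(config.paired_response_path, sep="\t") \
        if config.paired_response_path else None

    results = run_analysis(
        expr, groups, meth=meth, gene_sets=gene_sets, shrna=shrna,
        paired_response=paired, snowball_kwargs=config.snowball,
        module_kwargs=config.modules, methylation_kwargs=config.methylation,
        evaluation_kwargs=config.evaluation, seed=config.seed,
    )
    results["tables"]["sample_groups"] = results["groups"].to_frame()

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s["stage"]: stage_seed(config.seed, s["stage"])
                        for s in results["stages"]},
        "parameters": {
            "snowball": config.snowball, "modules": config.modules,
            "methylation": config.methylation, "evaluation": config.evaluation,
            "driver_gene": config.driver_gene, "driver_change": config.driver_change,
            "exclusion_genes": sorted(config.exclusion_genes),
        },
        "stages": results["stages"],
    }
    manifest_files = write_results(results["tables"], config.out_dir, metadata)
    manifest = {
        "files": manifest_files,
        "checksums": {name: _sha256(path) for name, path in manifest_files.items()
                      if not path.endswith("run_metadata.json")},
        "stages": results["stages"],
    }
    manifest_path = Path(config.out_dir) / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
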