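"""Weighted co-expression network, module detection and target finalization.

Builds an unsigned weighted network over the Snowball candidate genes
(adjacency a_ij = |cor(i,j)|^power on log2(x+1) expression, Pearson),
converts it to a topological overlap matrix (TOM), clusters 1 - TOM with
average linkage, tests each module's multivariate association with the
mutation label by the same permutation pseudo-F used for scoring, and
emits the final up/down target set from the significant modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .io import ExpressionMatrix, SampleGroups
from .snowball import gower_center, permutation_pvalue, standardize_log2

logger = logging.getLogger(__name__)

UNASSIGNED = 0


@dataclass
class TomMatrix:
    """Topological overlap values in [0, 1] between candidate genes."""

    values: pd.DataFrame  # gene x gene, symmetric, unit diagonal
    power: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ModuleAssignment:
    """gene -> module id; id 0 marks genes not in any retained module."""

    modules: pd.Series  # index gene, values int

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.modules) - {UNASSIGNED})

    def members(self, module_id: int) -> list[str]:
        return list(self.modules.index[self.modules == module_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.modules.index, "module": self.modules.to_numpy()})


@dataclass
class TargetSet:
    """Final putative driver targets with direction and log2 fold change."""

    table: pd.DataFrame  # gene, direction, log2_fc, module, module_p, zero_fc

    @property
    def up_genes(self) -> list[str]:
        return list(self.table.loc[self.table["direction"] == "up", "gene"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.table.loc[self.table["direction"] == "down", "gene"])

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def _adjacency(expr: ExpressionMatrix, power: int, drop_constant: bool = False) -> pd.DataFrame:
    data = expr.log2_values()
    sd = data.to_numpy().std(axis=1)
    if (sd == 0).any():
        flat = list(data.index[sd == 0])
        if not drop_constant:
            raise ValueError(f"constant-expression gene(s): {flat}")
        logger.warning("excluding %d constant gene(s) from network", len(flat))
        data = data.loc[sd > 0]
    cor = np.corrcoef(data.to_numpy())
    adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=data.index, columns=data.index)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> float:
    """Scale-free topology fit index of the connectivity distribution.

    Regresses log10 frequency on log10 binned connectivity k_i = sum_j
    a_ij; returns R^2 when the slope is negative (decreasing frequency
    with connectivity, the scale-free signature), else 0.
    """
    k = adjacency.to_numpy().sum(axis=0)
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    centers = np.array([k[which == i].mean() if (which == i).any() else np.nan
                        for i in range(n_bins)])
    ok = (freq > 0) & np.isfinite(centers) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    fit = linregress(np.log10(centers[ok]), np.log10(freq[ok]))
    if fit.slope >= 0:
        return 0.0
    return float(fit.rvalue**2)


def _default_power(n_samples: int) -> int:
    """Sample-size-based default soft power for unsigned networks."""
    if n_samples >= 40:
        return 6
    if n_samples >= 30:
        return 7
    if n_samples >= 20:
        return 8
    return 9


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: list[int] | range = range(1, 13),
    r2_target: float = 0.8,
    fallback: str = "default",
) -> int:
    """Smallest power whose scale-free fit R^2 reaches the target.

    When no candidate reaches the target, the R^2 profile carries little
    signal, so ``fallback="default"`` returns the sample-size-based
    default power for unsigned networks (6 for >= 40 samples, up to 9
    for very small cohorts), clipped into the candidate grid;
    ``fallback="max_r2"`` returns the power maximizing R^2 instead. A
    single candidate power is returned as-is.
    """
    powers = list(powers)
    if len(powers) == 1:
        return powers[0]
    fits = {}
    for power in powers:
        fits[power] = scale_free_fit(_adjacency(expr, power, drop_constant=True))
        if fits[power] >= r2_target:
            return power
    if fallback == "max_r2":
        best = max(fits, key=lambda p: (fits[p], -p))
    else:
        target = _default_power(len(expr.sample_ids))
        best = min(powers, key=lambda p: (abs(p - target), p))
    logger.info(
        "no power reached scale-free R^2 >= %.2f; falling back to power %d "
        "(fallback=%s, best R^2=%.3f)",
        r2_target, best, fallback, max(fits.values()),
    )
    return best


def tom_matrix(expr: ExpressionMatrix, power: int) -> TomMatrix:
    """Topological overlap from the unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i = sum_u a_iu and unit diagonal.
    """
    if len(expr.gene_ids) < 3:
        raise ValueError("TOM needs at least 3 genes")
    adj_frame = _adjacency(expr, power)
    adj = adj_frame.to_numpy()
    k = adj.sum(axis=0)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    genes = adj_frame.index
    return TomMatrix(values=pd.DataFrame(tom, index=genes, columns=genes), power=power)


def detect_modules(
    tom: TomMatrix, min_module_size: int = 10, cut_height: float = 0.85
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM cut at a fixed height.

    Clusters below ``min_module_size`` are assigned id 0. Retained
    modules are renumbered by decreasing size, ties broken by the
    lexicographically smallest member gene, so the labeling does not
    depend on gene input order.
    """
    if not (0 < cut_height < 1):
        raise ValueError("cut_height must be in (0, 1)")
    genes = list(tom.values.index)
    dissim = 1.0 - tom.values.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    linkage = average(squareform(dissim, checks=False))
    raw = fcluster(linkage, t=cut_height, criterion="distance")

    by_cluster: dict[int, list[str]] = {}
    for gene, cid in zip(genes, raw):
        by_cluster.setdefault(int(cid), []).append(gene)
    kept = [members for members in by_cluster.values() if len(members) >= min_module_size]
    kept.sort(key=lambda members: (-len(members), min(members)))

    modules = pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene"), dtype=int)
    for new_id, members in enumerate(kept, start=1):
        modules.loc[members] = new_id
    return ModuleAssignment(modules=modules)


def module_association_test(
    expr: ExpressionMatrix,
    module_genes: list[str],
    groups: SampleGroups,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation pseudo-F of a module's joint expression vs the label.

    Euclidean distance over the module genes' standardized log2
    expression, Gower-centered, then label-permutation p-value.
    """
    missing = sorted(set(module_genes) - set(expr.gene_ids))
    if missing:
        raise KeyError(f"module genes missing from expression matrix: {missing}")
    if len(module_genes) < 2:
        raise ValueError("module must have at least 2 genes")
    sample_ids = [s for s in expr.sample_ids if s in groups.labels]
    z = standardize_log2(expr.subset_genes(module_genes), sample_ids).to_numpy()
    diff = z[:, :, None] - z[:, None, :]
    distances = np.sqrt((diff**2).sum(axis=0))
    kernel = gower_center(distances)
    b = groups.indicator(sample_ids)
    return permutation_pvalue(kernel, b, n_perm=n_perm, seed=seed)


def finalize_targets(
    assignment: ModuleAssignment,
    module_pvalues: dict[int, float],
    expr: ExpressionMatrix,
    groups: SampleGroups,
    module_alpha: float = 0.05,
) -> TargetSet:
    """Union of genes from significant modules, labeled up/down by fold change.

    A gene is "up" when its mean log2(x+1) expression in MUT exceeds WT,
    else "down"; an exact zero fold change is labeled down and flagged.
    """
    missing = sorted(set(assignment.module_ids) - set(module_pvalues))
    if missing:
        raise KeyError(f"module_pvalues missing module id(s): {missing}")
    sample_ids = [s for s in expr.sample_ids if s in groups.labels]
    data = expr.log2_values().loc[:, sample_ids]
    b = groups.indicator(sample_ids)
    fc = data.to_numpy()[:, b].mean(axis=1) - data.to_numpy()[:, ~b].mean(axis=1)
    fc_series = pd.Series(fc, index=data.index)

    rows = []
    for module_id in assignment.module_ids:
        p = module_pvalues[module_id]
        if p >= module_alpha:
            continue
        for gene in sorted(assignment.members(module_id)):
            g_fc = float(fc_series[gene])
            rows.append(
                {
                    "gene": gene,
                    "direction": "up" if g_fc > 0 else "down",
                    "log2_fc": g_fc,
                    "module": module_id,
                    "module_p": p,
                    "zero_fc": g_fc == 0.0,
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene", "direction", "log2_fc", "module", "module_p", "zero_fc"]
    )
    return TargetSet(table=table)
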