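"""Downstream evaluation of a putative driver-target set.

Fold changes between mutant and wild-type groups, rank-sum comparisons of
external gene sets against expression-matched random backgrounds, paired
before/after inhibitor-response contrasts against random control genes,
shRNA proliferation-screen contrasts (down-regulated targets vs controls
vs up-regulated targets), replication overlap percentages, and a generic
hypergeometric over-representation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .io import ExpressionMatrix, GeneSetCollection, SampleGroups

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
#: sample sizes at or below which the exact rank-sum null is used (no ties)
EXACT_RANKSUM_MAX_N = 8


@dataclass
class SetComparisonResult:
    """One rank-sum comparison of a gene set against a background."""

    name: str
    n_set: int
    n_background: int
    statistic: float
    p: float
    direction: str  # 'set_greater' | 'background_greater' | 'tied'
    status: str = "ok"
    small_n: bool = False

    def to_row(self) -> dict:
        return {
            "name": self.name,
            "n_set": self.n_set,
            "n_background": self.n_background,
            "U": self.statistic,
            "p": self.p,
            "direction": self.direction,
            "status": self.status,
        }


def results_frame(results: list[SetComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def log2_fold_change(
    expr: ExpressionMatrix, groups: SampleGroups, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-gene mean log2(x + pseudocount) in MUT minus WT.

    Returns a frame indexed by gene with columns log2_fc and abs_log2_fc.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    sample_ids = [s for s in expr.sample_ids if s in groups.labels]
    b = groups.indicator(sample_ids)
    if b.sum() == 0 or (~b).sum() == 0:
        raise ValueError("both groups must be non-empty")
    data = np.log2(expr.data.loc[:, sample_ids].to_numpy() + pseudocount)
    fc = data[:, b].mean(axis=1) - data[:, ~b].mean(axis=1)
    return pd.DataFrame(
        {"log2_fc": fc, "abs_log2_fc": np.abs(fc)},
        index=pd.Index(expr.gene_ids, name="gene"),
    )


# ---------------------------------------------------------------------------
# Backgrounds and rank tests
# ---------------------------------------------------------------------------

def matched_background(
    targets: set[str],
    expr_levels: pd.Series,
    universe: set[str],
    n: int,
    seed: int = 0,
    mode: str = "range",
    n_bins: int = 10,
) -> set[str]:
    """Random non-target genes matched to the targets' expression levels.

    ``mode="range"`` (default) draws uniformly from non-targets whose
    level lies within the [min, max] of the target levels; ``mode="bins"``
    draws per-quantile-bin with the targets' bin occupancy. If fewer than
    ``n`` genes are eligible, all eligible genes are returned (warned).
    """
    rng = np.random.default_rng(seed)
    targets_present = sorted(targets & set(expr_levels.index))
    if not targets_present:
        raise ValueError("no target gene has an expression level")
    pool = sorted((universe & set(expr_levels.index)) - targets)
    levels = expr_levels

    if mode == "range":
        lo = levels.loc[targets_present].min()
        hi = levels.loc[targets_present].max()
        eligible = [g for g in pool if lo <= levels[g] <= hi]
        if not eligible:
            # degenerate range (e.g. a singleton target set): fall back to
            # the n nearest non-targets by expression level
            center = levels.loc[targets_present].median()
            logger.warning("no gene inside the target expression range; "
                           "using the %d nearest by level", n)
            ranked = sorted(pool, key=lambda g: (abs(levels[g] - center), g))
            return set(ranked[:n])
        if len(eligible) < n:
            logger.warning("only %d eligible background genes (< %d requested)",
                           len(eligible), n)
            return set(eligible)
        return set(rng.choice(eligible, size=n, replace=False))
    if mode == "bins":
        edges = np.quantile(levels.to_numpy(), np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        t_bins = np.clip(np.digitize(levels.loc[targets_present], edges[1:-1]), 0, len(edges) - 2)
        occupancy = np.bincount(t_bins, minlength=len(edges) - 1) / len(targets_present)
        pool_bins = np.clip(np.digitize(levels.loc[pool], edges[1:-1]), 0, len(edges) - 2)
        chosen: list[str] = []
        for bin_idx, frac in enumerate(occupancy):
            want = int(round(frac * n))
            members = [g for g, pb in zip(pool, pool_bins) if pb == bin_idx]
            if want and members:
                take = min(want, len(members))
                chosen.extend(rng.choice(members, size=take, replace=False))
        if len(chosen) < n:
            logger.warning("bin-matched background has %d < %d genes", len(chosen), n)
        return set(chosen)
    raise ValueError("mode must be 'range' or 'bins'")


def wilcoxon_rank_sum(
    a, b, alternative: str = "two-sided", name: str = ""
) -> SetComparisonResult:
    """Mann-Whitney U rank-sum comparison of two value lists.

    Exact null when the smaller sample has at most 8 values and there are
    no ties; normal approximation with tie correction otherwise. Two
    identical multisets give p = 1 with U at its null mean.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    mean_u = a.size * b.size / 2.0
    if np.unique(np.concatenate([a, b])).size == 1:
        return SetComparisonResult(
            name=name, n_set=a.size, n_background=b.size,
            statistic=mean_u, p=1.0, direction="tied", small_n=a.size == 1,
        )
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_RANKSUM_MAX_N and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    u = float(res.statistic)
    direction = "set_greater" if u > mean_u else ("background_greater" if u < mean_u else "tied")
    return SetComparisonResult(
        name=name, n_set=int(a.size), n_background=int(b.size),
        statistic=u, p=float(min(res.pvalue, 1.0)), direction=direction,
        small_n=a.size == 1,
    )


# ---------------------------------------------------------------------------
# Set-level evaluations
# ---------------------------------------------------------------------------

def evaluate_external_sets(
    fc: pd.DataFrame,
    expr: ExpressionMatrix,
    groups: SampleGroups,
    sets: GeneSetCollection,
    n_background: int = 1000,
    seed: int = 0,
    background_mode: str = "range",
) -> list[SetComparisonResult]:
    """Compare each external gene set to an expression-matched background.

    Two rank-sum comparisons per set: (i) median log2 expression level
    across all retained samples, and (ii) absolute log2 fold change
    between the groups. The background is re-drawn per set. Sets with no
    gene in the expression matrix are skipped with a log message.
    """
    sample_ids = [s for s in expr.sample_ids if s in groups.labels]
    levels = np.log2(expr.data.loc[:, sample_ids] + DEFAULT_PSEUDOCOUNT).median(axis=1)
    universe = set(expr.gene_ids)
    results: list[SetComparisonResult] = []
    rng = np.random.default_rng(seed)
    for set_name in sorted(sets.names()):
        members = sets[set_name] & universe
        if not members:
            logger.info("gene set %r has no gene in the expression matrix; skipped", set_name)
            continue
        bg = matched_background(
            members, levels, universe, n_background,
            seed=int(rng.integers(2**31)), mode=background_mode,
        )
        results.append(
            wilcoxon_rank_sum(
                levels.loc[sorted(members)], levels.loc[sorted(bg)],
                name=f"{set_name}:expression_level",
            )
        )
        results.append(
            wilcoxon_rank_sum(
                fc.loc[sorted(members & set(fc.index)), "abs_log2_fc"],
                fc.loc[sorted(bg & set(fc.index)), "abs_log2_fc"],
                name=f"{set_name}:abs_log2_fc",
            )
        )
    return results


def inhibitor_response_comparison(
    paired: pd.DataFrame,
    target_sets: GeneSetCollection,
    n_controls: int = 5000,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[SetComparisonResult]:
    """Targets' |log2 fold change| under inhibition vs random control genes.

    ``paired`` needs columns gene, expr_before, expr_after. Genes with a
    missing after-value are dropped (logged). Controls are drawn
    uniformly from the non-target genes; when fewer than ``n_controls``
    are available all of them are used (warned). Alternative 'greater':
    targets are expected to respond more than controls.
    """
    frame = paired.copy()
    missing = frame["expr_after"].isna() | frame["expr_before"].isna()
    if missing.any():
        logger.info("dropping %d gene(s) with missing paired values", int(missing.sum()))
        frame = frame[~missing]
    frame = frame.set_index("gene")
    abs_fc = np.abs(
        np.log2((frame["expr_after"] + pseudocount) / (frame["expr_before"] + pseudocount))
    )
    rng = np.random.default_rng(seed)
    results = []
    for set_name in sorted(target_sets.names()):
        members = sorted(target_sets[set_name] & set(abs_fc.index))
        if not members:
            results.append(SetComparisonResult(
                name=set_name, n_set=0, n_background=0, statistic=np.nan,
                p=np.nan, direction="none", status="skipped: no genes in table"))
            continue
        pool = sorted(set(abs_fc.index) - set(members))
        if not pool:
            results.append(SetComparisonResult(
                name=set_name, n_set=len(members), n_background=0, statistic=np.nan,
                p=np.nan, direction="none", status="skipped: no control genes"))
            continue
        if len(pool) <= n_controls:
            if len(pool) < n_controls:
                logger.warning("only %d control genes available (< %d)", len(pool), n_controls)
            controls = pool
        else:
            controls = list(rng.choice(pool, size=n_controls, replace=False))
        results.append(
            wilcoxon_rank_sum(
                abs_fc.loc[members], abs_fc.loc[controls],
                alternative="greater", name=f"{set_name}:inhibitor_abs_fc",
            )
        )
    return results


def shrna_comparison(
    shrna: pd.DataFrame,
    down_targets: set[str],
    up_targets: set[str],
    n_controls: int = 5000,
    seed: int = 0,
) -> list[SetComparisonResult]:
    """Proliferation effects of silencing down- vs up-regulated targets.

    Gene-level value = median log2 depletion ratio over cell lines (and
    probes). Down-regulated targets are compared against controls with
    alternative 'greater' (silencing a suppressor boosts growth),
    up-regulated targets with 'less'. Targets absent from the screen are
    dropped by intersection; an empty set yields a 'skipped' result.
    """
    per_gene = shrna.groupby("gene")["log2_ratio"].median()
    rng = np.random.default_rng(seed)
    d = sorted(down_targets & set(per_gene.index))
    u = sorted(up_targets & set(per_gene.index))
    pool = sorted(set(per_gene.index) - set(d) - set(u))
    if len(pool) > n_controls:
        controls = list(rng.choice(pool, size=n_controls, replace=False))
    else:
        controls = pool
    results = []
    for name, members, alternative in (
        ("down_targets_vs_controls", d, "greater"),
        ("up_targets_vs_controls", u, "less"),
    ):
        if not members or not controls:
            results.append(SetComparisonResult(
                name=name, n_set=len(members), n_background=len(controls),
                statistic=np.nan, p=np.nan, direction="none",
                status="skipped: empty set after intersection"))
            continue
        results.append(
            wilcoxon_rank_sum(
                per_gene.loc[members], per_gene.loc[controls],
                alternative=alternative, name=name,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Overlap and enrichment
# ---------------------------------------------------------------------------

def percent_overlap(
    set_a: set[str], set_b: set[str], denominator: str = "a"
) -> tuple[int, float]:
    """Overlap count and percentage relative to one of the two sets.

    Returns (|A intersect B|, 100 * count / |denominator set|) with the
    raw percentage; round for integer reporting.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    if denominator not in ("a", "b"):
        raise ValueError("denominator must be 'a' or 'b'")
    count = len(set_a & set_b)
    denom = len(set_a) if denominator == "a" else len(set_b)
    return count, 100.0 * count / denom


def overrepresentation_test(
    hits: set[str], annotation: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation of hits in an annotation.

    Returns (overlap count, P[overlap >= observed]) for |hits| draws
    without replacement from a universe containing |annotation| marked
    genes. An open-method substitute for proprietary pathway-enrichment
    scores.
    """
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not annotation <= universe:
        raise ValueError("annotation must be a subset of the universe")
    overlap = len(hits & annotation)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(annotation), len(hits)))
    return overlap, min(p, 1.0)
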