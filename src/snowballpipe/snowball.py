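"""Snowball: resampling-aggregated distance-based association ranking.

The method asks, for every gene, how strongly the joint (co-)expression of
random small groups of genes containing it separates mutant from wild-type
samples, and aggregates that evidence over many resampling rounds. The
per-subset statistic is the PERMANOVA-style pseudo-F computed from the
Euclidean distance between sample profiles over the subset's standardized
log2 expression:

    F = [tr(H G H) / (p - 1)] / [tr((I - H) G (I - H)) / (n - p)]

with G the Gower-centered inner-product form of the squared distances and
H the hat matrix of the two-group indicator design (p = 2). For a single
gene and Euclidean distance this reduces exactly to the classical one-way
ANOVA F, which the tests exploit as an oracle.

Each round partitions the genes into disjoint subsets of size k; every
member gene is assigned its subset's pseudo-F, and a gene's score S_g is
the mean over rounds. Significance is calibrated by repeating the whole
aggregation on label-permuted data and pooling the null scores across
genes, which preserves the gene-gene correlation structure under the null.

For Euclidean distances the two traces equal the between- and within-group
sums of squares summed over the subset's genes, so the per-round subset
statistics are computed from per-gene sums of squares without building any
distance matrix; a test asserts equality with the explicit Gower-kernel
route to 1e-10 relative tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleGroups

logger = logging.getLogger(__name__)


@dataclass
class DistanceKernel:
    """Gower-centered inner-product form G of a sample distance matrix."""

    g: np.ndarray
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return self.g.shape[0]


@dataclass(frozen=True)
class SnowballParams:
    """Tuning knobs of the aggregation.

    k: genes per resampled subset; b_rounds: resampling rounds; n_perm:
    label permutations for the pooled null; alpha: selection threshold on
    the BH-adjusted empirical p.
    """

    k: int = 50
    b_rounds: int = 100
    n_perm: int = 199
    alpha: float = 0.05
    distance_metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.b_rounds < 1:
            raise ValueError("b_rounds must be >= 1")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")


@dataclass
class SnowballResult:
    """Per-gene aggregated score, rank (1 = strongest), empirical p/q, flag."""

    table: pd.DataFrame  # columns: gene, score, rank, p, q, selected
    params: SnowballParams

    @property
    def selected_genes(self) -> list[str]:
        sel = self.table[self.table["selected"]].sort_values("rank")
        return list(sel["gene"])


# ---------------------------------------------------------------------------
# Distance-based statistic
# ---------------------------------------------------------------------------

def gower_center(distances: np.ndarray, metric: str = "euclidean") -> DistanceKernel:
    """Gower-center a distance matrix: G = -1/2 J A J, A_ij = d_ij^2.

    J = I - 11'/n is the centering projector; G recovers inner products
    about the centroid, so its rows and columns sum to zero.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (distances < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(distances), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    a = -0.5 * distances**2
    row_mean = a.mean(axis=1, keepdims=True)
    col_mean = a.mean(axis=0, keepdims=True)
    g = a - row_mean - col_mean + a.mean()
    return DistanceKernel(g=g, metric=metric)


def _as_indicator(groups, n: int, sample_ids=None) -> np.ndarray:
    if isinstance(groups, SampleGroups):
        if sample_ids is None:
            sample_ids = groups.retained_samples
        b = groups.indicator(sample_ids)
    else:
        arr = np.asarray(groups)
        b = arr == "MUT" if arr.dtype.kind in "UO" else arr.astype(bool)
    if b.shape[0] != n:
        raise ValueError(f"group vector length {b.shape[0]} != kernel size {n}")
    if b.sum() == 0 or b.sum() == b.shape[0]:
        raise ValueError("both groups must be non-empty")
    return b


def pseudo_f(kernel: DistanceKernel, groups, sample_ids=None) -> float:
    """PERMANOVA pseudo-F for a two-group design on a centered kernel.

    Returns +inf (with a warning) when the residual trace is zero, i.e.
    perfect multivariate separation of the groups.
    """
    g = kernel.g
    b = _as_indicator(groups, g.shape[0], sample_ids)
    return _pseudo_f_from_kernel(g, b)


def _pseudo_f_from_kernel(g: np.ndarray, b: np.ndarray) -> float:
    n = g.shape[0]
    n1 = int(b.sum())
    n0 = n - n1
    q1 = float(b @ g @ b)
    q0 = float((~b) @ g @ (~b))
    tr_between = q1 / n1 + q0 / n0
    tr_total = float(np.trace(g))
    tr_within = tr_total - tr_between
    if tr_within <= 1e-12 * max(tr_total, 1.0):
        logger.warning("zero residual trace: perfect group separation")
        return math.inf
    return (tr_between / 1.0) / (tr_within / (n - 2))


def permutation_pvalue(
    kernel: DistanceKernel,
    groups,
    n_perm: int = 199,
    seed: int = 0,
    sample_ids=None,
) -> tuple[float, float]:
    """Permutation p-value for the pseudo-F by shuffling group labels.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm). When the number
    of distinct label assignments does not exceed ``n_perm`` the exact
    null is enumerated instead and p is the exact tail fraction.
    """
    g = kernel.g
    n = g.shape[0]
    b = _as_indicator(groups, n, sample_ids)
    n1 = int(b.sum())
    observed = _pseudo_f_from_kernel(g, b)

    n_distinct = math.comb(n, n1)
    if n_distinct <= n_perm:
        logger.info("enumerating all %d label assignments exactly", n_distinct)
        count = 0
        for idx in combinations(range(n), n1):
            bb = np.zeros(n, dtype=bool)
            bb[list(idx)] = True
            if _pseudo_f_from_kernel(g, bb) >= observed - 1e-12:
                count += 1
        return observed, count / n_distinct

    rng = np.random.default_rng(seed)
    perm_matrix = np.empty((n_perm, n), dtype=bool)
    for r in range(n_perm):
        perm_matrix[r] = rng.permutation(b)
    f_perm = _batch_pseudo_f(g, perm_matrix)
    p = (1 + int((f_perm >= observed - 1e-12).sum())) / (1 + n_perm)
    return observed, p


def _batch_pseudo_f(g: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """Pseudo-F for many label vectors at once.

    Uses tr(HGH) = sum_g (1_g' G 1_g)/n_g; for a centered G the two group
    quadratic forms are equal (b'Gb = (1-b)'G(1-b)), checked in tests.
    """
    n = g.shape[0]
    bf = indicators.astype(float)
    n1 = bf.sum(axis=1)
    n0 = n - n1
    q1 = np.einsum("ri,ij,rj->r", bf, g, bf, optimize=True)
    tr_between = q1 * (1.0 / n1 + 1.0 / n0)
    tr_total = float(np.trace(g))
    tr_within = tr_total - tr_between
    with np.errstate(divide="ignore"):
        return np.where(
            tr_within <= 1e-12 * max(tr_total, 1.0),
            np.inf,
            tr_between / (tr_within / (n - 2)),
        )


# ---------------------------------------------------------------------------
# Aggregated scoring
# ---------------------------------------------------------------------------

def standardize_log2(expr: ExpressionMatrix, sample_ids=None) -> pd.DataFrame:
    """log2(x+1) then per-gene z-scoring (ddof=1); constant genes -> 0."""
    data = expr.log2_values()
    if sample_ids is not None:
        data = data.loc[:, list(sample_ids)]
    values = data.to_numpy()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("%d constant gene(s) standardized to zero", int(flat.sum()))
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=data.index, columns=data.columns)


def _per_gene_ss(z: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-group sums of squares per gene (row)."""
    n = z.shape[1]
    n1 = int(b.sum())
    n0 = n - n1
    gm = z.mean(axis=1)
    m1 = z[:, b].mean(axis=1)
    m0 = z[:, ~b].mean(axis=1)
    ssb = n1 * (m1 - gm) ** 2 + n0 * (m0 - gm) ** 2
    sst = ((z - gm[:, None]) ** 2).sum(axis=1)
    return ssb, np.maximum(sst - ssb, 0.0)


def _aggregate_rounds(
    ssb: np.ndarray, ssw: np.ndarray, n: int, k: int, b_rounds: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean subset pseudo-F per gene over random disjoint partitions.

    Each round shuffles the gene order and chunks it into subsets of size
    k (a trailing chunk of size 1 is merged into its neighbor); the
    subset statistic sum(SSB)/(sum(SSW)/(n-2)) is assigned to every
    member.
    """
    n_genes = ssb.shape[0]
    totals = np.zeros(n_genes)
    for _ in range(b_rounds):
        order = rng.permutation(n_genes)
        bounds = list(range(0, n_genes, k))
        # trailing singleton cannot form a subset: fold into previous chunk
        if len(bounds) > 1 and n_genes - bounds[-1] < 2:
            bounds = bounds[:-1]
        for start_idx, start in enumerate(bounds):
            stop = bounds[start_idx + 1] if start_idx + 1 < len(bounds) else n_genes
            members = order[start:stop]
            ssb_sum = ssb[members].sum()
            ssw_sum = ssw[members].sum()
            if ssw_sum <= 1e-12:
                f = np.inf if ssb_sum > 0 else 0.0
            else:
                f = ssb_sum / (ssw_sum / (n - 2))
            totals[members] += f
    return totals / b_rounds


def snowball_scores(
    expr: ExpressionMatrix, groups: SampleGroups, params: SnowballParams
) -> SnowballResult:
    """Score, rank and select genes by aggregated association with the label.

    The empirical p-value of gene g is the pooled-null tail fraction
    (1 + #{null scores >= S_g}) / (1 + n_null) over ``n_perm`` repeats of
    the full aggregation with shuffled labels; q-values are
    Benjamini-Hochberg. Deterministic for a given seed and params.
    """
    sample_ids = [s for s in expr.sample_ids if s in groups.labels]
    if params.k > len(expr.gene_ids):
        raise ValueError(f"k={params.k} exceeds number of genes {len(expr.gene_ids)}")
    z_frame = standardize_log2(expr, sample_ids)
    z = z_frame.to_numpy()
    b = groups.indicator(sample_ids)
    if b.sum() < 2 or (~b).sum() < 2:
        raise ValueError("need at least 2 samples in each group")
    n = z.shape[1]
    genes = np.array(z_frame.index)

    rng = np.random.default_rng(params.seed)
    ssb, ssw = _per_gene_ss(z, b)
    scores = _aggregate_rounds(ssb, ssw, n, params.k, params.b_rounds, rng)

    null_scores = np.empty((params.n_perm, len(genes)))
    for r in range(params.n_perm):
        b_perm = rng.permutation(b)
        ssb_p, ssw_p = _per_gene_ss(z, b_perm)
        null_scores[r] = _aggregate_rounds(ssb_p, ssw_p, n, params.k, params.b_rounds, rng)
    null_pool = np.sort(null_scores.ravel())

    n_null = null_pool.size
    ge_counts = n_null - np.searchsorted(null_pool, scores - 1e-12, side="left")
    pvals = (1 + ge_counts) / (1 + n_null)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    order = np.lexsort((genes, -scores))  # score desc, ties by gene id
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(1, len(genes) + 1)

    table = pd.DataFrame(
        {
            "gene": genes,
            "score": scores,
            "rank": ranks,
            "p": pvals,
            "q": qvals,
            "selected": qvals <= params.alpha,
        }
    ).sort_values("rank", ignore_index=True)
    return SnowballResult(table=table, params=params)


def select_candidates(result: SnowballResult, alpha: float | None = None) -> list[str]:
    """Genes with q <= alpha, ordered by rank (1 = strongest)."""
    if alpha is None:
        alpha = result.params.alpha
    table = result.table
    sel = table[table["q"] <= alpha].sort_values("rank")
    return list(sel["gene"])
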