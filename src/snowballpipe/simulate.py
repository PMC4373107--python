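"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes in a
driver-mutation cohort: correlated gene modules whose mean expression (and
hence co-expression pattern relative to the grouping) depends on mutation
status, Beta-distributed CpG methylation with a planted loss of methylation
in the mutant group, and downstream read-outs — an shRNA proliferation
screen and a paired before/after kinase-inhibitor expression table — whose
effects are anti-correlated with the planted regulation direction.

Expression is simulated on the log2 scale as a single-latent-factor model
per module (equal loadings sqrt(within_module_corr)), then mapped to a
count-like scale by 2**x - 1 so that the pipeline's log2(x+1) transform
approximately recovers the generating scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MethylationMatrix, SampleGroups, MUT, WT

logger = logging.getLogger(__name__)

#: Beta-distribution concentration for simulated 450K-like beta values.
BETA_CONCENTRATION = 20.0

UP = "up"
DOWN = "down"
NONE = "none"


class ConfigurationError(ValueError):
    """An infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator parameters.

    Expression parameters are on the log2 scale; ``delta_beta_effect`` is
    the planted MUT - WT difference in mean beta (negative = methylation
    loss in mutants). Defaults reflect a driver-mutation cohort of the
    size studied here: two balanced groups of 30 samples, 300 genes in six
    modules of 20 (two of them mutation-responsive, one shifted up and one
    down by 1.5 log2 units), and 10,000 CpG loci of which 1% carry a
    planted hypomethylation of 0.25.
    """

    n_mut: int = 30
    n_wt: int = 30
    n_genes: int = 300
    n_modules: int = 6
    module_size: int = 20
    n_responsive_modules: int = 2
    mean_shift: float = 1.5
    within_module_corr: float = 0.8
    noise_sd: float = 0.5
    n_loci: int = 10_000
    frac_hypo: float = 0.01
    delta_beta_effect: float = -0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mut < 2 or self.n_wt < 2:
            raise ConfigurationError("need at least 2 samples per group")
        if self.n_responsive_modules > self.n_modules:
            raise ConfigurationError("n_responsive_modules exceeds n_modules")
        if self.module_size * self.n_modules > self.n_genes:
            raise ConfigurationError("module_size * n_modules exceeds n_genes")
        if not (0 <= self.within_module_corr < 1):
            raise ConfigurationError("within_module_corr must be in [0, 1)")
        if abs(self.delta_beta_effect) > 0.5:
            raise ConfigurationError("|delta_beta_effect| must be <= 0.5")
        if not (0 <= self.frac_hypo <= 1):
            raise ConfigurationError("frac_hypo must be in [0, 1]")
        if self.noise_sd < 0 or self.mean_shift < 0:
            raise ConfigurationError("noise_sd and mean_shift must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Planted ground truth: per-gene module/direction, per-locus hypo flag."""

    genes: pd.DataFrame  # index gene; columns module, responsive, direction, true_shift
    loci: pd.DataFrame = field(default_factory=pd.DataFrame)  # index locus; column hypomethylated

    @property
    def responsive_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["responsive"]])

    @property
    def up_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["direction"] == UP])

    @property
    def down_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["direction"] == DOWN])

    @property
    def null_genes(self) -> list[str]:
        return list(self.genes.index[~self.genes["responsive"]])

    @property
    def hypo_loci(self) -> list[str]:
        if self.loci.empty:
            return []
        return list(self.loci.index[self.loci["hypomethylated"]])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _locus_ids(n: int) -> list[str]:
    width = max(8, len(str(n)))
    return [f"cg{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, MethylationMatrix, SampleGroups, SimulationTruth]:
    """Generate matched expression and methylation profiles with ground truth.

    Responsive modules alternate direction (first up in MUT, second down,
    ...); the group mean shift applies to every gene of a responsive
    module. Methylation betas are drawn per locus from Beta distributions
    with fixed concentration; planted loci get a MUT-group mean decreased
    by ``|delta_beta_effect|``. Fully reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mut + config.n_wt
    sample_ids = [f"MUT_{i:03d}" for i in range(1, config.n_mut + 1)] + [
        f"WT_{i:03d}" for i in range(1, config.n_wt + 1)
    ]
    is_mut = np.array([True] * config.n_mut + [False] * config.n_wt)
    groups = SampleGroups({s: (MUT if m else WT) for s, m in zip(sample_ids, is_mut)})

    genes = _gene_ids(config.n_genes)
    module_of = np.zeros(config.n_genes, dtype=int)
    for m in range(config.n_modules):
        module_of[m * config.module_size : (m + 1) * config.module_size] = m + 1

    # direction per module: responsive modules alternate up/down
    direction_of_module = {0: NONE}
    for m in range(1, config.n_modules + 1):
        if m <= config.n_responsive_modules:
            direction_of_module[m] = UP if m % 2 == 1 else DOWN
        else:
            direction_of_module[m] = NONE

    loading = np.sqrt(config.within_module_corr)
    factors = rng.normal(size=(config.n_modules, n))
    # orthogonalize factors in-sample (centered, unit variance) so planted
    # between-module correlation is exactly zero rather than O(1/sqrt(n))
    factors = factors - factors.mean(axis=1, keepdims=True)
    if config.n_modules > 1 and n > config.n_modules:
        q, _ = np.linalg.qr(factors.T)
        factors = q.T[: config.n_modules]
        factors = factors - factors.mean(axis=1, keepdims=True)
    factors = factors / factors.std(axis=1, ddof=1, keepdims=True)
    baseline = rng.uniform(3.0, 10.0, size=config.n_genes)
    # background genes get matched total variance so expression spread does
    # not give module membership away
    background_sd = np.sqrt(config.within_module_corr + config.noise_sd**2)

    log2_expr = np.empty((config.n_genes, n))
    shifts = np.zeros(config.n_genes)
    for g in range(config.n_genes):
        m = module_of[g]
        if m == 0:
            signal = rng.normal(scale=background_sd, size=n)
        else:
            signal = loading * factors[m - 1] + rng.normal(scale=config.noise_sd, size=n)
        d = direction_of_module[m]
        if d == UP:
            shifts[g] = config.mean_shift
        elif d == DOWN:
            shifts[g] = -config.mean_shift
        log2_expr[g] = baseline[g] + signal + shifts[g] * is_mut

    values = np.clip(2.0**log2_expr - 1.0, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))

    gene_truth = pd.DataFrame(
        {
            "module": module_of,
            "responsive": [direction_of_module[m] != NONE for m in module_of],
            "direction": [direction_of_module[m] for m in module_of],
            "true_shift": shifts,
        },
        index=pd.Index(genes, name="gene"),
    )

    loci = _locus_ids(config.n_loci)
    n_hypo = int(round(config.frac_hypo * config.n_loci))
    hypo_flags = np.zeros(config.n_loci, dtype=bool)
    hypo_flags[:n_hypo] = True
    mu_wt = np.empty(config.n_loci)
    mu_wt[:n_hypo] = rng.uniform(0.4, 0.8, size=n_hypo)
    mu_wt[n_hypo:] = rng.uniform(0.1, 0.9, size=config.n_loci - n_hypo)
    mu_mut = mu_wt.copy()
    mu_mut[:n_hypo] = np.clip(mu_wt[:n_hypo] + config.delta_beta_effect, 0.02, 0.98)

    c = BETA_CONCENTRATION
    beta = np.empty((config.n_loci, n))
    beta[:, is_mut] = rng.beta(
        mu_mut[:, None] * c, (1 - mu_mut[:, None]) * c, size=(config.n_loci, config.n_mut)
    )
    beta[:, ~is_mut] = rng.beta(
        mu_wt[:, None] * c, (1 - mu_wt[:, None]) * c, size=(config.n_loci, config.n_wt)
    )
    meth = MethylationMatrix(pd.DataFrame(beta, index=loci, columns=sample_ids))

    locus_truth = pd.DataFrame(
        {"hypomethylated": hypo_flags, "true_delta_beta": mu_mut - mu_wt},
        index=pd.Index(loci, name="locus"),
    )
    truth = SimulationTruth(genes=gene_truth, loci=locus_truth)
    return expr, meth, groups, truth


def simulate_shrna_screen(
    truth: SimulationTruth,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    n_cell_lines: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a pooled shRNA depletion screen over the truth's genes.

    Silencing a down-regulated target (a putative suppressor) increases
    proliferation, so those genes get mean log2 abundance ratio +effect;
    up-regulated targets get -effect; null genes 0. Gaussian noise with
    ``noise_sd`` is added per (gene, cell line).
    """
    if effect < 0:
        raise ConfigurationError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    direction = truth.genes["direction"]
    mean = np.where(direction == DOWN, effect, np.where(direction == UP, -effect, 0.0))
    cell_lines = [f"CL{i}" for i in range(1, n_cell_lines + 1)]
    rows = []
    for j, cl in enumerate(cell_lines):
        noise = rng.normal(scale=noise_sd, size=len(mean)) if noise_sd > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "gene": truth.genes.index,
                    "cell_line": cl,
                    "log2_ratio": mean + noise,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_inhibitor_response(
    truth: SimulationTruth,
    reversal: float = 0.8,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paired expression before/after driver inhibition.

    Target genes move back toward their wild-type level: up-regulated
    targets lose ``reversal`` log2 units after treatment, down-regulated
    targets gain it, null genes stay put (plus noise). In the noise-free
    limit every target has |log2 fold change| exactly equal to
    ``reversal`` under the pipeline's log2(x+1) convention.
    """
    if reversal < 0:
        raise ConfigurationError("reversal must be >= 0")
    rng = np.random.default_rng(seed)
    genes = truth.genes.index
    direction = truth.genes["direction"]
    delta = np.where(direction == UP, -reversal, np.where(direction == DOWN, reversal, 0.0))
    before_log2 = rng.uniform(3.0, 10.0, size=len(genes))
    noise = rng.normal(scale=noise_sd, size=len(genes)) if noise_sd > 0 else 0.0
    after_log2 = before_log2 + delta + noise
    return pd.DataFrame(
        {
            "gene": genes,
            "expr_before": 2.0**before_log2 - 1.0,
            "expr_after": np.clip(2.0**after_log2 - 1.0, 0.0, None),
        }
    )
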