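"""Differential DNA methylation between mutant and wild-type groups.

Beta values (methylated fraction per CpG, in [0, 1]) are converted to
M-values, M = log2(beta / (1 - beta)) after clipping beta into
[eps, 1 - eps], because the logit-like M scale is closer to the
homoscedastic-Gaussian assumptions of the per-locus F-test. The effect
filter, however, is applied on the beta scale: a locus is called
significantly differentially methylated when the raw F-test p-value is
below ``p_threshold`` (default 1e-3) and the absolute group difference
in mean beta is at least ``effect_threshold`` (default 0.2). The summary
reports, among significant loci, the count and fraction that are
hypomethylated in mutants (delta beta < 0), plus per-locus group medians
for density plots and the |delta beta| > 0.1 labeling flags.

Missing betas are allowed; statistics are pairwise-complete per locus and
loci with too few observed values per group are skipped from testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .io import MethylationMatrix, SampleGroups

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-3
DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_EFFECT_THRESHOLD = 0.2
#: minimum observed betas per group for a locus to be tested
DEFAULT_MIN_OBS_PER_GROUP = 3


@dataclass
class MValueMatrix:
    """Loci x samples M-values; NaN marks missing input betas."""

    data: pd.DataFrame
    epsilon: float = DEFAULT_EPSILON


@dataclass
class MethylationSummary:
    """Global-methylation-loss summary over the significant loci."""

    per_locus: pd.DataFrame  # locus, median_beta_mut, median_beta_wt, delta_beta, labeled
    n_significant: int
    n_hypomethylated: int
    hypo_fraction: float | None  # None when there are no significant loci

    @property
    def hypo_percent(self) -> str:
        """Percent hypomethylated among significant loci, 1 decimal; 'NA' if none."""
        if self.hypo_fraction is None:
            return "NA"
        return f"{100.0 * self.hypo_fraction:.1f}"


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """M-value transform, strictly increasing in beta on [eps, 1 - eps].

    Scalar in, scalar out; arrays pass through elementwise. NaN (missing)
    propagates.
    """
    if not (0 < epsilon < 0.5):
        raise ValueError("epsilon must be in (0, 0.5)")
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = (arr < 0) | (arr > 1)
    if out_of_range.any():
        raise ValueError(f"beta value(s) outside [0, 1]: {arr[out_of_range][:5]}")
    clipped = np.clip(arr, epsilon, 1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (exact on the unclipped range)."""
    arr = np.asarray(m, dtype=float)
    beta = 2.0**arr / (1.0 + 2.0**arr)
    return float(beta) if np.isscalar(m) else beta


def m_value_matrix(meth: MethylationMatrix, epsilon: float = DEFAULT_EPSILON) -> MValueMatrix:
    values = beta_to_m(meth.data.to_numpy(), epsilon)
    return MValueMatrix(
        data=pd.DataFrame(values, index=meth.data.index, columns=meth.data.columns),
        epsilon=epsilon,
    )


def dmp_test(
    m: MValueMatrix,
    groups: SampleGroups,
    min_obs_per_group: int = DEFAULT_MIN_OBS_PER_GROUP,
) -> pd.DataFrame:
    """Per-locus two-group F-test on M-values.

    F = between-group mean square / within-group mean square with p from
    the F(1, n - 2) reference distribution, n the observed sample count
    at the locus. Loci with fewer than ``min_obs_per_group`` observed
    values in either group are skipped (logged). A locus with zero
    within-group variance but a group difference gets p = 0 and a flag.

    Returns a frame indexed by locus with columns F, p, n_used,
    zero_variance.
    """
    sample_ids = [s for s in m.data.columns if s in groups.labels]
    values = m.data.loc[:, sample_ids].to_numpy()
    b = groups.indicator(sample_ids)

    obs = np.isfinite(values)
    n1 = obs[:, b].sum(axis=1)
    n0 = obs[:, ~b].sum(axis=1)
    testable = (n1 >= min_obs_per_group) & (n0 >= min_obs_per_group)
    n_skip = int((~testable).sum())
    if n_skip:
        logger.info("skipping %d locus/loci with < %d observed values in a group",
                    n_skip, min_obs_per_group)

    masked = np.where(obs, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum1 = masked[:, b].sum(axis=1)
        sum0 = masked[:, ~b].sum(axis=1)
        m1 = sum1 / n1
        m0 = sum0 / n0
        n = n1 + n0
        gm = (sum1 + sum0) / n
        ssb = n1 * (m1 - gm) ** 2 + n0 * (m0 - gm) ** 2
        sq = np.where(obs, (values - gm[:, None]) ** 2, 0.0)
        sst = sq.sum(axis=1)
        ssw = np.maximum(sst - ssb, 0.0)
        msw = ssw / (n - 2)

    f_stat = np.full(values.shape[0], np.nan)
    pvals = np.full(values.shape[0], np.nan)
    zero_var = np.zeros(values.shape[0], dtype=bool)
    idx = np.where(testable)[0]
    for i in idx:
        if msw[i] <= 1e-300:
            zero_var[i] = True
            if ssb[i] > 0:
                f_stat[i] = np.inf
                pvals[i] = 0.0
            else:
                f_stat[i] = 0.0
                pvals[i] = 1.0
        else:
            f_stat[i] = ssb[i] / msw[i]
            pvals[i] = f_dist.sf(f_stat[i], 1, n[i] - 2)

    frame = pd.DataFrame(
        {"F": f_stat, "p": pvals, "n_used": n, "zero_variance": zero_var},
        index=m.data.index.rename("locus"),
    )
    return frame[testable]


def delta_beta(meth: MethylationMatrix, groups: SampleGroups) -> pd.Series:
    """Per-locus mean beta difference, MUT minus WT (pairwise-complete).

    Loci with no observed value in either group are dropped.
    """
    sample_ids = [s for s in meth.data.columns if s in groups.labels]
    values = meth.data.loc[:, sample_ids].to_numpy()
    b = groups.indicator(sample_ids)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(values[:, b], axis=1)
        m0 = np.nanmean(values[:, ~b], axis=1)
    out = pd.Series(m1 - m0, index=meth.data.index.rename("locus"), name="delta_beta")
    return out.dropna()


def select_dmps(
    tests: pd.DataFrame,
    deltas: pd.Series,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    effect_threshold: float = DEFAULT_EFFECT_THRESHOLD,
    m_effects: pd.Series | None = None,
    effect_scale: str = "delta_beta",
) -> pd.DataFrame:
    """Call differentially methylated positions by p and effect thresholds.

    significant <=> p < p_threshold AND |effect| >= effect_threshold. The
    effect is the beta-scale group difference by default; pass
    ``effect_scale="m"`` with ``m_effects`` to threshold the M-scale
    group coefficient instead. Output rows are sorted by (p, locus id)
    and carry locus, F, p, delta_beta, significant.
    """
    if p_threshold <= 0 or effect_threshold < 0:
        raise ValueError("thresholds must be positive")
    if effect_scale not in ("delta_beta", "m"):
        raise ValueError("effect_scale must be 'delta_beta' or 'm'")
    common = tests.index.intersection(deltas.index)
    frame = tests.loc[common, ["F", "p"]].copy()
    frame["delta_beta"] = deltas.loc[common]
    if effect_scale == "m":
        if m_effects is None:
            raise ValueError("effect_scale='m' requires m_effects")
        effect = m_effects.loc[common].abs()
    else:
        effect = frame["delta_beta"].abs()
    frame["significant"] = (frame["p"] < p_threshold) & (effect >= effect_threshold)
    frame = frame.rename_axis("locus").reset_index()
    return frame.sort_values(["p", "locus"], kind="mergesort", ignore_index=True)


def methylation_summary(
    meth: MethylationMatrix, groups: SampleGroups, dmps: pd.DataFrame
) -> MethylationSummary:
    """Summarize global methylation loss and emit plot-ready medians.

    ``dmps`` is the output of :func:`select_dmps` on the same matrix.
    Loci with |delta beta| > 0.1 are flagged for plot labeling.
    """
    sample_ids = [s for s in meth.data.columns if s in groups.labels]
    values = meth.data.loc[:, sample_ids].to_numpy()
    b = groups.indicator(sample_ids)
    with np.errstate(invalid="ignore"):
        med_mut = np.nanmedian(values[:, b], axis=1)
        med_wt = np.nanmedian(values[:, ~b], axis=1)
        m1 = np.nanmean(values[:, b], axis=1)
        m0 = np.nanmean(values[:, ~b], axis=1)
    db = m1 - m0
    per_locus = pd.DataFrame(
        {
            "locus": meth.data.index,
            "median_beta_mut": med_mut,
            "median_beta_wt": med_wt,
            "delta_beta": db,
            "labeled": np.abs(db) > 0.1,
        }
    )
    sig = dmps[dmps["significant"]]
    n_sig = int(len(sig))
    n_hypo = int((sig["delta_beta"] < 0).sum())
    fraction = (n_hypo / n_sig) if n_sig else None
    return MethylationSummary(
        per_locus=per_locus,
        n_significant=n_sig,
        n_hypomethylated=n_hypo,
        hypo_fraction=fraction,
    )
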