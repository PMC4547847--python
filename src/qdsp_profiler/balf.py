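"""BALF vs tissue compartment analysis.

Bronchoalveolar lavage fluid (BALF) samples the epithelial lining fluid (ELF)
of the airway and alveolar lumen, but sensitive MS also picks up proteins that
leak from tissue or lyse from cells.  Genuine ELF residents are separated from
leakage by a SAM-style enrichment score computed per protein between the BALF
and tissue compartments:

    d = (mean_BALF - mean_tissue) / (s + s0)

where s is the gene-specific scatter (the pooled standard error of the mean
difference) and s0 is a small exchangeability constant that damps inflated
scores at low variance.  At s0 = 0, d is exactly the pooled-variance
two-sample t statistic and its p-value comes from the t reference; for s0 > 0
the t reference is invalid and significance comes from a label-permutation
null.  Proteins with positive d significant at the chosen FDR are called
ELF-enriched.

The module also provides the day-14 differential t-test and the BALF
time-course ANOVA (ratios against the mean of all control BALF replicates
pooled across time points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._groupstats import ttest_matrix
from .enrichment import bh_fdr
from .io import IntensityTable
from .timecourse import ImputationParams, anova_timecourse, compute_ratios

logger = logging.getLogger(__name__)

MAX_EXACT_PERMUTATIONS = 10_000


@dataclass
class SamParams:
    """SAM d-statistic parameters.

    ``s0_rule`` selects the exchangeability constant: FIXED uses ``s0`` as
    given; PERCENTILE sets s0 to the ``s0_percentile``-th percentile of the
    per-protein scatter distribution (default 5); CV_MIN picks the percentile
    that minimizes the coefficient of variation of the d-statistic's spread
    across scatter deciles (the classic automatic tuning).
    """

    s0: float = 0.0
    s0_rule: str = "PERCENTILE"
    s0_percentile: float = 5.0
    n_permutations: int = MAX_EXACT_PERMUTATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.s0_rule not in ("FIXED", "PERCENTILE", "CV_MIN"):
            raise ValueError("s0_rule must be FIXED, PERCENTILE or CV_MIN")
        if not 0 <= self.s0_percentile <= 100:
            raise ValueError("s0_percentile must be in [0, 100]")


def tusher_scatter(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Gene-specific scatter s(i): pooled standard error of the mean difference.

    s = sqrt{ (1/n1 + 1/n2)/(n1 + n2 - 2) * [sum dev1^2 + sum dev2^2] }.
    """
    n1 = (~np.isnan(x1)).sum(axis=-1).astype(float)
    n2 = (~np.isnan(x2)).sum(axis=-1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nansum(x1, axis=-1) / n1
        m2 = np.nansum(x2, axis=-1) / n2
        ss1 = np.maximum(np.nansum(x1 * x1, axis=-1) - n1 * m1 * m1, 0.0)
        ss2 = np.maximum(np.nansum(x2 * x2, axis=-1) - n2 * m2 * m2, 0.0)
        return np.sqrt((1 / n1 + 1 / n2) / (n1 + n2 - 2) * (ss1 + ss2))


def select_s0(s: np.ndarray, diffs: np.ndarray, rule: str, s0: float, percentile: float) -> float:
    s_valid = s[np.isfinite(s)]
    if rule == "FIXED":
        return s0
    if rule == "PERCENTILE":
        return float(np.percentile(s_valid, percentile))
    # CV_MIN: minimize the coefficient of variation of mad(d) across s-deciles
    order = np.argsort(s_valid)
    d_all = diffs[np.isfinite(s)][order]
    s_sorted = s_valid[order]
    bins = np.array_split(np.arange(s_sorted.size), 10)
    best, best_cv = 0.0, np.inf
    for alpha in np.arange(0, 100.1, 5):
        cand = float(np.percentile(s_valid, alpha))
        mads = []
        for idx in bins:
            if idx.size < 2:
                continue
            d = d_all[idx] / (s_sorted[idx] + cand)
            mads.append(stats.median_abs_deviation(d))
        mads = np.asarray(mads)
        if mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, cand
    return best


def _perm_pvalues(
    x1: np.ndarray, x2: np.ndarray, d_obs: np.ndarray, s0: float, params: SamParams
) -> np.ndarray:
    """Label-permutation two-sided p for |d| per protein, grouped by missingness
    pattern so each pattern's permutations are vectorized across proteins."""
    P = x1.shape[0]
    pvals = np.full(P, np.nan)
    masks1 = ~np.isnan(x1)
    masks2 = ~np.isnan(x2)
    patterns: dict[bytes, list[int]] = {}
    for i in range(P):
        if not np.isfinite(d_obs[i]):
            continue
        key = masks1[i].tobytes() + masks2[i].tobytes()
        patterns.setdefault(key, []).append(i)
    rng = np.random.default_rng(params.seed)
    for rows in patterns.values():
        rows = np.asarray(rows)
        m1, m2 = masks1[rows[0]], masks2[rows[0]]
        v = np.concatenate([x1[rows][:, m1], x2[rows][:, m2]], axis=1)
        n1, n = int(m1.sum()), int(m1.sum() + m2.sum())
        from math import comb

        total = comb(n, n1)
        if total <= params.n_permutations:
            sel = np.array(list(combinations(range(n), n1)), dtype=int)
            exact = True
        else:
            sel = np.argpartition(
                rng.random((params.n_permutations, n)), n1 - 1, axis=1
            )[:, :n1]
            exact = False
        K = sel.shape[0]
        ind = np.zeros((n, K))
        ind[sel.T, np.arange(K)[None, :].repeat(n1, axis=0)] = 1.0
        tot_s = v.sum(axis=1, keepdims=True)
        tot_ss = (v * v).sum(axis=1, keepdims=True)
        obs = np.abs(d_obs[rows])[:, None]
        exceed = np.zeros(rows.size)
        n2 = n - n1
        fac = (1 / n1 + 1 / n2) / (n - 2)
        for start in range(0, K, 2000):
            blk = ind[:, start : start + 2000]
            s1 = v @ blk
            ss1 = (v * v) @ blk
            s2 = tot_s - s1
            ss2 = tot_ss - ss1
            mm1 = s1 / n1
            mm2 = s2 / n2
            dev = np.maximum(ss1 - n1 * mm1 * mm1, 0) + np.maximum(ss2 - n2 * mm2 * mm2, 0)
            sperm = np.sqrt(fac * dev)
            dperm = (mm1 - mm2) / (sperm + s0)
            exceed += (np.abs(dperm) >= obs - 1e-12).sum(axis=1)
        if exact:
            pvals[rows] = exceed / K
        else:
            pvals[rows] = (1.0 + exceed) / (K + 1.0)
    return pvals


def sam_enrichment_scores(
    balf_values: pd.DataFrame,
    tissue_values: pd.DataFrame,
    params: SamParams | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """SAM-style BALF-vs-tissue enrichment score per protein.

    Inputs are aligned proteins x samples log2 matrices.  Returns per protein:
    ``d``, group means, scatter ``s``, ``p`` (pooled t reference when s0 = 0,
    permutation null otherwise), BH ``q``, and the ``elf_enriched`` call
    (d > 0 and q < fdr).  Proteins with < 2 valid values per compartment are
    untested.
    """
    params = params or SamParams()
    x1 = balf_values.to_numpy(dtype=float)
    x2 = tissue_values.to_numpy(dtype=float)
    n1 = (~np.isnan(x1)).sum(axis=1).astype(float)
    n2 = (~np.isnan(x2)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nansum(x1, axis=1) / n1
        m2 = np.nansum(x2, axis=1) / n2
    s = tusher_scatter(x1, x2)
    untested = (n1 < 2) | (n2 < 2)
    s0 = select_s0(s[~untested], (m1 - m2)[~untested], params.s0_rule, params.s0, params.s0_percentile)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (m1 - m2) / (s + s0)
    degenerate = ~untested & (s + s0 == 0)
    d[untested | degenerate] = np.nan

    if s0 == 0:
        df = n1 + n2 - 2
        p = 2.0 * stats.t.sf(np.abs(d), df)
        p[~np.isfinite(d)] = np.nan
    else:
        d_for_p = np.where(untested | degenerate, np.nan, d)
        p = _perm_pvalues(x1, x2, d_for_p, s0, params)

    res = pd.DataFrame(
        {"d": d, "mean_balf": m1, "mean_tissue": m2, "s": s, "p": p},
        index=balf_values.index,
    )
    res.loc[untested, ["mean_balf", "mean_tissue"]] = np.nan
    res["q"] = bh_fdr(res["p"])
    res["elf_enriched"] = (res["d"] > 0) & (res["q"] < fdr)
    res.attrs["s0"] = float(s0)
    return res


def balf_enrichment(
    table: IntensityTable,
    params: SamParams | None = None,
    fdr: float = 0.05,
    pool: str = "PBS",
) -> pd.DataFrame:
    """Compartment enrichment on an intensity table holding both compartments.

    By default pools the control (PBS) samples of each compartment across time
    points, mirroring the ratio-denominator pooling; ``pool="ALL"`` uses every
    sample.
    """
    samples = table.samples
    if pool != "ALL":
        samples = samples[samples["condition"] == pool]
    balf_ids = samples.index[samples["compartment"] == "BALF"]
    tissue_ids = samples.index[samples["compartment"] == "TISSUE"]
    if balf_ids.empty or tissue_ids.empty:
        raise ValueError("need samples from both BALF and TISSUE compartments")
    log2 = table.log2()
    return sam_enrichment_scores(log2[balf_ids], log2[tissue_ids], params, fdr)


def balf_day14_ttest(table: IntensityTable, welch: bool = False) -> pd.DataFrame:
    """Two-sample two-sided t-test on BALF log2 intensities at day 14."""
    samples = table.samples
    day14 = samples[(samples["compartment"] == "BALF") & (samples["timepoint_days"] == 14)]
    bleo = day14.index[day14["condition"] == "BLEO"]
    pbs = day14.index[day14["condition"] == "PBS"]
    if bleo.empty or pbs.empty:
        raise ValueError("need both BLEO and PBS BALF samples at day 14")
    import warnings as _warnings

    log2 = table.log2()
    la = log2[bleo].to_numpy()
    lb = log2[pbs].to_numpy()
    t, p = ttest_matrix(la, lb, welch=welch)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        log2fc = np.nanmean(la, axis=1) - np.nanmean(lb, axis=1)
    res = pd.DataFrame({"log2fc": log2fc, "t": t, "p": p}, index=table.values.index)
    res["q"] = bh_fdr(res["p"])
    return res


def balf_timecourse(
    table: IntensityTable, params: ImputationParams | None = None
) -> tuple[pd.DataFrame, "pd.DataFrame"]:
    """BALF time-course ANOVA on ratios against the pooled-control mean.

    Ratios use the mean of all PBS BALF replicates across time points as the
    denominator; returns (anova table, ratio matrix).
    """
    ratio_matrix = compute_ratios(
        table, params=params, denominator="mean", compartment="BALF"
    )
    return anova_timecourse(ratio_matrix), ratio_matrix
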