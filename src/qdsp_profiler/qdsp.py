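"""QDSP statistics: solubility-profile testing for detergent-fractionated proteomes.

Quantitative detergent solubility profiling (QDSP) extracts tissue into four
fractions of increasing detergent stringency (FR1, FR2, FR3, INSOL); a
protein's intensity profile across the fractions encodes its solubility and
hence its compartment (cytosolic proteins sit in FR1, extracellular matrix in
INSOL).  Injury can change a protein's total abundance, its solubility
profile, or both, and the two are separated here:

* total abundance per biological replicate = sum of the four fractions'
  linear intensities, compared between conditions by a two-sided Student t-test;
* solubility change = the treatment x fraction interaction term of a two-way
  ANOVA on per-condition mean-centered log2 profiles, so that abundance
  differences cancel and only profile shape differences remain.

Supporting summaries: share of MS intensity in the most insoluble fraction,
sample-level PCA, and correlation-distance hierarchical clustering of z-scored
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._groupstats import interaction_anova_matrix, ttest_matrix
from .enrichment import bh_fdr
from .io import CONDITIONS, QDSP_FRACTIONS, IntensityTable

logger = logging.getLogger(__name__)


def _qdsp_samples(table: IntensityTable) -> pd.DataFrame:
    samples = table.samples
    qdsp = samples[samples["fraction"].isin(QDSP_FRACTIONS)]
    if qdsp.empty:
        raise ValueError("table contains no QDSP fraction samples")
    counts = qdsp.groupby(["condition", "replicate"], observed=True)["fraction"].nunique()
    incomplete = counts[counts < len(QDSP_FRACTIONS)]
    if not incomplete.empty:
        raise ValueError(
            f"replicates missing fraction samples: {list(incomplete.index)}"
        )
    return qdsp


def total_abundance(table: IntensityTable) -> pd.DataFrame:
    """Per-protein total abundance per biological replicate.

    Sum of non-missing linear intensities over the four solubility fractions;
    a replicate with all four fractions missing stays missing.  Columns are a
    MultiIndex (condition, replicate).
    """
    qdsp = _qdsp_samples(table)
    groups = {}
    for (cond, rep), sub in qdsp.groupby(["condition", "replicate"], observed=True):
        vals = table.values[sub.index]
        total = vals.sum(axis=1, min_count=1)
        groups[(cond, rep)] = total
    out = pd.DataFrame(groups)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "replicate"])
    return out.sort_index(axis=1)


def differential_total(
    totals: pd.DataFrame,
    group_a: str = "BLEO",
    group_b: str = "PBS",
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample two-sided t-test on log2 totals between two condition groups.

    Returns per protein: ``log2fc`` (mean log2 A - mean log2 B), ``t``, ``p``,
    and BH ``q`` across tested proteins.  Proteins with fewer than 2 valid
    values in either group are reported untested (NaN).
    """
    import warnings as _warnings

    la = np.log2(totals[group_a]).to_numpy()
    lb = np.log2(totals[group_b]).to_numpy()
    t, p = ttest_matrix(la, lb, welch=welch)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        log2fc = np.nanmean(la, axis=1) - np.nanmean(lb, axis=1)
    res = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p}, index=totals.index
    )
    res["q"] = bh_fdr(res["p"])
    return res


def normalize_profiles(
    table: IntensityTable, per_replicate: bool = False
) -> pd.DataFrame:
    """Per-condition mean-centering of log2 QDSP profiles.

    For each protein and condition, the mean of all non-missing log2 cells
    (fractions x replicates jointly) is subtracted, so both conditions' mean
    log2 intensities are zero and abundance differences cancel before
    interaction testing.  ``per_replicate=True`` centers each replicate's
    four-fraction profile instead.
    """
    qdsp = _qdsp_samples(table)
    log2 = np.log2(table.values[qdsp.index])
    out = log2.copy()
    if per_replicate:
        for (_, _), sub in qdsp.groupby(["condition", "replicate"], observed=True):
            cols = sub.index
            out[cols] = log2[cols].sub(log2[cols].mean(axis=1), axis=0)
    else:
        for cond in qdsp["condition"].unique():
            cols = qdsp.index[qdsp["condition"] == cond]
            out[cols] = log2[cols].sub(log2[cols].mean(axis=1), axis=0)
    return out


def interaction_anova(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Two-way treatment x fraction interaction ANOVA per protein.

    Input is the mean-centered log2 matrix from :func:`normalize_profiles`
    restricted to QDSP samples.  Proteins with an empty treatment x fraction
    cell are untested (NaN).  Returns ``F``, ``p``, and BH ``q``.
    """
    meta = samples.loc[normalized.columns]
    F, p = interaction_anova_matrix(
        normalized.to_numpy(dtype=float),
        meta["condition"].to_numpy(),
        meta["fraction"].to_numpy(),
    )
    res = pd.DataFrame({"F": F, "p": p}, index=normalized.index)
    res["q"] = bh_fdr(res["p"])
    n_untested = int(res["p"].isna().sum())
    if n_untested:
        logger.info("interaction ANOVA: %d protein(s) untested (incomplete design cells)", n_untested)
    return res


def insoluble_share(table: IntensityTable, condition: str) -> pd.Series:
    """Share of linear MS intensity in the most insoluble fraction, per protein.

    Pooled over replicates: sum of INSOL intensities / sum over all four
    fractions; missing cells contribute zero mass.  All-missing proteins are
    missing (denominator zero).
    """
    qdsp = _qdsp_samples(table)
    cond = qdsp[qdsp["condition"] == condition]
    if cond.empty:
        raise ValueError(f"no QDSP samples for condition {condition!r}")
    vals = table.values[cond.index]
    denom = vals.sum(axis=1, min_count=1)
    insol_cols = cond.index[cond["fraction"] == "INSOL"]
    numer = vals[insol_cols].sum(axis=1, min_count=0)
    return (numer / denom).rename(f"insoluble_share_{condition}")


def abundance_rank(totals: pd.DataFrame) -> pd.Series:
    """Rank of each protein's mean log2 total intensity (1 = most abundant)."""
    mean_log2 = np.log2(totals).mean(axis=1, skipna=True)
    tested = mean_log2.dropna()
    ranks = tested.rank(ascending=False, method="first").astype(int)
    return ranks.reindex(mean_log2.index).rename("abundance_rank")


def pca_fractions(matrix: pd.DataFrame, n_components: int = 2) -> dict:
    """PCA of a complete samples x proteins matrix (z-scored upstream).

    Returns sample ``scores``, orthonormal protein ``loadings``, and the
    fraction of ``variance_explained`` per component (decreasing).  The sign
    convention makes each loading vector's largest-magnitude element positive.
    Missing values are a hard error: impute or filter upstream.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values; filter or impute upstream")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| loading element positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = svals**2 / max(X.shape[0] - 1, 1)
    explained = var / var.sum()
    scores = pd.DataFrame(
        U[:, :n_components] * svals[:n_components],
        index=matrix.index,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T,
        index=matrix.columns,
        columns=scores.columns,
    )
    return {
        "scores": scores,
        "loadings": loadings,
        "variance_explained": explained[:n_components],
    }


def cluster_profiles(
    matrix: pd.DataFrame,
    linkage: str = "average",
    distance: str = "correlation",
    n_clusters: int | None = None,
) -> dict:
    """Agglomerative clustering of z-scored rows.

    Default distance is 1 - Pearson r; constant rows make the correlation
    undefined and are a hard error.  Returns the scipy linkage matrix and,
    when ``n_clusters`` is given, flat cluster labels.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if np.isnan(X).any():
        raise ValueError("clustering input contains missing values")
    if distance == "correlation" and (X.std(axis=1) == 0).any():
        raise ValueError("constant row: correlation distance undefined")
    d = pdist(X, metric=distance)
    Z = hierarchy.linkage(d, method=linkage)
    out = {"linkage": Z, "index": matrix.index}
    if n_clusters is not None:
        out["clusters"] = pd.Series(
            hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust"),
            index=matrix.index,
            name="cluster",
        )
    return out


@dataclass
class QdspConfig:
    """Tunables for the QDSP differential pipeline."""

    fdr: float = 0.05
    welch: bool = False
    per_replicate_centering: bool = False
    #: protein enters profile testing when, per condition, at least this many
    #: biological replicates carry >= 1 fraction value
    min_valid_fraction_samples: int = 3


def run_qdsp(table: IntensityTable, config: QdspConfig | None = None) -> dict:
    """Full QDSP differential analysis.

    Returns a dict with ``stats`` (per-protein table: interaction F/p/q, total
    t-test log2fc/p/q, insoluble shares and their difference, abundance rank),
    ``normalized`` (centered log2 profiles of tested proteins), and ``totals``.
    """
    config = config or QdspConfig()
    qdsp = _qdsp_samples(table)
    totals = total_abundance(table)
    diff = differential_total(totals, welch=config.welch)

    # inclusion filter for profile-level testing
    keep = pd.Series(True, index=table.values.index)
    for cond in CONDITIONS:
        if cond in totals.columns.get_level_values(0):
            n_valid = totals[cond].notna().sum(axis=1)
            keep &= n_valid >= config.min_valid_fraction_samples
    normalized = normalize_profiles(table, per_replicate=config.per_replicate_centering).loc[keep]
    inter = interaction_anova(normalized, table.samples)

    share_pbs = insoluble_share(table, "PBS")
    share_bleo = insoluble_share(table, "BLEO")
    stats_df = pd.DataFrame(index=table.values.index)
    stats_df["interaction_F"] = inter["F"].reindex(stats_df.index)
    stats_df["interaction_p"] = inter["p"].reindex(stats_df.index)
    stats_df["interaction_q"] = inter["q"].reindex(stats_df.index)
    stats_df["total_log2fc"] = diff["log2fc"]
    stats_df["total_t_p"] = diff["p"]
    stats_df["total_t_q"] = diff["q"]
    stats_df["insoluble_share_PBS"] = share_pbs
    stats_df["insoluble_share_BLEO"] = share_bleo
    stats_df["delta_insoluble_share"] = share_bleo - share_pbs
    stats_df["abundance_rank"] = abundance_rank(totals)
    return {"stats": stats_df, "normalized": normalized, "totals": totals, "n_qdsp_samples": len(qdsp)}
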