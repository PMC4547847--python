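"""Ratiometric time-course analysis with left-censored imputation.

Label-free intensities are missing not at random: weak signals fall below the
detection limit, so missingness concentrates at the low end of the intensity
scale.  Ratios of treated replicates over the pooled control median are
therefore computed under explicit validity rules, and values missing on one
side are imputed from a normal distribution downshifted into the left tail of
the observed intensity distribution (default: mean - 1.8 sd, width 0.3 sd) —
only when the opposite side is well measured (>= 50% valid), so that imputed
ratios always contrast a real measurement with the detection floor.

Downstream, a one-way fixed-effects ANOVA across time points flags proteins
whose log2 ratio changes over the injury-repair timeline, and a per-protein
ordinary least squares fit against each mouse's lung-compliance ratio links
protein abundance to the physiological degree of fibrosis (compliance drops as
fibrotic tissue stiffens, so fibrosis-associated proteins have negative
slopes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._groupstats import oneway_anova_matrix, pearson_ols_matrix
from .enrichment import bh_fdr
from .io import IntensityTable

logger = logging.getLogger(__name__)

MEASURED = "MEASURED"
IMPUTED_NUM = "IMPUTED_NUM"
IMPUTED_DEN = "IMPUTED_DEN"
MISSING_RULE = "MISSING_RULE"


@dataclass
class ImputationParams:
    """Downshifted-normal imputation parameters (sigma units of the reference)."""

    downshift: float = 1.8
    width: float = 0.3
    seed: int = 0
    reference: str = "GLOBAL"  # or PER_SAMPLE

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be positive")
        if self.downshift < 0:
            raise ValueError("downshift must be non-negative")
        if self.reference not in ("GLOBAL", "PER_SAMPLE"):
            raise ValueError("reference must be GLOBAL or PER_SAMPLE")


@dataclass
class RatioMatrix:
    """Per-protein log2 treated/control ratios with per-cell provenance.

    ``ratios`` columns are a MultiIndex (timepoint_days, sample_id);
    ``provenance`` is the same shape with MEASURED / IMPUTED_NUM / IMPUTED_DEN /
    MISSING_RULE labels; ``denominator`` is the per-protein log2 control value.
    """

    ratios: pd.DataFrame
    provenance: pd.DataFrame
    denominator: pd.Series
    meta: dict = field(default_factory=dict)


def impute_missing(
    values: pd.DataFrame,
    params: ImputationParams,
    reference_distribution: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing cells by draws from a downshifted normal.

    Each missing cell is replaced by an independent draw from
    Normal(mu - downshift*sigma, (width*sigma)^2) where mu, sigma are the mean
    and sd of the reference distribution (all non-missing log2 values of
    ``values`` by default, per column with ``reference="PER_SAMPLE"``).  Draws
    are filled in row-major order (protein order, then column order), so a
    fixed seed gives identical output.  Returns (completed, imputed_mask).
    """
    arr = values.to_numpy(dtype=float).copy()
    mask = np.isnan(arr)
    rng = np.random.default_rng(params.seed)
    if params.reference == "PER_SAMPLE" and reference_distribution is None:
        for j in range(arr.shape[1]):
            col = arr[:, j]
            ref = col[~np.isnan(col)]
            _check_reference(ref)
            mu, sigma = ref.mean(), ref.std(ddof=1)
            idx = np.flatnonzero(np.isnan(col))
            col[idx] = rng.normal(mu - params.downshift * sigma, params.width * sigma, idx.size)
    else:
        if reference_distribution is None:
            reference_distribution = arr[~mask]
        ref = np.asarray(reference_distribution, dtype=float)
        ref = ref[~np.isnan(ref)]
        _check_reference(ref)
        mu, sigma = ref.mean(), ref.std(ddof=1)
        arr[mask] = rng.normal(
            mu - params.downshift * sigma, params.width * sigma, int(mask.sum())
        )
    completed = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return completed, pd.DataFrame(mask, index=values.index, columns=values.columns)


def _check_reference(ref: np.ndarray) -> None:
    if ref.size < 30:
        raise ValueError("reference distribution needs >= 30 values")
    if not ref.std(ddof=1) > 0:
        raise ValueError("degenerate reference distribution (zero spread)")


def compute_ratios(
    table: IntensityTable,
    params: ImputationParams | None = None,
    denominator: str = "median",
    compartment: str | None = None,
    min_valid_fraction: float = 0.5,
) -> RatioMatrix:
    """Log2 ratios of each treated replicate over the pooled control value.

    The denominator is the median (default) or mean of each protein's valid
    log2 control (PBS) intensities pooled over all control samples.  Per
    treated time-point group:

    * a valid treated replicate yields a MEASURED ratio;
    * an entirely missing treated group is imputed cell-wise (IMPUTED_NUM)
      when the control side has >= ``min_valid_fraction`` valid values;
    * an entirely missing control side is imputed once per protein
      (IMPUTED_DEN) when the treated group has >= ``min_valid_fraction`` valid
      values;
    * anything else is MISSING_RULE and stays missing.

    Imputation draws come from the downshifted normal of
    :class:`ImputationParams` against the distribution of all per-group log2
    medians (denominator draws first, then numerators, each in row-major
    protein x time-point x replicate order).
    """
    params = params or ImputationParams()
    samples = table.samples
    if compartment is not None:
        samples = samples[samples["compartment"] == compartment]
    pbs_ids = samples.index[samples["condition"] == "PBS"]
    if pbs_ids.empty:
        raise ValueError("no PBS control samples")
    treated = samples[samples["condition"] == "BLEO"].copy()
    if treated.empty:
        raise ValueError("no treated samples")
    treated = treated.sort_values(["timepoint_days", "replicate"])

    log2 = np.log2(table.values)
    pbs_linear = table.values[pbs_ids].to_numpy(dtype=float)
    n_pbs = pbs_linear.shape[1]
    pbs_valid = (~np.isnan(pbs_linear)).sum(axis=1)
    if denominator not in ("median", "mean"):
        raise ValueError("denominator must be 'median' or 'mean'")
    # median pools on the linear intensity scale (the conventional control
    # median); mean pools geometrically (mean of log2) so that a null
    # contrast stays centered on ratio 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if denominator == "median":
            with np.errstate(invalid="ignore"):
                den = np.log2(np.nanmedian(pbs_linear, axis=1))
        else:
            den = np.nanmean(log2[pbs_ids].to_numpy(), axis=1)

    timepoints = sorted(treated["timepoint_days"].dropna().unique())
    group_cols = {tp: treated.index[treated["timepoint_days"] == tp] for tp in timepoints}
    col_index = pd.MultiIndex.from_tuples(
        [(tp, sid) for tp in timepoints for sid in group_cols[tp]],
        names=["timepoint_days", "sample_id"],
    )
    num = log2[[sid for _, sid in col_index]].to_numpy()
    P, C = num.shape

    def _reference_loc_scale():
        # reference distribution: all per-(protein, group) log2 medians
        medians = [den]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for tp in timepoints:
                sub = log2[group_cols[tp]].to_numpy()
                medians.append(np.nanmedian(sub, axis=1))
        ref = np.concatenate(medians)
        ref = ref[~np.isnan(ref)]
        _check_reference(ref)
        mu, sigma = ref.mean(), ref.std(ddof=1)
        return mu - params.downshift * sigma, params.width * sigma, mu, sigma

    rng = np.random.default_rng(params.seed)

    group_slices = {}
    start = 0
    for tp in timepoints:
        width = len(group_cols[tp])
        group_slices[tp] = slice(start, start + width)
        start += width

    num_valid_count = {tp: (~np.isnan(num[:, group_slices[tp]])).sum(axis=1) for tp in timepoints}
    group_n = {tp: len(group_cols[tp]) for tp in timepoints}

    prov = np.full((P, C), MISSING_RULE, dtype=object)

    # denominator imputation: control all-missing, some treated group >= 50% valid
    den_missing = np.isnan(den)
    treated_ok = np.zeros(P, dtype=bool)
    for tp in timepoints:
        treated_ok |= num_valid_count[tp] >= min_valid_fraction * group_n[tp]
    impute_den = den_missing & treated_ok

    # numerator imputation: treated group all-missing, control >= 50% valid
    num = num.copy()
    impute_num = np.zeros((P, C), dtype=bool)
    control_ok = pbs_valid >= min_valid_fraction * n_pbs
    for tp in timepoints:
        sl = group_slices[tp]
        rows = (num_valid_count[tp] == 0) & control_ok & ~den_missing
        impute_num[rows, sl] = True

    mu = sigma = np.nan
    den = den.copy()
    if impute_den.any() or impute_num.any():
        loc, scale, mu, sigma = _reference_loc_scale()
        den[impute_den] = rng.normal(loc, scale, int(impute_den.sum()))
        num[impute_num] = rng.normal(loc, scale, int(impute_num.sum()))

    den_ok = ~np.isnan(den)
    measured = ~np.isnan(log2[[sid for _, sid in col_index]].to_numpy())
    prov[measured & den_ok[:, None] & ~impute_den[:, None]] = MEASURED
    prov[measured & impute_den[:, None]] = IMPUTED_DEN
    prov[impute_num] = IMPUTED_NUM

    ratios = np.where(prov != MISSING_RULE, num - den[:, None], np.nan)
    ratios_df = pd.DataFrame(ratios, index=table.values.index, columns=col_index)
    prov_df = pd.DataFrame(prov, index=table.values.index, columns=col_index)
    den_s = pd.Series(den, index=table.values.index, name="log2_denominator")
    den_s[~den_ok] = np.nan
    meta = {
        "denominator": denominator,
        "n_controls": n_pbs,
        "n_imputed_num": int(impute_num.sum()),
        "n_imputed_den": int(impute_den.sum()),
        "reference_mu": float(mu),
        "reference_sigma": float(sigma),
    }
    return RatioMatrix(ratios_df, prov_df, den_s, meta)


def anova_timecourse(ratio_matrix: RatioMatrix) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of log2 ratios across time-point groups.

    Proteins need >= 2 time points with >= 2 valid ratios each; others are
    untested (NaN).  Returns ``F``, ``p``, BH ``q``.
    """
    ratios = ratio_matrix.ratios
    groups = ratios.columns.get_level_values("timepoint_days").to_numpy()
    F, p = oneway_anova_matrix(ratios.to_numpy(dtype=float), groups)
    res = pd.DataFrame({"F": F, "p": p}, index=ratios.index)
    res["q"] = bh_fdr(res["p"])
    return res


def compliance_regression(
    ratio_matrix: RatioMatrix,
    compliance: pd.Series,
    pbs_compliance: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-protein OLS of log2 ratio on each mouse's compliance ratio.

    ``compliance`` is indexed by sample_id of the treated replicates (raw
    instrument units); when ``pbs_compliance`` is given, each value is divided
    by the median control compliance to form the compliance ratio.  Returns
    slope, intercept, Pearson r, two-sided t-based p on n-2 df, and BH q;
    proteins with < 3 paired values or zero variance are untested.
    """
    sample_ids = ratio_matrix.ratios.columns.get_level_values("sample_id")
    x = compliance.reindex(sample_ids).to_numpy(dtype=float)
    if pbs_compliance is not None:
        x = x / float(np.median(np.asarray(pbs_compliance, dtype=float)))
    res = pearson_ols_matrix(ratio_matrix.ratios.to_numpy(dtype=float), x)
    out = pd.DataFrame(
        {
            "slope": res["slope"],
            "intercept": res["intercept"],
            "pearson_r": res["r"],
            "p": res["p"],
            "n": res["n"].astype(int),
        },
        index=ratio_matrix.ratios.index,
    )
    out["q"] = bh_fdr(out["p"])
    return out
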