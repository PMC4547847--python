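"""Vectorized, missing-value-aware group statistics on proteins x samples matrices.

These are the fixed-effects building blocks behind the differential tests:
pooled/Welch two-sample t, one-way ANOVA, and the two-way treatment x fraction
interaction ANOVA (Type-II sums of squares: interaction SS = RSS(additive) -
RSS(cell means)).  All functions take a 2-D float array with NaN as missing and
return per-row statistics; rows whose design collapses (empty cells, too few
residual degrees of freedom) come back NaN and are reported untested upstream.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _group_sums(x: np.ndarray, group_cols: list[np.ndarray]):
    """Per-row n, sum, sum-of-squares for each column group (NaN-aware)."""
    n = np.empty((x.shape[0], len(group_cols)))
    s = np.empty_like(n)
    ss = np.empty_like(n)
    for j, cols in enumerate(group_cols):
        sub = x[:, cols]
        valid = ~np.isnan(sub)
        n[:, j] = valid.sum(axis=1)
        s[:, j] = np.nansum(sub, axis=1)
        ss[:, j] = np.nansum(sub * sub, axis=1)
    return n, s, ss


def ttest_matrix(
    x1: np.ndarray, x2: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample two-sided t-test; returns (t, p).

    Student (pooled variance) by default, Welch optionally.  Rows with fewer
    than 2 valid values in either group are NaN.  Degenerate rows (zero
    variance in both groups): p = 1 when the means agree, p = 0 otherwise.
    """
    n1 = (~np.isnan(x1)).sum(axis=1).astype(float)
    n2 = (~np.isnan(x2)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nansum(x1, axis=1) / n1
        m2 = np.nansum(x2, axis=1) / n2
        ss1 = np.nansum(x1 * x1, axis=1) - n1 * m1 * m1
        ss2 = np.nansum(x2 * x2, axis=1) - n2 * m2 * m2
        ss1 = np.maximum(ss1, 0.0)
        ss2 = np.maximum(ss2, 0.0)
        if welch:
            v1 = ss1 / (n1 - 1) / n1
            v2 = ss2 / (n2 - 1) / n2
            se = np.sqrt(v1 + v2)
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            sp2 = (ss1 + ss2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    untested = (n1 < 2) | (n2 < 2)
    degenerate = ~untested & (se == 0)
    p[degenerate] = np.where(m1[degenerate] == m2[degenerate], 1.0, 0.0)
    t[degenerate & (m1 == m2)] = 0.0
    t[untested] = np.nan
    p[untested] = np.nan
    return t, p


def oneway_anova_matrix(
    x: np.ndarray, groups: np.ndarray, min_groups: int = 2, min_per_group: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way fixed-effects ANOVA across column groups; returns (F, p).

    A row is tested when >= ``min_groups`` groups each hold >= ``min_per_group``
    valid values (groups below the floor are dropped for that row).  Zero
    residual variance: p = 0 if there is any between-group signal, else p = 1.
    """
    labels = np.unique(groups)
    group_cols = [np.flatnonzero(groups == g) for g in labels]
    n, s, ss = _group_sums(x, group_cols)
    use = n >= min_per_group
    k = use.sum(axis=1).astype(float)
    n_u = np.where(use, n, 0.0)
    s_u = np.where(use, s, 0.0)
    ss_u = np.where(use, ss, 0.0)
    n_tot = n_u.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        within = (ss_u - np.where(use, s_u * s_u / np.where(n_u > 0, n_u, 1), 0.0)).sum(axis=1)
        grand = s_u.sum(axis=1)
        between = np.where(use, s_u * s_u / np.where(n_u > 0, n_u, 1), 0.0).sum(axis=1) - (
            grand * grand / n_tot
        )
        within = np.maximum(within, 0.0)
        between = np.maximum(between, 0.0)
        df_b = k - 1
        df_w = n_tot - k
        f = (between / df_b) / (within / df_w)
        p = stats.f.sf(f, df_b, df_w)
    untested = (k < min_groups) | (df_w < 1)
    degenerate = ~untested & (within == 0)
    rel = np.zeros_like(between)
    scale = np.where(n_tot > 0, ss_u.sum(axis=1), 1.0)
    rel[degenerate] = between[degenerate] / np.maximum(scale[degenerate], 1e-300)
    p[degenerate] = np.where(between[degenerate] > 1e-12 * np.maximum(scale[degenerate], 1e-300), 0.0, 1.0)
    f[degenerate] = np.inf
    f[degenerate & (p == 1.0)] = 0.0
    f[untested] = np.nan
    p[untested] = np.nan
    return f, p


def _additive_design(treatment: np.ndarray, fraction: np.ndarray) -> np.ndarray:
    """Intercept + treatment and fraction dummies (reference-coded)."""
    t_levels = np.unique(treatment)
    f_levels = np.unique(fraction)
    cols = [np.ones(treatment.size)]
    for lv in t_levels[1:]:
        cols.append((treatment == lv).astype(float))
    for lv in f_levels[1:]:
        cols.append((fraction == lv).astype(float))
    return np.column_stack(cols)


def interaction_anova_matrix(
    x: np.ndarray, treatment: np.ndarray, fraction: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-way treatment x fraction interaction ANOVA; returns (F, p).

    The interaction sum of squares is Type-II: RSS of the additive model minus
    RSS of the full cell-means model, on F((a-1)(b-1), N - ab).  Rows with an
    empty treatment x fraction cell or no residual degrees of freedom are NaN
    (untested).  Zero residual variance: p = 0 if the interaction SS is
    positive, else p = 1.
    """
    treatment = np.asarray(treatment)
    fraction = np.asarray(fraction)
    t_levels = np.unique(treatment)
    f_levels = np.unique(fraction)
    a, b = t_levels.size, f_levels.size
    n_cells = a * b
    cell_id = np.searchsorted(t_levels, treatment) * b + np.searchsorted(f_levels, fraction)
    cell_cols = [np.flatnonzero(cell_id == c) for c in range(n_cells)]
    df_int = (a - 1) * (b - 1)

    p_rows, n_samp = x.shape
    F = np.full(p_rows, np.nan)
    P = np.full(p_rows, np.nan)

    complete = ~np.isnan(x).any(axis=1)
    if complete.any():
        xc = x[complete]
        n, s, ss = _group_sums(xc, cell_cols)
        rss_full = (ss - s * s / n).sum(axis=1)
        rss_full = np.maximum(rss_full, 0.0)
        X = _additive_design(treatment, fraction)
        # residual-maker of the additive model
        Q, _ = np.linalg.qr(X)
        M = np.eye(n_samp) - Q @ Q.T
        rss_add = np.einsum("pn,nm,pm->p", xc, M, xc)
        rss_add = np.maximum(rss_add, rss_full)
        ss_int = rss_add - rss_full
        df_resid = n_samp - n_cells
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ss_int / df_int) / (rss_full / df_resid)
            p = stats.f.sf(f, df_int, df_resid)
        scale = np.maximum((xc * xc).sum(axis=1), 1e-300)
        degenerate = rss_full == 0
        p[degenerate] = np.where(ss_int[degenerate] > 1e-12 * scale[degenerate], 0.0, 1.0)
        f[degenerate] = np.where(p[degenerate] == 0.0, np.inf, 0.0)
        if df_resid < 1:
            f[:] = np.nan
            p[:] = np.nan
        F[complete] = f
        P[complete] = p

    for i in np.flatnonzero(~complete):
        valid = ~np.isnan(x[i])
        counts = np.bincount(cell_id[valid], minlength=n_cells)
        if (counts == 0).any():
            continue  # empty design cell -> untested
        n_valid = int(valid.sum())
        df_resid = n_valid - n_cells
        if df_resid < 1:
            continue
        y = x[i, valid]
        means = np.bincount(cell_id[valid], weights=y, minlength=n_cells) / counts
        rss_full = float(np.sum((y - means[cell_id[valid]]) ** 2))
        Xi = _additive_design(treatment[valid], fraction[valid])
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        rss_add = float(np.sum((y - Xi @ beta) ** 2))
        ss_int = max(rss_add - rss_full, 0.0)
        if rss_full == 0:
            scale = max(float(y @ y), 1e-300)
            P[i] = 0.0 if ss_int > 1e-12 * scale else 1.0
            F[i] = np.inf if P[i] == 0.0 else 0.0
            continue
        F[i] = (ss_int / df_int) / (rss_full / df_resid)
        P[i] = float(stats.f.sf(F[i], df_int, df_resid))
    return F, P


def pearson_ols_matrix(
    y: np.ndarray, x: np.ndarray
) -> dict[str, np.ndarray]:
    """Row-wise OLS of y on a shared regressor x with Pearson r and its t-test p.

    ``y`` is rows x observations with NaN allowed; ``x`` is the observation
    vector.  Rows need >= 3 paired values and nonzero variance in both
    variables; others come back NaN.
    """
    valid = ~np.isnan(y) & ~np.isnan(x)[None, :]
    n = valid.sum(axis=1).astype(float)
    xm = np.where(valid, x[None, :], 0.0)
    ym = np.where(valid, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xm.sum(axis=1) / n
        my = ym.sum(axis=1) / n
        sxx = (xm * xm).sum(axis=1) - n * mx * mx
        syy = (ym * ym).sum(axis=1) - n * my * my
        sxy = (xm * ym).sum(axis=1) - n * mx * my
        slope = sxy / sxx
        intercept = my - slope * mx
        r = sxy / np.sqrt(sxx * syy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(r), 1.0) & (n >= 3)] = 0.0
    bad = (n < 3) | ~(sxx > 0) | ~(syy > 0)
    for arr in (slope, intercept, r, p):
        arr[bad] = np.nan
    return {"slope": slope, "intercept": intercept, "r": r, "p": p, "n": n}
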