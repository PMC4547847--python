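"""Shared statistical machinery: BH FDR, Fisher term enrichment, and 1D/2D
rank-based annotation enrichment.

The 1D annotation-enrichment score is the rank-biserial correlation
``2*U/(n_in*n_out) - 1`` of the Mann-Whitney U statistic of term members versus
non-members, a bounded [-1, 1] effect size; positive scores mean the term's
members carry systematically larger values.  The 2D variant scores a term on
two data dimensions (e.g. proteome vs transcriptome fold changes) and assigns
joint significance by membership permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationCollection

DEFAULT_MIN_MEMBERS = 5


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; input order preserved, NaN passed through.

    q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values, capped at 1,
    where n counts the non-missing tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    out[valid] = q
    return out


def fisher_enrichment(
    foreground: set, background: set, annotations: AnnotationCollection
) -> pd.DataFrame:
    """Two-sided Fisher's exact test of each term in a foreground vs background.

    The 2x2 table per term is {fg&term, fg-term, (bg-fg)&term, (bg-fg)-term};
    the two-sided p sums all tables with hypergeometric probability <= observed.
    Terms with no background overlap are skipped.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    if len(background) < 2:
        raise ValueError("background must contain at least 2 ids")
    rest = background - foreground
    rows = []
    for term_id, rec in annotations:
        members = rec["members"] & background
        if not members:
            continue
        a = len(foreground & members)
        b = len(foreground) - a
        c = len(rest & members)
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term_id, a, b, c, d, odds, p))
    res = pd.DataFrame(
        rows, columns=["term_id", "fg_in", "fg_out", "bg_in", "bg_out", "odds_ratio", "p"]
    ).set_index("term_id")
    res["q"] = bh_fdr(res["p"])
    return res


def _rank_biserial(ranks: np.ndarray, member_mask: np.ndarray) -> tuple[float, float]:
    """(U, score) for members vs non-members from precomputed mid-ranks."""
    n_in = int(member_mask.sum())
    n_out = member_mask.size - n_in
    r1 = float(ranks[member_mask].sum())
    u = r1 - n_in * (n_in + 1) / 2.0
    # (2U - n_in*n_out) is exact in floating point (mid-ranks are half-integers),
    # making score(term) == -score(complement) hold exactly
    score = (2.0 * u - n_in * n_out) / (n_in * n_out)
    return u, score


def _mwu_p(x: np.ndarray, y: np.ndarray, exact_limit: int = 10_000) -> float:
    """Two-sided Mann-Whitney p: exact enumeration when small and tie-free,
    otherwise normal approximation with tie correction."""
    small = x.size * y.size <= exact_limit
    tied = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if small and not tied else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def enrichment_1d(
    values: pd.Series,
    annotations: AnnotationCollection,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> pd.DataFrame:
    """1D annotation enrichment of each term over a per-id score vector.

    Returns per term: n_members_tested, U, score in [-1, 1], p, BH q.
    """
    values = pd.Series(values, dtype=float).dropna()
    ids = values.index.to_numpy()
    vals = values.to_numpy()
    ranks = stats.rankdata(vals)  # mid-ranks for ties
    id_pos = {i: k for k, i in enumerate(ids)}
    rows = []
    for term_id, rec in annotations:
        pos = [id_pos[m] for m in rec["members"] if m in id_pos]
        n_in = len(pos)
        n_out = ids.size - n_in
        if n_in < min_members or n_out == 0:
            continue
        mask = np.zeros(ids.size, dtype=bool)
        mask[pos] = True
        u, score = _rank_biserial(ranks, mask)
        p = _mwu_p(vals[mask], vals[~mask])
        rows.append((term_id, n_in, score, u, p))
    res = pd.DataFrame(
        rows, columns=["term_id", "n_members_tested", "score", "U", "p"]
    ).set_index("term_id")
    res["q"] = bh_fdr(res["p"]) if len(res) else np.nan
    return res


def enrichment_2d(
    values_x: pd.Series,
    values_y: pd.Series,
    annotations: AnnotationCollection,
    min_members: int = DEFAULT_MIN_MEMBERS,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """2D annotation enrichment: rank-biserial score on each dimension plus a
    joint membership-permutation p-value of max(|score_x|, |score_y|)."""
    values_x = pd.Series(values_x, dtype=float)
    values_y = pd.Series(values_y, dtype=float)
    common = values_x.dropna().index.intersection(values_y.dropna().index)
    vx = values_x.loc[common].to_numpy()
    vy = values_y.loc[common].to_numpy()
    rx = stats.rankdata(vx)
    ry = stats.rankdata(vy)
    n = common.size
    id_pos = {i: k for k, i in enumerate(common)}
    rng = np.random.default_rng(seed)
    rows = []
    for term_id, rec in annotations:
        pos = np.array(sorted(id_pos[m] for m in rec["members"] if m in id_pos), dtype=int)
        n_in = pos.size
        n_out = n - n_in
        if n_in < min_members or n_out == 0:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[pos] = True
        _, sx = _rank_biserial(rx, mask)
        _, sy = _rank_biserial(ry, mask)
        obs = max(abs(sx), abs(sy))
        # permutation null: random member subsets of the same size (chunked to
        # bound memory at large id counts)
        denom = n_in * n_out
        base = n_in * (n_in + 1) / 2.0
        n_exceed = 0
        done = 0
        while done < n_permutations:
            chunk = min(1000, n_permutations - done)
            perm_idx = np.argpartition(rng.random((chunk, n)), n_in - 1, axis=1)[:, :n_in]
            sx_null = (2.0 * (rx[perm_idx].sum(axis=1) - base) - denom) / denom
            sy_null = (2.0 * (ry[perm_idx].sum(axis=1) - base) - denom) / denom
            null = np.maximum(np.abs(sx_null), np.abs(sy_null))
            n_exceed += int(np.sum(null >= obs - 1e-12))
            done += chunk
        p = (1.0 + n_exceed) / (n_permutations + 1.0)
        rows.append((term_id, n_in, sx, sy, p))
    res = pd.DataFrame(
        rows, columns=["term_id", "n_members_tested", "score_x", "score_y", "p"]
    ).set_index("term_id")
    res["q"] = bh_fdr(res["p"]) if len(res) else np.nan
    return res


def signature_timecourse(
    ratios: pd.DataFrame,
    signatures: AnnotationCollection,
    alpha: float = 0.05,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> pd.DataFrame:
    """Cell-type signature enrichment per time point.

    ``ratios`` is a per-protein log2-ratio matrix with MultiIndex columns
    (timepoint_days, replicate) or plain per-time-point columns; replicates are
    collapsed to the median per time point, then each time point is scored by
    1D annotation enrichment.  Significance is flagged at ``alpha`` (the
    asterisk rule used for per-condition signature calls).
    """
    if isinstance(ratios.columns, pd.MultiIndex):
        summary = ratios.T.groupby(level=0).median().T
    else:
        summary = ratios
    records = []
    for tp in summary.columns:
        col = summary[tp].dropna()
        res = enrichment_1d(col, signatures, min_members=min_members)
        for term_id, row in res.iterrows():
            records.append(
                {
                    "term_id": term_id,
                    "timepoint_days": tp,
                    "n_members_tested": int(row["n_members_tested"]),
                    "score": row["score"],
                    "p": row["p"],
                    "significant": bool(row["p"] < alpha),
                }
            )
    return pd.DataFrame.from_records(records)
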