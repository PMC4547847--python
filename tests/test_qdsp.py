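"""QDSP statistics against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from qdsp_profiler import (
    GeneratorConfig,
    IntensityTable,
    cluster_profiles,
    differential_total,
    generate_qdsp_dataset,
    insoluble_share,
    interaction_anova,
    normalize_profiles,
    pca_fractions,
    total_abundance,
)
from qdsp_profiler._groupstats import interaction_anova_matrix, ttest_matrix
from qdsp_profiler.qdsp import abundance_rank


def make_table(values, conditions, fractions, replicates):
    """Tiny IntensityTable from an array and per-column design labels."""
    n_prot, n_samp = values.shape
    cols = [f"s{i}" for i in range(n_samp)]
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "timepoint_days": np.nan,
            "fraction": fractions,
            "replicate": replicates,
            "mouse_id": [f"{c}_m{r}" for c, r in zip(conditions, replicates)],
            "compartment": "TISSUE",
            "compliance": np.nan,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    idx = pd.Index([f"P{i}" for i in range(n_prot)], name="protein_id")
    proteins = pd.DataFrame({"gene_name": [f"G{i}" for i in range(n_prot)]}, index=idx)
    return IntensityTable(pd.DataFrame(values, index=idx, columns=cols), proteins, samples)


def full_qdsp_design(n_reps=2):
    conditions, fractions, replicates = [], [], []
    for cond in ("PBS", "BLEO"):
        for rep in range(1, n_reps + 1):
            for frac in ("FR1", "FR2", "FR3", "INSOL"):
                conditions.append(cond)
                fractions.append(frac)
                replicates.append(rep)
    return conditions, fractions, replicates


class TestTotalAbundance:
    def test_sums_fractions_and_ignores_missing(self):
        cond, frac, rep = full_qdsp_design(n_reps=1)
        vals = np.array([
            [1.0, 2.0, 3.0, 4.0, 1.0, 1.0, 1.0, 1.0],
            [5.0, np.nan, np.nan, 5.0, np.nan, np.nan, np.nan, np.nan],
        ])
        table = make_table(vals, cond, frac, rep)
        totals = total_abundance(table)
        assert totals.loc["P0", ("PBS", 1)] == 10.0
        assert totals.loc["P1", ("PBS", 1)] == 10.0  # missing ignored
        assert np.isnan(totals.loc["P1", ("BLEO", 1)])  # all-missing stays missing

    def test_incomplete_replicate_is_design_error(self):
        table = make_table(
            np.ones((2, 3)), ["PBS"] * 3, ["FR1", "FR2", "FR3"], [1, 1, 1]
        )
        with pytest.raises(ValueError, match="missing fraction"):
            total_abundance(table)


class TestDifferentialTotal:
    def test_identical_groups_give_p_one(self):
        x = np.array([[1.0, 2.0, 3.0]])
        t, p = ttest_matrix(x, x.copy())
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_pooled_t_oracle(self):
        a = np.array([[0.0, 0.0, 1.0, 1.0]])
        b = np.array([[2.0, 2.0, 3.0, 3.0]])
        t, p = ttest_matrix(a, b)
        ref = spstats.ttest_ind(a[0], b[0], equal_var=True)
        assert t[0] == pytest.approx(ref.statistic, abs=1e-10)
        assert p[0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_random_instances_match_scipy(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(2, 10, size=2)
            a = rng.normal(size=(1, n1))
            b = rng.normal(size=(1, n2))
            t, p = ttest_matrix(a, b)
            ref = spstats.ttest_ind(a[0], b[0], equal_var=True)
            assert t[0] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_zero_variance(self):
        t, p = ttest_matrix(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]))
        assert p[0] == 1.0
        t, p = ttest_matrix(np.array([[1.0, 1.0]]), np.array([[2.0, 2.0]]))
        assert p[0] == 0.0

    def test_untested_with_single_value(self):
        t, p = ttest_matrix(np.array([[1.0, np.nan]]), np.array([[1.0, 2.0]]))
        assert np.isnan(p[0])

    def test_welch_option(self, rng):
        a, b = rng.normal(size=(1, 5)), rng.normal(size=(1, 8))
        t, p = ttest_matrix(a, b, welch=True)
        ref = spstats.ttest_ind(a[0], b[0], equal_var=False)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)


class TestNormalizeProfiles:
    def test_hand_computed_centering(self):
        cond, frac, rep = full_qdsp_design(n_reps=1)
        vals = 2.0 ** np.array([[10.0, 12.0, 14.0, 16.0, 10.0, 12.0, 14.0, 16.0]])
        table = make_table(vals, cond, frac, rep)
        out = normalize_profiles(table)
        np.testing.assert_allclose(
            out.iloc[0, :4].to_numpy(), [-3.0, -1.0, 1.0, 3.0], atol=1e-12
        )

    def test_per_condition_mean_zero(self, small_qdsp):
        table, _ = small_qdsp
        out = normalize_profiles(table)
        sm = table.samples
        for cond in ("PBS", "BLEO"):
            cols = [c for c in out.columns if sm.loc[c, "condition"] == cond]
            means = out[cols].mean(axis=1).dropna()
            np.testing.assert_allclose(means.to_numpy(), 0.0, atol=1e-9)


def interaction_oracle_balanced(y, n_reps):
    """Classical balanced two-way ANOVA decomposition (2 conditions x 4 fractions).

    ``y`` has shape (2, 4, n_reps).
    """
    grand = y.mean()
    a_means = y.mean(axis=(1, 2))
    b_means = y.mean(axis=(0, 2))
    cell_means = y.mean(axis=2)
    ss_int = n_reps * np.sum(
        (cell_means - a_means[:, None] - b_means[None, :] + grand) ** 2
    )
    ss_within = np.sum((y - cell_means[:, :, None]) ** 2)
    df_int, df_within = 3, y.size - 8
    F = (ss_int / df_int) / (ss_within / df_within)
    return F, spstats.f.sf(F, df_int, df_within)


class TestInteractionAnova:
    def _design(self, n_reps):
        cond = ["PBS"] * (4 * n_reps) + ["BLEO"] * (4 * n_reps)
        frac = (["FR1", "FR2", "FR3", "INSOL"] * n_reps) * 2
        return np.array(cond), np.array(frac)

    def test_additive_data_have_zero_interaction(self):
        cond, frac = self._design(2)
        alpha = {"PBS": 0.0, "BLEO": 1.5}
        beta = {"FR1": 0.0, "FR2": 1.0, "FR3": 2.0, "INSOL": 3.0}
        y = np.array([[alpha[c] + beta[f] for c, f in zip(cond, frac)]])
        F, p = interaction_anova_matrix(y, cond, frac)
        assert p[0] == pytest.approx(1.0)

    def test_matches_brute_force_ss_oracle(self, rng):
        cond, frac = self._design(2)
        for _ in range(100):
            y3 = rng.normal(size=(2, 4, 2))
            flat = np.concatenate([y3[0].T.ravel(), y3[1].T.ravel()])
            # column order above is rep-major; rebuild to match design labels
            y = np.array(
                [[y3[0 if c == "PBS" else 1, ["FR1", "FR2", "FR3", "INSOL"].index(f), r - 1]
                  for c, f, r in zip(cond, frac, [1, 1, 1, 1, 2, 2, 2, 2] * 2)]]
            )
            F, p = interaction_anova_matrix(y, cond, frac)
            F_ref, p_ref = interaction_oracle_balanced(y3, 2)
            assert F[0] == pytest.approx(F_ref, rel=1e-10)
            assert p[0] == pytest.approx(p_ref, rel=1e-10)

    def test_unbalanced_matches_statsmodels_type2(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cond, frac = self._design(3)
        y = rng.normal(size=(1, cond.size))
        y[0, 5] = np.nan  # unbalance one cell
        F, p = interaction_anova_matrix(y, cond, frac)
        df = pd.DataFrame({"y": y[0], "t": cond, "f": frac}).dropna()
        fit = ols("y ~ C(t) * C(f)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert F[0] == pytest.approx(tab.loc["C(t):C(f)", "F"], rel=1e-8)
        assert p[0] == pytest.approx(tab.loc["C(t):C(f)", "PR(>F)"], rel=1e-8)

    def test_empty_cell_marks_untested(self):
        cond, frac = self._design(2)
        y = np.random.default_rng(0).normal(size=(1, cond.size))
        y[0, (cond == "BLEO") & (frac == "FR2")] = np.nan
        F, p = interaction_anova_matrix(y, cond, frac)
        assert np.isnan(p[0])

    def test_invariant_to_per_condition_constants(self, small_qdsp):
        """Adding any constant per condition leaves the interaction p unchanged
        once profiles are re-centered (abundance and profile are decoupled)."""
        table, _ = small_qdsp
        sub = table.values.iloc[:40]
        shifted = sub.copy()
        sm = table.samples
        for cond, factor in (("PBS", 2.0**1.7), ("BLEO", 2.0**-0.9)):
            cols = sm.index[sm["condition"] == cond]
            shifted[cols] = shifted[cols] * factor
        t1 = IntensityTable(sub, table.proteins.iloc[:40].copy(), table.samples.copy())
        t2 = IntensityTable(shifted, table.proteins.iloc[:40].copy(), table.samples.copy())
        p1 = interaction_anova(normalize_profiles(t1), t1.samples)["p"]
        p2 = interaction_anova(normalize_profiles(t2), t2.samples)["p"]
        pd.testing.assert_series_equal(p1, p2, atol=1e-9, rtol=0)


class TestInsolubleShare:
    def test_uniform_profile_gives_quarter(self):
        cond, frac, rep = full_qdsp_design(n_reps=1)
        table = make_table(np.ones((1, 8)), cond, frac, rep)
        assert insoluble_share(table, "PBS").iloc[0] == pytest.approx(0.25)

    def test_only_insoluble_detected_gives_one(self):
        cond, frac, rep = full_qdsp_design(n_reps=1)
        vals = np.full((1, 8), np.nan)
        vals[0, 3] = 5.0  # PBS INSOL
        table = make_table(vals, cond, frac, rep)
        assert insoluble_share(table, "PBS").iloc[0] == pytest.approx(1.0)
        assert np.isnan(insoluble_share(table, "BLEO").iloc[0])

    def test_pooled_over_replicates(self):
        cond, frac, rep = full_qdsp_design(n_reps=2)
        vals = np.array([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 5.0] + [np.nan] * 8])
        table = make_table(vals, cond, frac, rep)
        assert insoluble_share(table, "PBS").iloc[0] == pytest.approx(6.0 / 12.0)


class TestAbundanceRank:
    def test_rank_is_permutation(self, small_qdsp):
        table, _ = small_qdsp
        ranks = abundance_rank(total_abundance(table)).dropna()
        assert sorted(ranks) == list(range(1, len(ranks) + 1))


class TestPca:
    def test_duplicated_samples_have_identical_scores(self, rng):
        X = rng.normal(size=(6, 15))
        X = np.vstack([X, X[2]])
        res = pca_fractions(pd.DataFrame(X), n_components=2)
        np.testing.assert_allclose(
            res["scores"].iloc[2].to_numpy(), res["scores"].iloc[6].to_numpy(), atol=1e-8
        )

    def test_loadings_orthonormal(self, rng):
        res = pca_fractions(pd.DataFrame(rng.normal(size=(10, 30))), n_components=4)
        L = res["loadings"].to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-8)

    def test_variances_match_eigen_oracle(self, rng):
        X = rng.normal(size=(20, 8))
        res = pca_fractions(pd.DataFrame(X), n_components=8)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        total = eig.sum()
        np.testing.assert_allclose(res["variance_explained"], eig / total, atol=1e-8)

    def test_missing_values_hard_error(self):
        X = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            pca_fractions(X, 1)


def average_linkage_oracle(X):
    """Naive agglomeration: correlation distance, unweighted average linkage,
    lowest-index tie-break.  Returns the sequence of merged member-sets."""
    n = X.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    D = {}
    for i in range(n):
        for j in range(i + 1, n):
            r = np.corrcoef(X[i], X[j])[0, 1]
            D[(i, j)] = 1 - r
    merges = []
    active = sorted(clusters)
    while len(active) > 1:
        best, best_d = None, np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                d = np.mean(
                    [D[tuple(sorted((a, b)))] for a in clusters[i] for b in clusters[j]]
                )
                if d < best_d - 1e-12:
                    best_d, best = d, (i, j)
        i, j = best
        new = clusters[i] | clusters[j]
        merges.append((new, best_d))
        key = max(clusters) + 1
        clusters[key] = new
        active = [a for a in active if a not in (i, j)] + [key]
    return merges


class TestClusterProfiles:
    def test_identical_rows_merge_at_zero(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        res = cluster_profiles(X)
        assert res["linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_at_distance_two(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        res = cluster_profiles(pd.DataFrame([x, -x]))
        assert res["linkage"][0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_constant_row_hard_error(self):
        with pytest.raises(ValueError, match="constant"):
            cluster_profiles(pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))

    def test_merge_sequence_matches_brute_force(self, rng):
        X = rng.normal(size=(6, 10))
        res = cluster_profiles(pd.DataFrame(X))
        Z = res["linkage"]
        oracle = average_linkage_oracle(X)
        # rebuild member sets from the scipy linkage matrix
        members = {i: frozenset([i]) for i in range(6)}
        for step, (row, (oracle_set, oracle_d)) in enumerate(zip(Z, oracle)):
            a, b, d, _ = row
            new = members[int(a)] | members[int(b)]
            members[6 + step] = new
            assert new == oracle_set
            assert d == pytest.approx(oracle_d, rel=1e-10)


class TestParameterRecoverySmall:
    def test_detected_shifts_change_insoluble_share_in_true_direction(self):
        from qdsp_profiler import run_qdsp

        table, truth = generate_qdsp_dataset(GeneratorConfig(n_proteins=600, seed=14))
        stats = run_qdsp(table)["stats"]
        detected = stats["interaction_q"] < 0.05
        delta = stats["delta_insoluble_share"]
        toward = detected & (truth.proteins["shift_direction"] == "TOWARD_INSOLUBLE")
        away = detected & (truth.proteins["shift_direction"] == "TOWARD_SOLUBLE")
        assert toward.sum() >= 10 and away.sum() >= 10
        assert (delta[toward] > 0).mean() >= 0.95
        assert (delta[away] < 0).mean() >= 0.85  # small-n counterpart of the full-scale check
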