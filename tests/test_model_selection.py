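import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pyroseasons as ps


class TestPerVariableR2:
    def test_perfect_separation_gives_unit_r2(self):
        values = np.array([[0.0], [0.0], [1.0], [1.0]])
        labels = np.array([1, 1, 2, 2])
        r2, mean = ps.per_variable_r2(values, labels, ("x",))
        assert r2["x"] == pytest.approx(1.0)

    def test_hand_computed_anova(self):
        # SS_between = 4, SS_total = 5 -> R^2 = 0.8
        values = np.array([[1.0], [2.0], [3.0], [4.0]])
        labels = np.array([1, 1, 2, 2])
        r2, mean = ps.per_variable_r2(values, labels, ("x",))
        assert r2["x"] == pytest.approx(0.8)
        assert mean == pytest.approx(0.8)

    def test_random_labels_give_small_r2(self, rng):
        values = rng.normal(0, 1, (500, 1))
        labels = rng.integers(1, 4, 500)
        _, mean = ps.per_variable_r2(values, labels, ("x",))
        assert mean < 0.05

    def test_invariant_to_standardization(self, rng):
        values = rng.normal(5, 3, (100, 2))
        labels = rng.integers(1, 3, 100)
        std = (values - values.mean(0)) / values.std(0, ddof=1)
        a, _ = ps.per_variable_r2(values, labels, ("x", "y"))
        b, _ = ps.per_variable_r2(std, labels, ("x", "y"))
        for v in ("x", "y"):
            assert a[v] == pytest.approx(b[v], abs=1e-10)

    def test_unassigned_days_excluded(self):
        values = np.array([[1.0], [2.0], [3.0], [4.0], [99.0]])
        labels = np.array([1, 1, 2, 2, 0])
        r2, _ = ps.per_variable_r2(values, labels, ("x",))
        assert r2["x"] == pytest.approx(0.8)

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ValueError):
            ps.per_variable_r2(np.ones((4, 1)), np.array([1, 1, 1, 1]), ("x",))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_refining_a_cluster_never_lowers_r2(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        values = rng.normal(0, 1, (n, 2))
        labels = rng.integers(1, 4, n)
        # split cluster 1 into 1 and 4
        ones = np.flatnonzero(labels == 1)
        if ones.size < 2 or len(set(labels)) < 2:
            return
        refined = labels.copy()
        refined[ones[: ones.size // 2]] = 4
        if len(set(refined)) < 2:
            return
        before, _ = ps.per_variable_r2(values, labels, ("x", "y"))
        after, _ = ps.per_variable_r2(values, refined, ("x", "y"))
        for v in ("x", "y"):
            assert after[v] >= before[v] - 1e-12


class TestPillaiTrace:
    def test_scalar_case_equals_anova_r2(self, rng):
        values = rng.normal(0, 1, (30, 1))
        labels = rng.integers(1, 3, 30)
        r2, _ = ps.per_variable_r2(values, labels, ("x",))
        assert ps.pillai_trace(values, labels) == pytest.approx(r2["x"])

    def test_perfect_separation_approaches_bound(self, rng):
        centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        labels = np.repeat([1, 2, 3], 20)
        values = centers[labels - 1] + 1e-3 * rng.standard_normal((60, 2))
        V = ps.pillai_trace(values, labels)
        assert V == pytest.approx(2.0, abs=1e-3)

    def test_matches_manova_reference(self, rng):
        # statsmodels MANOVA as the independent linear-algebra oracle
        from statsmodels.multivariate.manova import MANOVA

        values = rng.normal(0, 1, (12, 2))
        values[4:8] += 2.0
        values[8:] -= 1.5
        labels = np.repeat([1, 2, 3], 4)
        got = ps.pillai_trace(values, labels)
        mv = MANOVA(values, np.column_stack([
            np.ones(12), labels == 2, labels == 3
        ]))
        tab = mv.mv_test([("g", np.array([[0, 1, 0], [0, 0, 1]]))])
        expected = tab.results["g"]["stat"].loc["Pillai's trace", "Value"]
        assert got == pytest.approx(float(expected), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, (50, 3))
        labels = rng.integers(1, 4, 50)
        V = ps.pillai_trace(values, labels)
        assert 0.0 <= V <= min(3, len(set(labels)) - 1) + 1e-12


class TestAICScore:
    def test_single_cluster_matches_closed_form(self, rng):
        values = rng.normal(0, 1, (100, 2))
        labels = np.ones(100, dtype=int)
        n, d = values.shape
        S = np.cov(values, rowvar=False, bias=True)
        logdet = np.linalg.slogdet(S)[1]
        p = d + d * (d + 1) // 2
        expected = n * (d * np.log(2 * np.pi) + logdet) + n * d + 2 * p
        assert ps.aic_score(values, labels) == pytest.approx(expected)

    def test_duplicating_observations_doubles_likelihood_term_only(self, rng):
        # same MLE fit, doubled log-likelihood, fixed penalty:
        # AIC(dup) = 2 * AIC(orig) - 2p exactly
        values = rng.normal(0, 1, (60, 2))
        labels = np.repeat([1, 2], 30)
        doubled = np.vstack([values, values])
        dlabels = np.concatenate([labels, labels])
        d, k = 2, 2
        p = k * (d + d * (d + 1) // 2)
        assert ps.aic_score(doubled, dlabels) == pytest.approx(
            2 * ps.aic_score(values, labels) - 2 * p
        )

    def test_true_partition_beats_single_cluster(self, rng):
        values = np.vstack([
            rng.normal(0, 1, (80, 2)), rng.normal((10, 10), 1, (80, 2))
        ])
        labels2 = np.repeat([1, 2], 80)
        labels1 = np.ones(160, dtype=int)
        assert ps.aic_score(values, labels2) < ps.aic_score(values, labels1)


class TestSweepAndCulling:
    def test_sweep_emits_one_row_per_radius(self, small_run):
        _, _, _, fm = small_run
        grid = np.geomspace(0.5, 2.5, 6)
        cs = ps.sweep_radius(fm, R_grid=grid, CK=30)
        assert len(cs.table()) == len(grid)

    def test_huge_radius_flagged_as_single_cluster(self, small_run):
        _, _, _, fm = small_run
        cs = ps.sweep_radius(fm, R_grid=[8.0], CK=30)
        assert cs.models[0][0].k == 1
        assert any("k=1" in line for line in cs.culling_log)

    def test_three_cluster_model_found_on_default_data(self, default_run):
        _, _, _, fm = default_run
        cs = ps.sweep_radius(fm, R_grid=np.geomspace(0.5, 0.8, 8), CK=50)
        assert any(m.k == 3 for m, s in ps.usable(cs))

    def test_fit_generally_improves_with_more_clusters(self, default_run):
        from scipy.stats import spearmanr

        _, _, _, fm = default_run
        cs = ps.sweep_radius(fm, R_grid=np.geomspace(0.45, 0.9, 10), CK=50)
        tab = cs.table().dropna()
        rho = spearmanr(tab["k"], tab["mean_r2"]).statistic
        assert rho > 0

    def test_cull_drops_thin_clusters(self, small_run):
        _, _, _, fm = small_run
        cs = ps.sweep_radius(fm, R_grid=np.geomspace(0.4, 1.2, 8), CK=10)
        culled = ps.cull_by_days_per_year(cs, min_days=10)
        for m, s in ps.usable(culled):
            assert all(d >= 10 for d in s.days_per_year.values())

    def test_observed_season_lengths_pass_the_cull(self):
        # clusters averaging {137, 137, 91} days/yr must be kept
        assert all(d >= 10 for d in (137, 137, 91))


class TestScreenVariableSubsets:
    def test_pure_noise_variable_is_flagged_as_wrench(self):
        # wind is aseasonal by construction in the generator; its
        # inclusion dilutes every cluster-number class
        cfg = ps.SynthConfig(seed=11, n_years=10)
        series, _ = ps.generate_weather(cfg)
        verdict = ps.screen_variable_subsets(
            series, ("rh", "temp", "solar", "wind", "soil"),
            CK=50, R_grid=np.geomspace(0.4, 1.2, 24),
        )
        assert verdict.loc["wind", "wrench"]
        assert not verdict.drop("wind")["wrench"].any()

    def test_equally_seasonal_variables_are_never_flagged(self):
        cfg = ps.SynthConfig(seed=12, n_years=6)
        series, _ = ps.generate_weather(cfg)
        verdict = ps.screen_variable_subsets(
            series, ("rh", "temp", "solar", "soil"), CK=50,
            R_grid=np.geomspace(0.4, 1.1, 12),
        )
        assert not verdict["wrench"].any()

    def test_counts_full_plus_leave_one_out_subsets(self):
        cfg = ps.SynthConfig(seed=12, n_years=4)
        series, _ = ps.generate_weather(cfg)
        verdict = ps.screen_variable_subsets(
            series, ("rh", "temp", "solar"), CK=30,
            R_grid=np.geomspace(0.6, 1.2, 3),
        )
        assert len(verdict.attrs["best_by_subset"]) == 4
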