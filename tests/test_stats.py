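"""Test battery: oracles for each statistic, sweep semantics, run extraction."""

import itertools

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings, strategies as st

from lcdmcensor import (
    CensoringGrid,
    GroupedDistances,
    TestSpec,
    anova_f,
    extract_runs,
    holm_adjust,
    kernel_density_export,
    kruskal_wallis,
    ks_two_sample,
    lilliefors,
    run_sweep,
    welch_t,
    wilcoxon_rank_sum,
)
from lcdmcensor.stats import SweepResult, default_specs


class TestKruskalWallis:
    def test_identical_groups_give_p_one(self):
        g = [1.0, 2.0, 3.0]
        assert kruskal_wallis([g, g, g]) == 1.0

    def test_empty_group_gives_na(self):
        assert np.isnan(kruskal_wallis([[1.0, 2.0], []]))

    def test_against_permutation_oracle(self, rng):
        """Chi-square p agrees with the sampled permutation distribution of H
        to within the approximation's small-sample bias."""
        groups = [[0.3, 1.1, 2.2, 2.9], [0.8, 1.9, 3.4, 4.0], [0.1, 0.5, 1.4, 2.6]]
        p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = ss.rankdata(pooled)
        n = len(pooled)

        def h_stat(r):
            parts = np.split(r, [4, 8])
            s = sum(len(p) * (p.mean() - (n + 1) / 2) ** 2 for p in parts)
            return 12 / (n * (n + 1)) * s

        h_obs = h_stat(ranks)
        perm = np.array([h_stat(rng.permutation(ranks)) for _ in range(20000)])
        p_perm = np.mean(perm >= h_obs - 1e-12)
        assert p_chi2 == pytest.approx(p_perm, abs=0.05)

    def test_two_group_case_equals_squared_wilcoxon_deviate(self, rng):
        """For two groups, H equals the square of the tie-corrected normal
        deviate of the rank sum test (with ties present)."""
        g1 = rng.integers(0, 8, size=30).astype(float)
        g2 = rng.integers(2, 10, size=25).astype(float)
        p_kw = kruskal_wallis([g1, g2])
        p_less = wilcoxon_rank_sum(g1, g2, "less")
        z = ss.norm.ppf(p_less)
        assert ss.chi2.sf(z**2, df=1) == pytest.approx(p_kw, abs=1e-10)


class TestAnovaF:
    def test_two_group_hov_equals_pooled_t_squared(self, rng):
        g1 = rng.normal(size=20)
        g2 = rng.normal(loc=0.5, size=25)
        p_f = anova_f([g1, g2], assume_hov=True)
        p_t = ss.ttest_ind(g1, g2, equal_var=True).pvalue
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_two_group_welch_equals_welch_t(self, rng):
        g1 = rng.normal(scale=1.0, size=18)
        g2 = rng.normal(loc=0.4, scale=2.5, size=30)
        p_f = anova_f([g1, g2], assume_hov=False)
        p_t = ss.ttest_ind(g1, g2, equal_var=False).pvalue
        assert p_f == pytest.approx(p_t, rel=1e-8)

    def test_degenerate_inputs_give_na(self):
        assert np.isnan(anova_f([[1.0], [2.0]], assume_hov=False))
        assert np.isnan(anova_f([[1.0, 1.0], [1.0, 1.0]], assume_hov=False))


class TestWilcoxon:
    def test_one_sided_pvalues_are_complementary(self, rng):
        g1 = rng.normal(size=120)
        g2 = rng.normal(loc=0.2, size=150)
        p_less = wilcoxon_rank_sum(g1, g2, "less")
        p_greater = wilcoxon_rank_sum(g1, g2, "greater")
        assert p_less + p_greater == pytest.approx(1.0, abs=1e-9)

    def test_extreme_separation(self, rng):
        g1 = rng.uniform(0, 1, size=100)
        g2 = rng.uniform(10, 11, size=100)
        assert wilcoxon_rank_sum(g1, g2, "less") < 1e-10

    def test_exact_small_sample_matches_enumeration(self):
        """3-vs-3 exact p equals enumeration over all 20 rank assignments."""
        g1 = [1.0, 4.0, 6.0]
        g2 = [2.0, 3.0, 5.0]
        ranks = ss.rankdata(g1 + g2)
        w_obs = ranks[:3].sum()
        ws = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
        p_enum_less = np.mean([w <= w_obs for w in ws])
        assert wilcoxon_rank_sum(g1, g2, "less", method="exact") == pytest.approx(
            p_enum_less)

    def test_empty_group_gives_na(self):
        assert np.isnan(wilcoxon_rank_sum([], [1.0], "less"))


class TestWelchT:
    def test_identical_samples_give_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert welch_t(g, g) == pytest.approx(1.0)

    def test_equal_variance_equal_n_matches_pooled_t(self, rng):
        g1 = rng.normal(size=30)
        g2 = g1 + 0.3  # identical sample variance, equal n -> same df
        p_welch = welch_t(g1, g2)
        p_pooled = ss.ttest_ind(g1, g2, equal_var=True).pvalue
        assert p_welch == pytest.approx(p_pooled, abs=1e-6)

    def test_hand_computed_example(self):
        g1 = np.array([2.1, 2.5, 2.9, 3.1, 3.6])
        g2 = np.array([3.0, 3.4, 3.9, 4.4, 4.9])
        m1, m2 = g1.mean(), g2.mean()
        v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
        se2 = v1 / 5 + v2 / 5
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / 5) ** 2 / 4 + (v2 / 5) ** 2 / 4)
        p_manual = 2 * ss.t.sf(abs(t), df)
        assert welch_t(g1, g2) == pytest.approx(p_manual, rel=1e-12)

    def test_insufficient_size_gives_na(self):
        assert np.isnan(welch_t([1.0], [2.0, 3.0]))


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        g = [1.0, 2.0, 3.0]
        assert ks_two_sample(g, g) == pytest.approx(1.0)

    def test_disjoint_supports(self, rng):
        g1 = rng.uniform(0, 1, size=50)
        g2 = rng.uniform(5, 6, size=50)
        assert ks_two_sample(g1, g2) < 1e-6

    def test_small_sample_matches_exact_enumeration(self):
        """2-vs-2 exact p from enumerating the 6 rank arrangements."""
        p = ks_two_sample([1.0, 2.0], [3.0, 4.0], method="exact")
        # D = 1 occurs for 2 of the C(4,2)=6 equally likely arrangements
        assert p == pytest.approx(2 / 6)


class TestLilliefors:
    def test_null_calibration_on_gaussian(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=5000)
            if lilliefors(x) > 0.05:
                hits += 1
        assert hits >= 16  # ~95% expected under the null

    def test_detects_bimodal_mixture(self, rng):
        x = np.concatenate([rng.normal(-3, 0.5, 2500), rng.normal(3, 0.5, 2500)])
        assert lilliefors(x) <= 0.001 + 1e-12

    def test_degenerate_inputs(self):
        assert np.isnan(lilliefors([1.0, 2.0, 3.0]))  # n < 4
        assert np.isnan(lilliefors([2.0] * 10))  # constant


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_down(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])

    def test_na_passthrough(self):
        out = holm_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.all(np.isfinite(out[[0, 2]]))

    def test_invalid_input_raises(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRunSweep:
    def test_last_step_equals_pooled_analysis_bit_identical(self, grouped_random):
        grid = CensoringGrid(delta=0.5, d_max=5.5)
        specs = default_specs(grouped_random.group_labels)
        sweep = run_sweep(grouped_random, grid, specs)
        groups = [grouped_random.groups[g] for g in grouped_random.group_labels]
        last = sweep.table[sweep.table["k"] == grid.n_steps]
        kw_row = last[last["test"] == "kruskal_wallis"]["p"].iloc[0]
        assert kw_row == kruskal_wallis(groups)
        a, b = grouped_random.group_labels[:2]
        wil = last[(last["test"] == "wilcoxon") & (last["pair"] == f"{a}:{b}")]
        assert wil["p"].iloc[0] == wilcoxon_rank_sum(
            grouped_random.groups[a], grouped_random.groups[b], "less")

    def test_degenerate_steps_yield_na_not_abort(self, grouped_random):
        grid = CensoringGrid(delta=0.5, d_max=5.5)
        sweep = run_sweep(grouped_random, grid)
        step0 = sweep.table[sweep.table["k"] == 0]
        assert len(step0) > 0
        assert step0["p"].isna().all()
        assert sweep.table["p"].dropna().between(0, 1).all()

    def test_holm_within_step_across_pairs(self, grouped_random):
        grid = CensoringGrid(delta=5.5, d_max=5.5)
        specs = [TestSpec("wilcoxon", "less", p)
                 for p in [("A", "B"), ("A", "C"), ("B", "C")]]
        sweep = run_sweep(grouped_random, grid, specs, holm=True)
        last = sweep.table[sweep.table["k"] == 1].sort_values("pair")
        raw = last["p"].to_numpy()
        np.testing.assert_allclose(
            np.sort(last["p_holm"].to_numpy()), np.sort(holm_adjust(raw)))
        assert np.all(last["p_holm"].to_numpy() >= raw - 1e-15)

    def test_monotone_transform_invariance_of_rank_tests(self, grouped_random):
        """A strictly increasing map of data and thresholds leaves every
        rank-based p unchanged."""
        grid = CensoringGrid(delta=1.1, d_max=5.5)
        f = np.expm1  # strictly increasing
        transformed = GroupedDistances(
            "left", {g: f(d) for g, d in grouped_random.groups.items()},
            grouped_random.n_subjects)
        specs = [TestSpec("kruskal_wallis"),
                 TestSpec("wilcoxon", "less", ("A", "B")),
                 TestSpec("ks_two_sample", "two_sided", ("A", "C"))]
        for gamma in grid.thresholds[1:]:
            from lcdmcensor import censor

            c1 = censor(grouped_random, gamma)
            c2 = censor(transformed, f(gamma))
            assert kruskal_wallis([c1.groups[g] for g in "ABC"]) == pytest.approx(
                kruskal_wallis([c2.groups[g] for g in "ABC"]), abs=1e-12)
            assert wilcoxon_rank_sum(c1.groups["A"], c1.groups["B"], "less") == \
                pytest.approx(wilcoxon_rank_sum(c2.groups["A"], c2.groups["B"],
                                                "less"), abs=1e-12)

    def test_change_point_recovery(self, rng):
        """Two groups identical below 2 mm, group A thinned above: the 'less'
        Wilcoxon curve drops below 0.05 only near/above 2 mm."""
        base = rng.uniform(0, 5.5, size=30000)
        keep = (base <= 2.0) | (rng.uniform(size=30000) < 0.5)
        g_a = base[keep]
        g_b = rng.uniform(0, 5.5, size=30000)
        grouped = GroupedDistances("left", {"A": g_a, "B": g_b}, {"A": 1, "B": 1})
        grid = CensoringGrid(delta=0.1, d_max=5.5)
        sweep = run_sweep(grouped, grid,
                          [TestSpec("wilcoxon", "less", ("A", "B"))], holm=False)
        runs = [r for r in extract_runs(sweep, alpha=0.05, min_run_steps=3)
                if r.direction == "less"]
        assert runs, "no persistent significance run found"
        dominant = max(runs, key=lambda r: r.steps)
        assert dominant.d_start == pytest.approx(2.0, abs=0.3)


class TestExtractRuns:
    def _sweep_from_ps(self, ps, alternative="two_sided", delta=0.01):
        import pandas as pd

        grid = CensoringGrid(delta=delta, d_max=delta * (len(ps) - 1))
        spec = TestSpec("wilcoxon", alternative, ("A", "B"))
        rows = [(k, k * delta, spec.name, spec.pair_label, alternative, p,
                 np.nan, grid.reliable(k * delta), "") for k, p in enumerate(ps)]
        table = pd.DataFrame(rows, columns=["k", "gamma_mm", "test", "pair",
                                            "alternative", "p", "p_holm",
                                            "reliable", "n_per_group"])
        return SweepResult(table, grid, ["A", "B"])

    def test_no_run_when_never_significant(self):
        sweep = self._sweep_from_ps([0.5, 0.8, 0.2, 0.9])
        assert extract_runs(sweep, alpha=0.05, min_run_steps=1) == []

    def test_hand_enumerated_runs(self):
        ps = [1, 1, 0.01, 0.01, 0.01, 1, 0.04, 1]
        runs = extract_runs(self._sweep_from_ps(ps), alpha=0.05, min_run_steps=2)
        assert len(runs) == 1
        run = runs[0]
        assert run.steps == 3
        assert run.d_start == pytest.approx(0.02)
        assert run.d_end == pytest.approx(0.04)

    def test_terminal_step_only(self):
        ps = [0.5, 0.5, 0.01]
        runs = extract_runs(self._sweep_from_ps(ps), alpha=0.05, min_run_steps=1)
        assert len(runs) == 1
        assert runs[0].d_start == runs[0].d_end == pytest.approx(0.02)

    def test_mirror_line_reports_opposite_direction(self):
        ps = [0.5, 0.97, 0.99, 0.98, 0.5]
        runs = extract_runs(self._sweep_from_ps(ps, "less"), alpha=0.05,
                            min_run_steps=2)
        assert len(runs) == 1
        assert runs[0].direction == "greater"
        assert runs[0].steps == 3

    def test_runs_cannot_span_na(self):
        ps = [0.01, 0.01, np.nan, 0.01, 0.01]
        runs = extract_runs(self._sweep_from_ps(ps), alpha=0.05, min_run_steps=2)
        assert len(runs) == 2
        assert all(r.steps == 2 for r in runs)


class TestKernelDensity:
    def test_integral_is_one_per_group(self, grouped_random):
        x, dens, bws = kernel_density_export(grouped_random)
        for g, d in dens.items():
            assert np.trapezoid(d, x) == pytest.approx(1.0, abs=1e-3)
            assert bws[g] > 0

    def test_single_point_peaks_at_value(self):
        grouped = GroupedDistances("left", {"A": np.array([2.0])}, {"A": 1})
        x, dens, _ = kernel_density_export(grouped)
        assert x[np.argmax(dens["A"])] == pytest.approx(2.0, abs=0.02)

    def test_shift_recovery(self, rng):
        base = rng.normal(2.0, 0.3, size=4000)
        grouped = GroupedDistances("left", {"A": base, "B": base + 1.0},
                                   {"A": 1, "B": 1})
        x, dens, _ = kernel_density_export(grouped)
        shift = x[np.argmax(dens["B"])] - x[np.argmax(dens["A"])]
        assert shift == pytest.approx(1.0, abs=0.05)

    def test_empty_group_warns_and_is_omitted(self, rng):
        grouped = GroupedDistances("left",
                                   {"A": rng.uniform(0, 5, 50), "B": np.empty(0)},
                                   {"A": 1, "B": 0})
        with pytest.warns(UserWarning):
            _, dens, _ = kernel_density_export(grouped)
        assert "B" not in dens


class TestTestSpec:
    def test_multigroup_rejects_one_sided(self):
        with pytest.raises(ValueError):
            TestSpec("kruskal_wallis", "less")

    def test_pairwise_requires_pair(self):
        with pytest.raises(ValueError):
            TestSpec("wilcoxon", "less")
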