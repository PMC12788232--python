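"""Statistical-layer tests: flight-time law, power analysis, RM-ANOVA,
Friedman, post hoc corrections, effect sizes and the normality gate."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kicksyn import jumpstats as js
from kicksyn.synthgen import GeneratorConfig, generate_jump_heights


class TestJumpHeight:
    def test_zero_and_quadratic_law(self):
        assert js.jump_height(0.0) == 0.0
        assert js.jump_height(0.8) == pytest.approx(4 * js.jump_height(0.4))

    def test_flight_time_inversion(self):
        # 0.6328 s of air time corresponds to a 49.1 cm jump
        assert js.jump_height(0.6328) == pytest.approx(49.1, abs=0.05)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            js.jump_height(-0.1)

    def test_best_of_jumps(self):
        assert js.best_of_jumps([46.0, 48.2, 47.1]) == 48.2
        assert js.best_of_jumps([47.0, 47.0, 47.0]) == 47.0
        assert js.best_of_jumps([48.2, 46.0, 47.1]) == \
            js.best_of_jumps([46.0, 48.2, 47.1])
        with pytest.raises(ValueError):
            js.best_of_jumps([])


class TestSampleSize:
    def test_canonical_within_factor_example(self):
        """f=0.25, alpha=.05, power .80, 3 measurements, rho=.5 is the
        standard worked example of the within-factor convention: N=28."""
        n = js.rm_anova_sample_size(js.PowerSpec(effect_size_f=0.25))
        assert n == 28
        assert js.rm_anova_power(js.PowerSpec(effect_size_f=0.25), 28) >= 0.80
        assert js.rm_anova_power(js.PowerSpec(effect_size_f=0.25), 27) < 0.80

    def test_larger_effect_never_needs_more_subjects(self):
        ns = [js.rm_anova_sample_size(js.PowerSpec(effect_size_f=f))
              for f in (0.15, 0.25, 0.30, 0.40, 0.60)]
        assert all(b <= a for a, b in zip(ns, ns[1:]))

    def test_against_direct_noncentral_f_computation(self):
        """Independent oracle: recompute power from scipy noncentral-F at the
        returned N and N-1 for f=0.25, power .95, two measurements."""
        spec = js.PowerSpec(effect_size_f=0.25, power_target=0.95,
                            n_measurements=2)
        n = js.rm_anova_sample_size(spec)

        def oracle(N):
            df1, df2 = 1, N - 1
            lam = N * 0.25 ** 2 * 2 / 0.5
            crit = sps.f.ppf(0.95, df1, df2)
            return 1 - sps.ncf.cdf(crit, df1, df2, lam)

        assert oracle(n) >= 0.95 > oracle(n - 1)

    def test_unreachable_power_reports_cap(self):
        with pytest.raises(ValueError, match="unreachable"):
            js.rm_anova_sample_size(js.PowerSpec(effect_size_f=0.01,
                                                 power_target=0.99),
                                    n_cap=30)


class TestRmAnova:
    def test_degrees_of_freedom_for_18_subject_crossover(self, rng):
        """A 3x3 fully within design on 18 subjects tests main effects on
        (2, 34) df and the interaction on (4, 68) df."""
        res = js.two_way_rm_anova(rng.normal(size=(18, 3, 3)))
        assert (res[0].df_num, res[0].df_den) == (2, 34)
        assert (res[1].df_num, res[1].df_den) == (2, 34)
        assert (res[2].df_num, res[2].df_den) == (4, 68)

    def test_zero_between_condition_variation_gives_zero_F(self, rng):
        subj = rng.normal(size=(10, 1, 1))
        y = np.broadcast_to(subj, (10, 3, 3)).copy()
        res = js.two_way_rm_anova(y)
        assert all(r.F == 0.0 for r in res)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_anova_rm(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(12, 3, 3)) + rng.normal(size=(12, 1, 1))
        mine = js.two_way_rm_anova(y)
        rows = [{"s": i, "a": a, "b": b, "y": y[i, a, b]}
                for i in range(12) for a in range(3) for b in range(3)]
        from statsmodels.stats.anova import AnovaRM
        table = AnovaRM(pd.DataFrame(rows), "y", "s",
                        within=["a", "b"]).fit().anova_table
        for r, (_, ref) in zip(mine, table.iterrows()):
            assert r.F == pytest.approx(ref["F Value"], abs=1e-6)
            assert (r.df_num, r.df_den) == (ref["Num DF"], ref["Den DF"])
            assert r.p == pytest.approx(ref["Pr > F"], abs=1e-6)

    def test_partial_eta_squared_matches_pingouin(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 3)) + np.array([0.0, 0.4, 0.8])
        mine = js.one_way_rm_anova(y)
        import pingouin as pg
        df = pd.DataFrame({"y": y.ravel(),
                           "cond": np.tile(np.arange(3), 10),
                           "subj": np.repeat(np.arange(10), 3)})
        ref = pg.rm_anova(df, dv="y", within="cond", subject="subj",
                          effsize="np2")
        assert mine.F == pytest.approx(ref["F"][0], abs=1e-6)
        assert mine.eta_p_sq == pytest.approx(ref["np2"][0], abs=1e-6)

    def test_missing_cells_rejected(self):
        y = np.ones((5, 3, 3))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            js.two_way_rm_anova(y)


class TestFriedman:
    def test_hand_computed_no_tie_case(self):
        """Three subjects ranking three conditions identically:
        chi2 = 12n/(k(k+1)) * sum (Rbar - (k+1)/2)^2 = 6."""
        y = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.1, 0.5, 0.9]])
        res = js.friedman_test(y)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2

    def test_column_permutation_invariance(self, rng):
        y = rng.normal(size=(9, 3))
        a = js.friedman_test(y)
        b = js.friedman_test(y[:, [2, 0, 1]])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_raw == pytest.approx(b.p_raw)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_including_ties(self, seed):
        rng = np.random.default_rng(seed)
        y = np.round(rng.normal(size=(12, 4)), 1)   # rounding induces ties
        mine = js.friedman_test(y)
        ref = sps.friedmanchisquare(*y.T)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_rows_flagged_degenerate(self):
        res = js.friedman_test(np.ones((5, 3)))
        assert res.degenerate and np.isnan(res.statistic)


class TestPosthoc:
    def test_three_conditions_make_three_comparisons(self, rng):
        y = rng.normal(size=(10, 3))
        assert len(js.posthoc_pairwise(y, parametric=True)) == 3
        assert len(js.posthoc_pairwise(y, parametric=False)) == 3

    def test_bonferroni_and_holm_sequences(self, rng):
        """Adjusted p values follow the step rules: Bonferroni multiplies by
        the family size (capped at 1); Holm multiplies sorted p's by k, k-1,
        ... with running-maximum monotonicity."""
        y = rng.normal(size=(15, 3)) + np.array([0.0, 0.6, 1.2])
        for correction in ("bonferroni", "holm"):
            res = js.posthoc_pairwise(y, parametric=True,
                                      correction=correction)
            raw = np.array([r.p_raw for r in res])
            adj = np.array([r.p_adjusted for r in res])
            if correction == "bonferroni":
                np.testing.assert_allclose(adj, np.minimum(raw * 3, 1.0))
            else:
                order = np.argsort(raw)
                expect = np.empty(3)
                running = 0.0
                for rank, idx in enumerate(order):
                    running = max(running, raw[idx] * (3 - rank))
                    expect[idx] = min(running, 1.0)
                np.testing.assert_allclose(adj, expect)
            assert (adj >= raw - 1e-15).all()

    def test_wilcoxon_branch_signs_and_effect(self, rng):
        y = np.column_stack([rng.normal(size=30),
                             rng.normal(size=30) + 2.0])
        res = js.posthoc_pairwise(y, labels=("A", "B"), parametric=False)[0]
        assert res.statistic < 0          # A well below B
        assert res.effect_size < 0
        assert res.p_adjusted < 0.01

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            js.posthoc_pairwise(np.ones((1, 3)))


class TestCohensD:
    def test_zero_sign_and_worked_value(self):
        assert js.cohens_d_from_z(0.0, 16) == 0.0
        assert js.cohens_d_from_z(-1.5, 16) == -js.cohens_d_from_z(1.5, 16)
        # z=2, n=16: r = 0.5, d = 2*0.5/sqrt(0.75)
        assert js.cohens_d_from_z(2.0, 16) == pytest.approx(1.1547, abs=1e-4)

    def test_overlarge_z_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            js.cohens_d_from_z(5.0, 4)


class TestShapiroGate:
    def test_gaussian_cells_usually_route_parametric(self):
        """Type-I of the gate: a single Gaussian cell (n=18) passes in at
        least 90% of seeds (about 5% per-cell rejection)."""
        hits = sum(
            js.shapiro_gate({"cell": np.random.default_rng(s).normal(
                size=18)}).parametric
            for s in range(100))
        assert hits >= 90

    def test_skewed_cells_route_nonparametric(self):
        hits = sum(
            not js.shapiro_gate({"cell": np.exp(
                1.5 * np.random.default_rng(s).normal(size=18))}).parametric
            for s in range(100))
        assert hits >= 95

    def test_constant_cells_flagged(self):
        gate = js.shapiro_gate({"a": np.ones(10),
                                "b": np.random.default_rng(0).normal(
                                    size=10)})
        assert not gate.parametric and gate.degenerate_cells == ("a",)

    def test_tiny_cell_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            js.shapiro_gate({"a": np.array([1.0, 2.0])})


class TestPowerOrdering:
    def test_bigger_injected_effect_rejects_more(self):
        """Raising the ESG jump advantage monotonically raises the rejection
        rate of the protocol main effect."""
        rates = []
        for boost in (0.0, 1.5, 3.0):
            base = GeneratorConfig(n_subjects=12).without_protocol_effects()
            table = {p: {t: ms for t, ms in tab.items()}
                     for p, tab in base.jump_means_sds.items()}
            table["ESG"] = {t: (m + boost, s)
                            for t, (m, s) in table["ESG"].items()}
            cfg = GeneratorConfig(n_subjects=12, jump_means_sds=table)
            rej = 0
            reps = 120
            root = np.random.SeedSequence(77)
            for ss in root.spawn(reps):
                h = generate_jump_heights(cfg, np.random.default_rng(ss))
                arr = np.stack([h[p] for p in ("ESG", "RBG", "SQG")], axis=1)
                rej += js.two_way_rm_anova(arr)[0].p < 0.05
            rates.append(rej / reps)
        assert rates[0] < rates[1] < rates[2]
        assert rates[2] > 0.9
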