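"""Statistical workflow: endpoints, Welch/Cohen/Levene, factorial ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import conetrace as ct
from conetrace.stats import AssayOutcome, GroupSummary

# group summaries of total movement activity for the two strain contrasts
# (susceptible strain: n = 40 vs 55 assays; resistant strain: 10 vs 10)
KIS_PLUS = GroupSummary("KS PFAS+", 40, 3628.3, 1014.209)
KIS_MINUS = GroupSummary("KS PFAS-", 55, 3211.655, 830.311)
TIA_PLUS = GroupSummary("TS PFAS+", 10, 3804.0, 531.208)
TIA_MINUS = GroupSummary("TS PFAS-", 10, 2141.6, 738.529)


class TestWelch:
    def test_susceptible_strain_contrast(self):
        res = ct.welch_t(KIS_PLUS, KIS_MINUS)
        assert round(res.t, 3) == 2.130
        assert round(res.df, 3) == 73.649
        assert round(res.p, 3) == 0.036

    def test_resistant_strain_contrast(self):
        res = ct.welch_t(TIA_PLUS, TIA_MINUS)
        assert abs(res.t - 5.778) <= 1e-3
        assert round(res.df, 3) == 16.346
        assert res.p < 0.001

    def test_matches_scipy_from_stats(self):
        res = ct.welch_t(KIS_PLUS, KIS_MINUS)
        t, p = sps.ttest_ind_from_stats(
            KIS_PLUS.mean, KIS_PLUS.sd, KIS_PLUS.n,
            KIS_MINUS.mean, KIS_MINUS.sd, KIS_MINUS.n,
            equal_var=False,
        )
        assert res.t == pytest.approx(float(t), rel=1e-12)
        assert res.p == pytest.approx(float(p), rel=1e-9)

    def test_identical_groups_t_zero(self):
        g = GroupSummary("g", 10, 5.0, 2.0)
        assert ct.welch_t(g, g).t == 0.0

    def test_degenerate_zero_variance_rejected(self):
        a = GroupSummary("a", 5, 1.0, 0.0)
        with pytest.raises(ValueError, match="variance"):
            ct.welch_t(a, a)


class TestCohensD:
    def test_small_effect_with_ci(self):
        eff = ct.cohens_d(KIS_PLUS, KIS_MINUS)
        assert round(eff.d, 3) == 0.457
        assert round(eff.ci_lo, 3) == 0.039
        assert round(eff.ci_hi, 3) == 0.875

    def test_large_effect_with_ci(self):
        eff = ct.cohens_d(TIA_PLUS, TIA_MINUS)
        assert round(eff.d, 3) == 2.584
        assert round(eff.ci_lo, 3) == 1.312
        assert round(eff.ci_hi, 3) == 3.857

    def test_equal_means_d_zero(self):
        a = GroupSummary("a", 8, 3.0, 1.0)
        b = GroupSummary("b", 8, 3.0, 2.0)
        assert ct.cohens_d(a, b).d == 0.0

    def test_zero_pooled_sd_rejected(self):
        a = GroupSummary("a", 8, 3.0, 0.0)
        with pytest.raises(ValueError, match="pooled"):
            ct.cohens_d(a, a)


class TestCiMean:
    @pytest.mark.parametrize(
        "summary, hi",
        [(KIS_PLUS, 3952.66), (TIA_MINUS, 2669.91), (TIA_PLUS, 4184.00)],
    )
    def test_printed_upper_bounds(self, summary, hi):
        assert round(ct.ci_mean(summary)[1], 2) == hi

    def test_zero_sd_degenerate(self):
        g = GroupSummary("g", 5, 4.2, 0.0)
        assert ct.ci_mean(g) == (4.2, 4.2)


class TestLevene:
    def test_matches_bruteforce_anova_on_deviations(self):
        groups = [[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]]
        res = ct.levene_test(groups)
        # independent oracle: one-way ANOVA on |y - group mean|
        devs = [np.abs(np.array(g) - np.mean(g)) for g in groups]
        alld = np.concatenate(devs)
        gm = alld.mean()
        ss_b = sum(len(d) * (d.mean() - gm) ** 2 for d in devs)
        ss_w = sum(((d - d.mean()) ** 2).sum() for d in devs)
        k, n = len(devs), len(alld)
        f_ref = (ss_b / (k - 1)) / (ss_w / (n - k))
        assert res.F == pytest.approx(f_ref, rel=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(sps.f.sf(f_ref, 1, 4), rel=1e-9)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ct.levene_test([[1.0, 1.0, 1.0], [2.0, 2.0]])

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            ct.levene_test([[1.0, 2.0]])


class TestEndpoints:
    @staticmethod
    def outcomes(deaths, swatch="s1"):
        return [
            AssayOutcome(
                swatch_id=swatch,
                replicate_id=f"r{i}",
                n_exposed=5,
                n_kd_60min=d,
                n_dead_24h=d,
                arm="treated",
            )
            for i, d in enumerate(deaths)
        ]

    def test_full_mortality(self):
        rates = ct.endpoint_rates(self.outcomes([5, 5, 5, 5, 5]))
        row = rates.per_swatch.iloc[0]
        assert row["n_exposed"] == 25  # 5 replicates x 5 mosquitoes
        assert row["mortality_pct"] == 100.0

    def test_partial_mortality_arithmetic(self):
        rates = ct.endpoint_rates(self.outcomes([0, 1, 2, 3, 4]))
        assert rates.per_swatch.iloc[0]["mortality_pct"] == pytest.approx(40.0)

    def test_nonstandard_exposure_flagged_not_rejected(self):
        out = self.outcomes([2, 2])
        odd = AssayOutcome(
            swatch_id="s1", replicate_id="r9", n_exposed=4,
            n_kd_60min=1, n_dead_24h=1, arm="treated",
        )
        rates = ct.endpoint_rates(out + [odd])
        assert bool(rates.per_swatch.iloc[0]["nonstandard_exposure"])

    def test_outcome_bounds_validated(self):
        with pytest.raises(ValueError):
            AssayOutcome("s", "r", 5, 6, 0, "treated")


class TestAbbott:
    def test_zero_control_identity(self):
        assert ct.abbott_adjust(56.0, 0.0).adjusted_pct == 56.0

    def test_full_treated_stays_full(self):
        for c in (0.0, 4.0, 12.0, 20.0):
            assert ct.abbott_adjust(100.0, c).adjusted_pct == pytest.approx(100.0)

    def test_formula_in_adjustment_window(self):
        res = ct.abbott_adjust(60.0, 10.0)
        assert res.applied
        assert res.adjusted_pct == pytest.approx(55.56, abs=0.005)

    def test_low_control_reported_unadjusted(self):
        res = ct.abbott_adjust(60.0, 4.0)
        assert not res.applied and res.adjusted_pct == 60.0

    def test_high_control_invalidates_assay(self):
        res = ct.abbott_adjust(60.0, 30.0)
        assert not res.valid

    def test_control_at_100_rejected(self):
        with pytest.raises(ValueError):
            ct.abbott_adjust(60.0, 100.0)


class TestTwoWayAnova:
    @staticmethod
    def balanced_2x2(effects=(3.0, -2.0, 1.0), reps=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, a in enumerate(("s1", "s2")):
            for j, b in enumerate(("n1", "n2")):
                mu = (
                    10.0
                    + effects[0] * (1 if i else -1)
                    + effects[1] * (1 if j else -1)
                    + effects[2] * (1 if i == j else -1)
                )
                for _ in range(reps):
                    rows.append({"strain": a, "net": b, "y": mu + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_balanced_f_matches_classical_decomposition(self):
        df = self.balanced_2x2()
        rep = ct.two_way_anova(df, "y", "strain", "net")
        # closed-form balanced two-way SS oracle
        y = df["y"].to_numpy()
        gm = y.mean()
        cell = df.groupby(["strain", "net"])["y"].mean().unstack().to_numpy()
        am = cell.mean(axis=1)
        bm = cell.mean(axis=0)
        r = 5
        ss_a = r * 2 * ((am - gm) ** 2).sum()
        ss_b = r * 2 * ((bm - gm) ** 2).sum()
        ss_ab = r * ((cell - am[:, None] - bm[None, :] + gm) ** 2).sum()
        ss_res = (
            df.groupby(["strain", "net"])["y"]
            .apply(lambda v: ((v - v.mean()) ** 2).sum())
            .sum()
        )
        f_oracle = {
            "strain": (ss_a / 1) / (ss_res / 16),
            "net": (ss_b / 1) / (ss_res / 16),
            "strain:net": (ss_ab / 1) / (ss_res / 16),
        }
        for _, row in rep.effects.iterrows():
            assert row["F"] == pytest.approx(f_oracle[row["effect"]], rel=1e-9)
            ss = {"strain": ss_a, "net": ss_b, "strain:net": ss_ab}[row["effect"]]
            assert row["partial_eta2"] == pytest.approx(ss / (ss + ss_res), rel=1e-9)

    def test_emmeans_equal_unweighted_cell_means_on_balanced_data(self):
        df = self.balanced_2x2(seed=3)
        rep = ct.two_way_anova(df, "y", "strain", "net")
        cell = df.groupby(["strain", "net"])["y"].mean().unstack()
        for _, row in rep.emmeans["strain"].iterrows():
            assert row["emmean"] == pytest.approx(
                cell.loc[row["level"]].mean(), rel=1e-9
            )

    def test_tukey_with_two_levels_equals_t_test(self):
        df = self.balanced_2x2(seed=5)
        rep = ct.two_way_anova(df, "y", "strain", "net")
        row = rep.contrasts["strain"].iloc[0]
        p_t = 2 * sps.t.sf(abs(row["t"]), rep.df_resid)
        assert row["p_tukey"] == pytest.approx(p_t, rel=1e-6)

    def test_null_data_f_near_one_and_p_moderate(self):
        df = self.balanced_2x2(effects=(0.0, 0.0, 0.0), reps=30, seed=7)
        rep = ct.two_way_anova(df, "y", "strain", "net")
        assert (rep.effects["p"] > 0.001).all()
        assert 0 < rep.shapiro_p <= 1

    def test_strong_main_effect_detected(self):
        df = self.balanced_2x2(effects=(0.0, 5.0, 0.0), reps=10, seed=11)
        rep = ct.two_way_anova(df, "y", "strain", "net")
        p_net = rep.effects.set_index("effect").loc["net", "p"]
        assert p_net < 1e-6

    def test_text_report_contains_all_sections(self):
        rep = ct.two_way_anova(self.balanced_2x2(seed=13), "y", "strain", "net")
        text = rep.format_text()
        for needle in (
            "Type-III",
            "Shapiro-Wilk",
            "Estimated marginal means: strain",
            "Tukey-adjusted contrasts: net",
            "net | strain=s1",
        ):
            assert needle in text

    def test_empty_cell_rejected(self):
        df = self.balanced_2x2()
        df = df[~((df["strain"] == "s1") & (df["net"] == "n2"))]
        with pytest.raises(ValueError, match="cell"):
            ct.two_way_anova(df, "y", "strain", "net")


def test_group_summary_validation():
    with pytest.raises(ValueError):
        GroupSummary("g", 1, 0.0, 1.0)
    with pytest.raises(ValueError):
        GroupSummary("g", 5, 0.0, -1.0)
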