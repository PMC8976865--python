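"""Model-structure arithmetic, likelihood-ratio tests, Satterthwaite
contrasts, FDR, and effect sizes -- cross-checked against lme4/lmerTest."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import nirsdual.models as M
from nirsdual.models import (ModelSpec, adjust_contrasts, analyze_dv, cohens_d,
                             count_parameters, effect_band, fdr_adjust, fit,
                             likelihood_ratio_test, planned_contrasts)
from nirsdual.sim import ScenarioConfig, simulate_scores


def _spec(fixed, short=False, est="ML", dv="scan"):
    return ModelSpec(dv=dv, fixed=fixed, short_slope=short, estimation=est)


class TestCountParameters:
    """The printed model sizes: a session-effects model has 7 parameters and
    its individual-differences counterpart 12; adding the extracerebral
    random slope makes these 8 and 13."""

    @pytest.mark.parametrize("fixed,short,expected", [
        ("1 + Session", False, 7),
        ("1 + Group + Group:Session", False, 12),
        ("1 + Session", True, 8),
        ("1 + Group + Group:Session", True, 13),
        ("1", False, 3),
        ("1 + Group", False, 4),
        ("1 + Group + Group:Session + Group:Session:AdpTF", False, 22),
    ])
    def test_counts(self, fixed, short, expected):
        assert count_parameters(_spec(fixed, short)) == expected

    def test_comparison_dfs(self):
        """df of the three standard comparisons: 4 (null), 8 (group), 5
        (between models), identical with and without the short slope."""
        for short in (False, True):
            null = count_parameters(_spec("1", short))
            sess = count_parameters(_spec("1 + Session", short))
            grp = count_parameters(_spec("1 + Group", short))
            full = count_parameters(_spec("1 + Group + Group:Session", short))
            assert sess - null == 4
            assert full - grp == 8
            assert full - sess == 5

    def test_adptf_term_adds_ten(self):
        a = count_parameters(_spec("1 + Group + Group:Session"))
        b = count_parameters(_spec("1 + Group + Group:Session + Group:Session:AdpTF"))
        assert b - a == 10

    def test_unknown_term_errors(self):
        with pytest.raises(Exception):
            count_parameters(_spec("1 + Bogus"))

    def test_random_intercept_mandatory(self):
        with pytest.raises(ValueError):
            ModelSpec(dv="y", fixed="1", random_intercept=False)


class TestLikelihoodRatioTest:
    def test_identical_models_give_zero(self, model_frame):
        a = fit(_spec("1 + Group"), model_frame)
        b = fit(_spec("1 + Group"), model_frame)
        out = likelihood_ratio_test(a, b)
        assert out.chi2 == pytest.approx(0.0, abs=1e-6)
        assert out.df == 0

    def test_table_style_df_five(self, model_frame):
        sess = fit(_spec("1 + Session"), model_frame)
        full = fit(_spec("1 + Group + Group:Session"), model_frame)
        out = likelihood_ratio_test(sess, full)
        assert out.df == 5
        assert out.chi2 >= 0

    def test_session_nested_in_group_session(self, model_frame):
        # span-based nesting: Session main effect lies inside Group:Session
        sess = fit(_spec("1 + Session"), model_frame)
        full = fit(_spec("1 + Group + Group:Session"), model_frame)
        assert likelihood_ratio_test(sess, full).p <= 1

    def test_non_nested_raises(self, model_frame):
        grp = fit(_spec("1 + Group"), model_frame)
        sess = fit(_spec("1 + Session"), model_frame)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(grp, sess)

    def test_reml_fits_rejected(self, model_frame):
        a = fit(_spec("1 + Group", est="REML"), model_frame)
        b = fit(_spec("1 + Group + Group:Session", est="REML"), model_frame)
        with pytest.raises(ValueError, match="ML"):
            likelihood_ratio_test(a, b)

    def test_nested_loglik_ordering(self, model_frame):
        fits = [fit(_spec(f), model_frame)
                for f in ("1", "1 + Session", "1 + Group + Group:Session")]
        assert fits[0].llf <= fits[1].llf + 1e-6 <= fits[2].llf + 1e-5

    def test_chi2_invariant_to_dv_rescaling(self, model_frame):
        df2 = model_frame.copy()
        df2["scan"] = 100.0 * df2["scan"] + 7.0
        a1 = likelihood_ratio_test(fit(_spec("1 + Group"), model_frame),
                                   fit(_spec("1 + Group + Group:Session"), model_frame))
        a2 = likelihood_ratio_test(fit(_spec("1 + Group"), df2),
                                   fit(_spec("1 + Group + Group:Session"), df2))
        assert a1.chi2 == pytest.approx(a2.chi2, rel=1e-3)


class TestAgainstLme4:
    """statsmodels-backed fits must agree with the R reference stack."""

    @pytest.fixture(scope="class")
    def r_output(self, model_frame, tmp_path_factory):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        d = tmp_path_factory.mktemp("r")
        csv = d / "data.csv"
        model_frame.to_csv(csv, index=False)
        script = d / "check.R"
        script.write_text(f"""
suppressMessages({{library(lmerTest); library(emmeans)}})
d <- read.csv("{csv}")
d$Group <- factor(d$Group, levels=c("attention","accuracy"))
d$Session <- factor(d$Session)
ml <- lmer(scan ~ Group*Session + (1|ID), d, REML=FALSE)
reml <- lmer(scan ~ Group*Session + (1|ID), d, REML=TRUE)
emm <- emmeans(reml, ~ Group | Session, lmer.df="satterthwaite")
pr <- summary(pairs(emm), adjust="none")
cat(sprintf("%.6f %.6f %.6f %.6f %.6f\\n", logLik(ml), logLik(reml),
    pr$estimate[1], pr$df[1], pr$SE[1]))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        return [float(x) for x in out.stdout.split()]

    def test_loglik_matches(self, model_frame, r_output):
        ll_ml, ll_reml = r_output[0], r_output[1]
        ml = fit(_spec("1 + Group + Group:Session"), model_frame)
        reml = fit(_spec("1 + Group + Group:Session", est="REML"), model_frame)
        assert ml.llf == pytest.approx(ll_ml, abs=1e-4)
        assert reml.llf == pytest.approx(ll_reml, abs=1e-4)

    def test_contrast_and_satterthwaite_match(self, model_frame, r_output):
        est_r, df_r, se_r = r_output[2], r_output[3], r_output[4]
        reml = fit(_spec("1 + Group + Group:Session", est="REML"), model_frame)
        cons = planned_contrasts(reml)
        c_e1 = next(c for c in cons if c.label == "attention vs accuracy @ E1")
        assert c_e1.estimate == pytest.approx(est_r, abs=1e-5)
        assert c_e1.se == pytest.approx(se_r, rel=1e-4)
        assert c_e1.df == pytest.approx(df_r, rel=0.02)


class TestContrasts:
    def test_scheme_enumerates_eleven(self):
        scheme = M.default_contrast_scheme()
        assert len(scheme) == 11
        assert sum(s["kind"] == "between" for s in scheme) == 5
        assert sum(s["kind"] == "within" for s in scheme) == 6

    def test_identical_groups_give_null_estimates(self):
        """Duplicate one group's data under both labels: every Group x
        Session cell mean coincides, so contrasts between groups vanish."""
        cfg = ScenarioConfig(seed=33, n_subjects=6)
        sc = simulate_scores(cfg)
        half = sc[sc.group == "attention"].copy()
        flipped = half.copy()
        flipped["group"] = "accuracy"
        flipped["subject"] = flipped["subject"] + "x"
        both = pd.concat([half, flipped], ignore_index=True)
        df = both.rename(columns={"subject": "ID", "group": "Group",
                                  "session": "Session", "adp_tf": "AdpTF"})
        reml = fit(_spec("1 + Group + Group:Session", est="REML"), df)
        for c in planned_contrasts(reml):
            if c.kind == "between":
                assert abs(c.estimate) < 1e-6

    def test_absent_level_raises(self, model_frame):
        sub = model_frame[model_frame["Session"] != "H2"]
        reml = fit(_spec("1 + Group + Group:Session", est="REML"), sub)
        with pytest.raises(ValueError, match="H2"):
            planned_contrasts(reml, [{"kind": "between", "session": "H2",
                                      "label": "x"}])

    def test_satterthwaite_between_vs_within_scales(self, model_frame):
        """Between-group comparisons are subject-level (df near n_subjects);
        within-group session comparisons are observation-level."""
        reml = fit(_spec("1 + Group + Group:Session", est="REML"), model_frame)
        cons = planned_contrasts(reml)
        between = [c.df for c in cons if c.kind == "between"]
        within = [c.df for c in cons if c.kind == "within"]
        assert all(5 < df < 30 for df in between)
        assert all(df > 100 for df in within)

    def test_adjusted_p_never_below_raw(self, model_frame):
        reml = fit(_spec("1 + Group + Group:Session", est="REML"), model_frame)
        cons = adjust_contrasts(planned_contrasts(reml))
        assert all(c.adj_p >= c.p - 1e-15 for c in cons)


class TestFitRecovery:
    def test_null_data_estimates_near_zero(self):
        cfg = ScenarioConfig(
            seed=77, scan_slope_by_group={"attention": 0.0, "accuracy": 0.0},
            scan_base_by_group={"attention": 0.55, "accuracy": 0.55})
        df = simulate_scores(cfg).rename(columns={
            "subject": "ID", "group": "Group", "session": "Session",
            "adp_tf": "AdpTF"})
        res = fit(_spec("1 + Group + Group:Session"), df)
        se = res.result.bse_fe
        for name, est in res.fe_params.items():
            if name == "Intercept":
                continue
            assert abs(est) < 3 * se[name]

    def test_planted_interaction_recovered_at_scale(self):
        """At n=200 subjects the Group x Session divergence is estimated
        within 10% of its planted value."""
        slope = 0.1
        cfg = ScenarioConfig(seed=99, n_subjects=200,
                             scan_slope_by_group={"attention": slope,
                                                  "accuracy": -slope},
                             scan_base_by_group={"attention": 0.5, "accuracy": 0.5})
        df = simulate_scores(cfg).rename(columns={
            "subject": "ID", "group": "Group", "session": "Session",
            "adp_tf": "AdpTF"})
        res = fit(_spec("1 + Group + Group:Session"), df)
        # planted E1->E3 divergence between groups: 2*slope*2 sessions
        reml = res.fe_params
        att_e3 = reml["Group[attention]:Session[T.E3]"]
        acc_e3 = reml["Group[accuracy]:Session[T.E3]"]
        got = att_e3 - acc_e3
        assert got == pytest.approx(2 * slope * 2, rel=0.10)


class TestFdrAndEffectSize:
    def test_bh_hand_example(self):
        """m=4, sorted p (0.01,0.02,0.03,0.04): adjusted_i = min over j>=i of
        p_j * 4/j = 0.04 for every rank."""
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert len(fdr_adjust([])) == 0

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @pytest.mark.parametrize("est,sd,d,band", [
        (0.5, 0.5, 1.0, "large"),
        (0.0, 0.5, 0.0, "negligible"),
        (0.1, 0.5, 0.2, "small"),
        (0.25, 0.5, 0.5, "medium"),
    ])
    def test_cohens_d_bands(self, est, sd, d, band):
        got = cohens_d(est, sd)
        assert got == pytest.approx(d)
        assert effect_band(got) == band

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0)


def test_heteroscedasticity_check_fires_on_scaled_noise():
    rng = np.random.default_rng(11)
    n_subj, n_obs = 10, 30
    rows = []
    for i in range(n_subj):
        mu = rng.uniform(1, 5)
        for sess in ("E1", "E2", "E3", "H1", "H2"):
            for k in range(6):
                val = mu + rng.normal(0, 0.5 * mu)   # noise grows with level
                rows.append({"ID": f"S{i}", "Group": "attention" if i < 5 else "accuracy",
                             "Session": sess, "y": val})
    df = pd.DataFrame(rows)
    reml = fit(ModelSpec(dv="y", fixed="1 + Group + Group:Session",
                         estimation="REML"), df)
    slope, p = M.heteroscedasticity_check(reml)
    assert slope > 0 and p < 0.05


def test_analyze_dv_battery(model_frame):
    an = analyze_dv(model_frame, "scan")
    assert set(an.comparisons) >= {"session_vs_null", "group_session_vs_group",
                                   "group_session_vs_session"}
    assert an.comparisons["group_session_vs_group"].df == 8
    assert an.comparisons["session_vs_null"].df == 4
    assert an.comparisons["group_session_vs_session"].df == 5
    assert an.comparisons["adptf_vs_group_session"].df == 10
    # planted group-divergent trends make the interaction significant here
    assert an.comparisons["group_session_vs_group"].p < 0.05
    assert len(an.contrasts) == 11
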