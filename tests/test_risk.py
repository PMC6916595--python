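"""Risk contrasts: scaling, quintiles, subtypes, heterogeneity, death sets."""

import numpy as np
import pandas as pd
import pytest

import treeletomics as tm
from treeletomics import risk
from treeletomics.clogit import CLogitFit


def latent_exposure(cohort, block="latent_block1", name="score"):
    s = cohort.participants.set_index("participant_id")[block]
    return risk.ExposureSpec(s, name=name)


class TestPerSDScaling:
    def test_identity_scaling(self):
        fit = CLogitFit(np.log(0.77), 0.1, np.log(0.77) - 0.196,
                        np.log(0.77) + 0.196, 0.01, -10.0, 50, 50, True)
        out = risk.or_per_sd(fit, 1.0)
        assert out.odds_ratio == pytest.approx(0.77)

    def test_scaling_law(self):
        fit = CLogitFit(0.3, 0.1, 0.104, 0.496, 0.01, -10.0, 50, 50, True)
        out = risk.or_per_sd(fit, 2.0)
        assert out.odds_ratio == pytest.approx(np.exp(0.6))
        assert out.ci_low == pytest.approx(0.208)

    def test_non_positive_sd_rejected(self):
        fit = CLogitFit(0.3, 0.1, 0.1, 0.5, 0.01, -10.0, 50, 50, True)
        with pytest.raises(ValueError):
            risk.or_per_sd(fit, 0.0)

    def test_prescaled_exposure_equals_posthoc_scaling(self, effect_cohort):
        """Fitting on score/SD equals rescaling the raw-unit fit."""
        s = effect_cohort.participants.set_index("participant_id")["latent_block1"]
        pre = risk.clogit_fit(
            effect_cohort, risk.ExposureSpec(s, scale="per_sd", name="s"),
            risk.AdjustmentSet.none())
        raw = risk.clogit_fit(
            effect_cohort, risk.ExposureSpec(s, scale="raw", name="s"),
            risk.AdjustmentSet.none())
        sd = risk.ExposureSpec(s, name="s").reference_sd(effect_cohort)
        post = risk.or_per_sd(raw, sd)
        assert pre.beta == pytest.approx(post.beta, abs=1e-10)


class TestAdjustedFit:
    def test_effect_recovered_with_adjustment(self, effect_cohort):
        """Null covariates leave the latent-score effect unbiased."""
        fit = risk.clogit_fit(effect_cohort, latent_exposure(effect_cohort))
        # generating OR 0.6 per 1 SD of the standardized latent score
        assert fit.ci_low < np.log(0.6) < fit.ci_high

    def test_constant_exposure_refused(self, null_cohort):
        s = pd.Series(1.0, index=null_cohort.participants["participant_id"])
        with pytest.raises(Exception, match="SD|variation"):
            risk.clogit_fit(null_cohort, risk.ExposureSpec(s, name="flat"),
                            risk.AdjustmentSet.none())


class TestQuintiles:
    def test_percentile_cutpoints_linear_interpolation(self, null_cohort):
        part = null_cohort.participants
        ctrl = part[part["role"] == "control"]["participant_id"]
        scores = pd.Series(0.0, index=part["participant_id"])
        scores.loc[ctrl] = np.arange(1.0, float(len(ctrl)) + 1)
        np.testing.assert_allclose(
            np.percentile(np.arange(1.0, 101.0), [20, 40, 60, 80]),
            [20.8, 40.6, 60.4, 80.2])

    def test_quintile_table_shape_and_reference(self, effect_cohort):
        s = effect_cohort.participants.set_index("participant_id")["latent_block1"]
        out = risk.quintile_analysis(effect_cohort, s, risk.AdjustmentSet.none())
        assert list(out["quintile"]) == ["Q1", "Q2", "Q3", "Q4", "Q5"]
        assert out.loc[0, "odds_ratio"] == 1.0
        assert len(out.attrs["cutpoints"]) == 4

    def test_protective_effect_monotone_decreasing(self, effect_cohort):
        """A strong protective score yields decreasing quintile ORs."""
        s = effect_cohort.participants.set_index("participant_id")["latent_block1"]
        out = risk.quintile_analysis(effect_cohort, s, risk.AdjustmentSet.none())
        assert out.loc[4, "odds_ratio"] < out.loc[1, "odds_ratio"]

    def test_degenerate_scores_rejected(self, null_cohort):
        s = pd.Series(np.tile([1.0, 2.0], null_cohort.n_sets),
                      index=null_cohort.participants["participant_id"])
        with pytest.raises(ValueError, match="distinct"):
            risk.quintile_analysis(null_cohort, s)


class TestSubtypes:
    def test_single_subtype_equals_overall(self, effect_cohort):
        expo = latent_exposure(effect_cohort)
        fits = risk.subtype_analysis(effect_cohort, expo,
                                     risk.AdjustmentSet.none())
        assert list(fits) == ["advanced"]  # all cases labeled advanced
        overall = risk.clogit_fit(effect_cohort, expo, risk.AdjustmentSet.none())
        assert fits["advanced"].beta == pytest.approx(overall.beta, abs=1e-12)

    def test_disjoint_subtypes_partition_informative_sets(self, null_cohort):
        expo = latent_exposure(null_cohort)
        fits = risk.subtype_analysis(null_cohort, expo,
                                     risk.AdjustmentSet.none())
        labels = risk._case_labels(null_cohort, "stage")
        labeled = labels.isin(["localized", "advanced"]).sum()
        assert sum(f.n_sets for f in fits.values()) == labeled

    def test_effect_only_in_advanced_recovered(self, panel):
        """Cases driven by the pattern only when advanced: the subtype
        fit sees the effect, the localized fit stays near the null."""
        eff = tm.EffectSpec({("block1", "advanced"): 0.5})
        adv = tm.simulate_matched_pairs(panel, eff, 400, "advanced", seed=31)
        nul = tm.simulate_matched_pairs(panel, eff, 400, "localized", seed=32)
        part = pd.concat([adv.participants,
                          nul.participants.assign(
                              set_id=lambda d: d["set_id"] + "L",
                              participant_id=lambda d: d["participant_id"] + "L")],
                         ignore_index=True)
        logc = pd.concat([adv.log_concentrations,
                          nul.log_concentrations.set_axis(
                              nul.log_concentrations.index + "L")])
        both = tm.MatchedCohort(part, logc, panel)
        expo = latent_exposure(both)
        fits = risk.subtype_analysis(both, expo, risk.AdjustmentSet.none())
        assert fits["advanced"].odds_ratio < 0.7
        lo, hi = fits["localized"].or_ci
        assert lo < 1.0 < hi

    def test_empty_labels_rejected(self, effect_cohort):
        expo = latent_exposure(effect_cohort)
        empty = pd.Series(dtype=object)
        with pytest.raises(ValueError, match="no labeled"):
            risk.subtype_analysis(effect_cohort, expo,
                                  risk.AdjustmentSet.none(), labels=empty)


class TestHeterogeneity:
    def test_identical_subtypes_give_null_chi2(self, effect_cohort):
        """Two copies of the same data cannot show heterogeneity."""
        c = effect_cohort
        dup_part = pd.concat([
            c.participants,
            c.participants.assign(
                set_id=lambda d: d["set_id"] + "B",
                participant_id=lambda d: d["participant_id"] + "B",
                stage="localized")], ignore_index=True)
        dup_logc = pd.concat([
            c.log_concentrations,
            c.log_concentrations.set_axis(c.log_concentrations.index + "B")])
        dup = tm.MatchedCohort(dup_part, dup_logc, c.panel)
        expo = latent_exposure(dup)
        het = risk.heterogeneity_lrt(dup, expo, risk.AdjustmentSet.none())
        assert het.df == 1
        assert het.chi2 == pytest.approx(0.0, abs=1e-6)
        assert het.p_value > 0.99

    def test_gross_heterogeneity_detected(self, panel):
        protective = tm.EffectSpec({("block1", "advanced"): 0.5})
        harmful = tm.EffectSpec({("block1", "localized"): 2.0})
        a = tm.simulate_matched_pairs(panel, protective, 400, "advanced", seed=41)
        b = tm.simulate_matched_pairs(panel, harmful, 400, "localized", seed=42)
        part = pd.concat([a.participants,
                          b.participants.assign(
                              set_id=lambda d: d["set_id"] + "B",
                              participant_id=lambda d: d["participant_id"] + "B")],
                         ignore_index=True)
        logc = pd.concat([a.log_concentrations,
                          b.log_concentrations.set_axis(
                              b.log_concentrations.index + "B")])
        both = tm.MatchedCohort(part, logc, panel)
        het = risk.heterogeneity_lrt(both, latent_exposure(both),
                                     risk.AdjustmentSet.none())
        assert het.p_value < 0.001

    def test_single_subtype_rejected(self, effect_cohort):
        with pytest.raises(ValueError, match="2 non-empty"):
            risk.heterogeneity_lrt(effect_cohort, latent_exposure(effect_cohort),
                                   risk.AdjustmentSet.none())


class TestFollowupStrata:
    def test_empty_stratum_reported_as_none(self, panel):
        cohort = tm.simulate_matched_pairs(
            panel, tm.EffectSpec(), 100, "overall", seed=51)
        cohort.participants["time_to_dx"] = 5.0
        out = risk.followup_strata(cohort, latent_exposure(cohort),
                                   risk.AdjustmentSet.none())
        assert out[">10y"] is None and out["<=10y"] is not None

    def test_null_effect_in_both_strata(self, null_cohort):
        out = risk.followup_strata(null_cohort, latent_exposure(null_cohort),
                                   risk.AdjustmentSet.none())
        for fit in out.values():
            lo, hi = fit.or_ci
            assert lo < 1.0 < hi


class TestMutualAdjustment:
    def test_correlated_component_enters_model(self, null_cohort):
        part = null_cohort.participants.set_index("participant_id")
        scores = part[["latent_block1", "latent_block3"]].rename(
            columns={"latent_block1": "TC1", "latent_block3": "TC3"})
        # blocks 1 and 3 are generated with r = 0.46 > 0.2 -> co-adjusted
        adj = risk.mutual_adjust(null_cohort, "TC1", scores,
                                 risk.AdjustmentSet.none(), threshold=0.2)
        solo = risk.clogit_fit(null_cohort,
                               risk.ExposureSpec(scores["TC1"], name="TC1"),
                               risk.AdjustmentSet.none())
        assert adj.beta != pytest.approx(solo.beta, abs=1e-12)

    def test_uncorrelated_components_no_coadjustment(self, null_cohort):
        part = null_cohort.participants.set_index("participant_id")
        scores = part[["latent_block1", "latent_block2"]].rename(
            columns={"latent_block1": "TC1", "latent_block2": "TC2"})
        adj = risk.mutual_adjust(null_cohort, "TC1", scores,
                                 risk.AdjustmentSet.none(), threshold=0.2)
        solo = risk.clogit_fit(null_cohort,
                               risk.ExposureSpec(scores["TC1"], name="TC1"),
                               risk.AdjustmentSet.none())
        assert adj.beta == pytest.approx(solo.beta, abs=1e-12)


class TestDeathAnalysis:
    def test_exclusion_counts(self, panel):
        cohort = tm.simulate_matched_pairs(
            panel, tm.EffectSpec(), 3057, "overall", seed=61)
        cohort = tm.assign_outcomes(cohort, seed=62)
        _, counts = risk.death_analysis(cohort, latent_exposure(cohort),
                                        risk.AdjustmentSet.none())
        assert counts["n_analyzed"] == counts["n_death_sets"] - counts[
            "n_censored_excluded"]
        # at the configured rates roughly 326 deaths and 29 exclusions
        assert 250 < counts["n_death_sets"] < 400
        assert 10 <= counts["n_censored_excluded"] <= 50

    def test_no_censoring_no_exclusions(self, panel):
        cohort = tm.simulate_matched_pairs(
            panel, tm.EffectSpec(), 500, "death", seed=63)
        _, counts = risk.death_analysis(cohort, latent_exposure(cohort),
                                        risk.AdjustmentSet.none())
        assert counts["n_censored_excluded"] == 0
        assert counts["n_analyzed"] == 500

    def test_no_eligible_sets_rejected(self, effect_cohort):
        with pytest.raises(ValueError, match="eligible"):
            risk.death_analysis(effect_cohort, latent_exposure(effect_cohort),
                                risk.AdjustmentSet.none())


def test_adjustment_design_levels(null_cohort):
    design = risk.adjustment_design(null_cohort, risk.AdjustmentSet())
    assert "age_blood" in design.columns
    assert "bmi_q2" in design.columns and "bmi_q1" not in design.columns
    assert "smoking_never" not in design.columns  # reference level omitted
    assert "smoking_unknown" in design.columns    # unknown is its own level
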