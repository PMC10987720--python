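"""Synthetic trial generator: determinism, structure, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wmtransfer as wt
from wmtransfer import scoring, study


class TestCohort:
    def test_sizes_and_columns(self):
        cfg = wt.StudyConfig()
        cohort = wt.generate_cohort(cfg, seed=0)
        assert len(cohort) == 60
        assert cohort["group"].value_counts().to_dict() == {"EG": 30, "CG": 30}
        for col in ("R_verbal", "R_spatial", "d_f_verbal", "K", "gds", "mmse"):
            assert col in cohort

    def test_latent_ranges(self):
        cohort = wt.generate_cohort(wt.StudyConfig(), seed=5)
        assert cohort["R_verbal"].between(0, 1).all()
        assert cohort["R_spatial"].between(0, 1).all()
        assert (cohort["d_f_verbal"] >= 0).all()
        assert (cohort["K"] > 0).all()
        assert cohort["gds"].between(0, 15).all()
        assert cohort["mmse"].between(0, 30).all()

    def test_determinism(self):
        a = wt.generate_cohort(wt.StudyConfig(), seed=9)
        b = wt.generate_cohort(wt.StudyConfig(), seed=9)
        assert a.equals(b)

    def test_zero_variance_latents_are_identical(self):
        cfg = wt.StudyConfig(R_sd=0.0, d_f_sd=0.0, c_sd=0.0, K_sd=0.0,
                             p_proc_sd=0.0, simple_span_sd=0.0, school_assoc=0.0)
        cohort = wt.generate_cohort(cfg, seed=2)
        for col in ("R_spatial", "d_f_spatial", "c", "K", "p_proc"):
            assert cohort[col].nunique() == 1

    def test_schooling_gap_between_arms(self):
        gaps = []
        for seed in range(15):
            cohort = wt.generate_cohort(wt.StudyConfig(), seed=seed)
            means = cohort.groupby("group")["schooling_years"].mean()
            gaps.append(means["CG"] - means["EG"])
        assert np.mean(gaps) == pytest.approx(1.5, abs=0.5)

    def test_schooling_correlates_with_verbal_latents(self):
        cohort = wt.generate_cohort(wt.StudyConfig(n_per_group=300), seed=1)
        r = np.corrcoef(cohort["schooling_years"], cohort["R_verbal"])[0, 1]
        assert 0.15 < r < 0.55

    def test_eligibility_exclusions_bounded(self):
        """A handful of exclusions per 60-person draw, never a large fraction."""
        sizes = []
        for seed in range(30):
            cohort = wt.generate_cohort(wt.StudyConfig(), seed=seed)
            retained, excluded = wt.apply_eligibility(cohort)
            sizes.append(len(excluded))
        assert np.mean(sizes) == pytest.approx(5.0, abs=2.5)
        assert max(sizes) <= 15


class TestTrialRun:
    def test_structure(self, default_run):
        n = len(default_run["participants"])
        trials = default_run["trials"]
        # every retained participant: 2 sessions x (27+27+12+14) items
        assert len(trials) == n * 2 * 80
        assert set(trials["condition"]) == {"inclusion", "exclusion", "global", "local"}
        protocols = default_run["span_protocols"]
        per_ps = protocols.groupby(["participant_id", "session"]).size()
        assert (per_ps == (5 + 6 + 6) * 2).all()   # levels x 2 trials per level

    def test_training_log_arms(self, default_run):
        log = default_run["training_log"]
        participants = default_run["participants"]
        assert set(log["participant_id"]) == set(participants["participant_id"])
        merged = log.merge(participants[["participant_id", "group"]],
                           on="participant_id")
        eg = merged[merged["group"] == "EG"]
        counts = eg.groupby(["participant_id", "session", "task"]).size()
        assert (counts == 15).all()
        # control pseudo-training is non-adaptive: one level per session
        cg = merged[merged["group"] == "CG"]
        assert (cg.groupby(["participant_id", "session"])["level"].nunique() == 1).all()

    def test_complete_cases_after_eligibility(self, default_run):
        scores = default_run["scores"]
        counts = scores.groupby("participant_id").size()
        assert (counts == 14).all()               # 2 sessions x 7 measures
        excluded = set(default_run["excluded"]["participant_id"])
        assert not excluded & set(scores["participant_id"])

    def test_determinism_end_to_end(self):
        cfg = wt.StudyConfig(n_per_group=6, include_training=False)
        a = wt.simulate_trial_run(wt.generate_cohort(cfg, 4), cfg, 4)
        b = wt.simulate_trial_run(wt.generate_cohort(cfg, 4), cfg, 4)
        assert a["scores"].equals(b["scores"])
        assert a["trials"].equals(b["trials"])

    def test_version_counterbalancing_recorded(self, default_run):
        p = default_run["participants"]
        assert set(zip(p["pretest_version"], p["posttest_version"])) == {(1, 2), (2, 1)}
        n12 = (p["pretest_version"] == 1).sum()
        assert abs(n12 - (len(p) - n12)) <= 1


class TestNullModel:
    def test_zero_deltas_leave_groups_exchangeable(self):
        """With all training deltas 0, expected group differences in change
        are 0 for every measure (sign test across seeds)."""
        cfg = wt.StudyConfig(delta_R_verbal=0, delta_R_spatial=0, delta_K=0,
                             delta_d_f=0, include_training=False)
        diffs = {m: [] for m in study.MEASURES}
        for seed in range(12):
            run = wt.simulate_trial_run(wt.generate_cohort(cfg, seed), cfg, seed)
            scores = run["scores"]
            wide = scores.pivot_table(index=["participant_id", "group", "measure"],
                                      columns="session", values="score")
            change = (wide["post"] - wide["pre"]).reset_index()
            for m, grp in change.groupby("measure"):
                means = grp.groupby("group")[0].mean()
                diffs[m].append(means["EG"] - means["CG"])
        for m, vals in diffs.items():
            t, p = stats.ttest_1samp(vals, 0.0)
            assert p > 0.01, f"{m} shows a systematic null-model group difference"

    def test_null_interaction_rejection_near_nominal(self):
        """Scaled-down null calibration through the full pipeline."""
        cfg = wt.StudyConfig(delta_R_verbal=0, delta_R_spatial=0, delta_K=0,
                             n_per_group=30)
        rates = study.replicate_interaction_rates(cfg, n_reps=120, seed=17)
        pooled = rates["rejection_rate"].mean()   # 7 measures x 120 reps
        assert pooled == pytest.approx(0.05, abs=0.025)


class TestParameterRecovery:
    def test_estimated_recollection_change_tracks_injected_shift(self):
        """Mean EG change in d'(i) is monotone (near-linear) in the injected
        recollection shift; precision boosted via scaled forms."""
        deltas = [0.0, 0.06, 0.12, 0.18, 0.24, 0.30]
        gains = []
        for i, d in enumerate(deltas):
            cfg = wt.StudyConfig(delta_R_verbal=d, delta_R_spatial=d, delta_K=0,
                                 scale=6, include_training=False, retest_R=0.0)
            run = wt.simulate_trial_run(wt.generate_cohort(cfg, 100 + i), cfg, 100 + i)
            scores = run["scores"]
            sub = scores[scores["measure"] == "d_i_verbal"].pivot_table(
                index=["participant_id", "group"], columns="session", values="score"
            ).reset_index()
            eg = sub[sub["group"] == "EG"]
            gains.append((eg["post"] - eg["pre"]).mean())
        rho = stats.spearmanr(deltas, gains).statistic
        assert rho > 0.95
        assert gains[-1] > gains[0]

    def test_reading_span_gain_monotone_in_capacity_shift(self):
        """EG reading-span gain grows with the injected capacity shift."""
        gains = []
        for d_k in (0.0, 0.5, 1.0):
            per_seed = []
            for seed in range(25):
                cfg = wt.StudyConfig(delta_K=d_k, retest_K=0.0)
                cohort = wt.generate_cohort(cfg, seed)
                retained, _ = wt.apply_eligibility(cohort)
                rng = np.random.default_rng(seed)
                pre = study._simulate_protocols(retained, "pre", cfg, rng)
                post = study._simulate_protocols(retained, "post", cfg, rng)
                s = scoring.score_spans(pd.concat([pre, post], ignore_index=True))
                s = s.merge(retained[["participant_id", "group"]], on="participant_id")
                sub = s[(s["measure"] == "reading_span") & (s["group"] == "EG")]
                wide = sub.pivot_table(index="participant_id", columns="session",
                                       values="score")
                per_seed.append((wide["post"] - wide["pre"]).mean())
            gains.append(np.mean(per_seed))
        assert gains[0] < gains[1] < gains[2]

    def test_simple_spans_isolated_when_unloaded(self):
        """With zero capacity loading the backward spans cannot inherit the
        trained gain, by construction."""
        cfg = wt.StudyConfig(simple_K_loading=0.0, delta_K=2.0, retest_K=0.0)
        cohort = wt.generate_cohort(cfg, 3)
        pre = study._span_abilities(cohort, "pre", cfg)
        post = study._span_abilities(cohort, "post", cfg)
        assert np.allclose(pre["digit_span"], post["digit_span"])
        assert np.allclose(pre["spatial_span"], post["spatial_span"])
        assert (post["reading_span"] > pre["reading_span"]).any()


def test_span_task_measures_bounded():
    cfg = wt.StudyConfig()
    cohort = wt.generate_cohort(cfg, 8)
    scores = wt.span_task_measures(cohort, cfg, seed=8)
    assert set(scores["measure"]) == set(scoring.SPAN_MEASURES)
    assert scores["score"].between(0, 1).all()


def test_analyze_study_outputs(default_run):
    results = wt.analyze_study(default_run["scores"], default_run["participants"])
    anova = results["anova"]
    assert anova["measure"].nunique() == 7
    assert set(anova["effect"]) == {"group", "session", "interaction"}
    assert results["ancova"]["measure"].nunique() == 7
    es = results["effect_sizes"]
    assert len(es) == 14                       # 7 measures x 2 groups
    assert (results["anova"]["p"].between(0, 1)).all()
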