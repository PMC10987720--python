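"""Mixed ANOVA, ANCOVA, effect sizes, eligibility screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wmtransfer as wt
from wmtransfer import inference


def make_dataset(rng, n1=10, n2=10, group_effect=0.0, session_effect=0.0,
                 interaction=0.0, sd=1.0):
    rows = []
    for g, n, shift in (("EG", n1, interaction), ("CG", n2, 0.0)):
        base = rng.normal(0.0, 1.0, n) + (group_effect if g == "EG" else 0.0)
        pre = base + rng.normal(0.0, sd, n)
        post = base + session_effect + shift + rng.normal(0.0, sd, n)
        for i in range(n):
            pid = f"{g}{i}"
            rows.append({"participant_id": pid, "group": g, "session": "pre",
                         "score": pre[i]})
            rows.append({"participant_id": pid, "group": g, "session": "post",
                         "score": post[i]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_interaction_equals_squared_change_score_t(self):
        """Algebraic identity on 100 random datasets, to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(3, 25, size=2)
            data = make_dataset(rng, int(n1), int(n2),
                                interaction=rng.normal(), sd=rng.uniform(0.2, 2))
            res = wt.mixed_anova_2x2(data)["interaction"]
            wide = data.pivot_table(index=["participant_id", "group"],
                                    columns="session", values="score")
            change = (wide["post"] - wide["pre"]).reset_index(level="group")
            c_eg = change[change["group"] == "EG"][0].to_numpy()
            c_cg = change[change["group"] == "CG"][0].to_numpy()
            t, p = stats.ttest_ind(c_eg, c_cg, equal_var=True)
            assert res.F == pytest.approx(t**2, abs=1e-10, rel=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_independent_mixed_anova_library(self):
        """Balanced dataset cross-checked against pingouin's mixed ANOVA."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        data = make_dataset(rng, 12, 12, group_effect=0.4, session_effect=0.3,
                            interaction=0.5)
        mine = wt.mixed_anova_2x2(data)
        theirs = pingouin.mixed_anova(
            data=data, dv="score", within="session", subject="participant_id",
            between="group",
        ).set_index("Source")
        assert mine["group"].F == pytest.approx(theirs.loc["group", "F"], rel=1e-8)
        assert mine["session"].F == pytest.approx(theirs.loc["session", "F"], rel=1e-8)
        assert mine["interaction"].F == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )

    def test_constant_scores_give_zero_f(self):
        data = make_dataset(np.random.default_rng(0), 5, 5, sd=0.0)
        data["score"] = 1.0
        res = wt.mixed_anova_2x2(data)
        assert all(r.F == 0.0 and r.p == 1.0 for r in res.values())

    def test_degenerate_noise_free_interaction(self):
        """Group-specific change with zero error SS exercises the guard."""
        rows = []
        for g, delta in (("EG", 1.0), ("CG", 0.0)):
            for i in range(4):
                rows.append({"participant_id": f"{g}{i}", "group": g,
                             "session": "pre", "score": float(i)})
                rows.append({"participant_id": f"{g}{i}", "group": g,
                             "session": "post", "score": float(i) + delta})
        res = wt.mixed_anova_2x2(pd.DataFrame(rows))["interaction"]
        assert np.isinf(res.F) and res.p == 0.0 and res.eta_p2 == 1.0

    def test_eta_p2_identity(self):
        rng = np.random.default_rng(3)
        data = make_dataset(rng, 8, 9, interaction=0.4)
        for r in wt.mixed_anova_2x2(data).values():
            assert r.eta_p2 == pytest.approx(
                r.df1 * r.F / (r.df1 * r.F + r.df2), rel=1e-12
            )
            assert r.eta_p2 == pytest.approx(
                r.ss_effect / (r.ss_effect + r.ss_error), rel=1e-12
            )

    def test_missing_session_rejected(self):
        data = make_dataset(np.random.default_rng(0), 4, 4)
        broken = data.drop(data[(data["participant_id"] == "EG0")
                                & (data["session"] == "post")].index)
        with pytest.raises(ValueError, match="EG0"):
            wt.mixed_anova_2x2(broken)


class TestAncova:
    def test_orthogonal_covariate_is_a_no_op(self):
        rng = np.random.default_rng(11)
        data = make_dataset(rng, 15, 15, interaction=0.5)
        pids = data["participant_id"].unique()
        cov = pd.Series(rng.normal(size=len(pids)), index=pids)
        adj = wt.ancova_change(data, cov)
        unadj = wt.mixed_anova_2x2(data)["interaction"]
        assert adj.F == pytest.approx(unadj.F, rel=0.15)

    def test_confounded_covariate_shrinks_effect(self):
        """When the group difference in change is carried entirely by the
        covariate, adjustment removes it."""
        rng = np.random.default_rng(13)
        rows = []
        for g in ("EG", "CG"):
            for i in range(20):
                pid = f"{g}{i}"
                cov_val = rng.normal(2.0 if g == "EG" else -2.0, 0.5)
                change = 0.8 * cov_val + rng.normal(0, 0.2)
                rows.append({"participant_id": pid, "group": g, "session": "pre",
                             "score": 0.0, "cov": cov_val})
                rows.append({"participant_id": pid, "group": g, "session": "post",
                             "score": change, "cov": cov_val})
        data = pd.DataFrame(rows)
        cov = data.drop_duplicates("participant_id").set_index("participant_id")["cov"]
        adj = wt.ancova_change(data[["participant_id", "group", "session", "score"]], cov)
        unadj = wt.mixed_anova_2x2(data)["interaction"]
        assert unadj.F > 10
        assert adj.F < unadj.F / 2

    def test_constant_outcome_gives_zero_f(self):
        data = make_dataset(np.random.default_rng(0), 5, 5)
        data["score"] = 2.0
        pids = data["participant_id"].unique()
        cov = pd.Series(np.arange(len(pids), dtype=float), index=pids)
        assert wt.ancova_change(data, cov).F == 0.0

    def test_zero_variance_covariate_rejected(self):
        data = make_dataset(np.random.default_rng(0), 5, 5)
        pids = data["participant_id"].unique()
        with pytest.raises(ValueError, match="variance"):
            wt.ancova_change(data, pd.Series(1.0, index=pids))


class TestHedgesD:
    def test_no_change_is_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert wt.hedges_d(x, x).d == 0.0

    def test_correction_factor_at_n27(self):
        assert inference.hedges_j(26) == pytest.approx(1 - 3 / 103)
        es = wt.hedges_d(np.zeros(27), np.ones(27) + np.linspace(-0.1, 0.1, 27))
        assert es.J == pytest.approx(1 - 3 / 103)

    def test_one_sd_shift_approaches_one(self):
        rng = np.random.default_rng(5)
        pre = rng.normal(0, 1, 5000)
        post = pre + 1.0
        es = wt.hedges_d(pre, post)
        assert es.d == pytest.approx(1.0, abs=0.05)

    def test_change_convention(self):
        rng = np.random.default_rng(6)
        pre = rng.normal(0, 1, 30)
        post = pre + rng.normal(0.5, 0.3, 30)
        es = wt.hedges_d(pre, post, sd="change")
        diff = post - pre
        expected = diff.mean() / diff.std(ddof=1) * inference.hedges_j(29)
        assert es.d == pytest.approx(expected)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            wt.hedges_d(np.ones(5), np.full(5, 2.0))


class TestBonferroni:
    @pytest.mark.parametrize("alpha, m, expected",
                             [(0.05, 7, 0.05 / 7), (0.05, 1, 0.05), (0.01, 5, 0.002)])
    def test_threshold(self, alpha, m, expected):
        assert wt.bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            wt.bonferroni_alpha(1.5, 7)


class TestEligibility:
    def _cohort(self, **overrides):
        base = {"participant_id": ["a"], "gds": [5], "mmse": [28],
                "sessions_missed": [0], "cognition_medication": [False]}
        base.update({k: [v] for k, v in overrides.items()})
        return pd.DataFrame(base)

    @pytest.mark.parametrize(
        "overrides, reason",
        [
            (dict(gds=10), "depression screen"),
            (dict(mmse=23), "cognitive screen"),
            (dict(sessions_missed=3), "attendance"),
            (dict(cognition_medication=True), "medication"),
        ],
    )
    def test_each_rule_triggers(self, overrides, reason):
        retained, excluded = wt.apply_eligibility(self._cohort(**overrides))
        assert len(retained) == 0
        assert excluded["reason"].iloc[0] == reason

    def test_boundaries_are_inclusive_of_retention(self):
        retained, excluded = wt.apply_eligibility(
            self._cohort(gds=9, mmse=24, sessions_missed=2)
        )
        assert len(retained) == 1 and len(excluded) == 0

    def test_multiple_reasons_listed(self):
        _, excluded = wt.apply_eligibility(self._cohort(gds=12, mmse=20))
        assert excluded["reason"].iloc[0] == "depression screen; cognitive screen"

    def test_missing_field_rejected(self):
        with pytest.raises(ValueError, match="mmse"):
            wt.apply_eligibility(self._cohort().drop(columns="mmse"))


def test_baseline_balance_report(default_run):
    report = inference.baseline_balance(
        default_run["scores"], default_run["participants"]
    )
    assert set(report["measure"]) >= set(wt.study.MEASURES)
    assert report["p"].between(0, 1).all()
    assert (report[report["measure"] == "gender"]["test"] == "chi-square").all()
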