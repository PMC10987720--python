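"""Inference stack of a two-arm pre/post trial.

The workhorse is the 2 (group: experimental vs. control) x 2 (session:
pre vs. post) mixed ANOVA.  With only two occasions the design collapses
algebraically: the between-subjects stratum is a one-way ANOVA on
subject means, and the within-subjects stratum is carried entirely by
the change scores ``c = post - pre``.  In particular the group x session
interaction F equals the squared pooled-variance two-sample t on the
change scores — an identity used as an independent oracle in the test
suite.  Effect sizes are reported as partial eta squared,
``SS_effect / (SS_effect + SS_error) = df1 F / (df1 F + df2)``.

The covariate-adjusted analysis (years of schooling in the motivating
design) is run as an ANCOVA on change scores, ``c ~ group + centered
covariate``, which in a two-occasion design is equivalent to the
covariate-adjusted group x session interaction.

Standardised pre/post gains use Cohen's d with Hedges' small-sample
correction ``J = 1 - 3 / (4 df - 1)``; the denominator convention
(pooled SD of pre and post, or SD of the change scores) is configurable
because published reports are often ambiguous about it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AnovaResult",
    "EffectSize",
    "mixed_anova_2x2",
    "ancova_change",
    "hedges_d",
    "hedges_j",
    "bonferroni_alpha",
    "apply_eligibility",
    "baseline_balance",
    "ELIGIBILITY_RULES",
]


@dataclass(frozen=True)
class AnovaResult:
    """One F test of a mixed-design decomposition."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class EffectSize:
    """Hedges-corrected standardised mean difference."""

    d: float
    J: float
    df: int
    convention: str


def _f_result(effect: str, ss_eff: float, df1: int, ss_err: float, df2: int) -> AnovaResult:
    if ss_err <= 0.0:
        # degenerate: no residual variability in this stratum
        if ss_eff > 0.0:
            F, p, eta = float("inf"), 0.0, 1.0
        else:
            F, p, eta = 0.0, 1.0, 0.0
    else:
        F = (ss_eff / df1) / (ss_err / df2)
        p = float(stats.f.sf(F, df1, df2))
        eta = ss_eff / (ss_eff + ss_err)
    return AnovaResult(effect, float(F), df1, df2, float(p), float(eta),
                       float(ss_eff), float(ss_err))


def _pre_post_matrix(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (group labels, pre, post) aligned per participant."""
    for col in ("participant_id", "group", "session", "score"):
        if col not in data:
            raise ValueError(f"missing column {col!r}")
    wide = data.pivot_table(
        index=["participant_id", "group"], columns="session", values="score",
        aggfunc="mean",
    )
    for sess in ("pre", "post"):
        if sess not in wide.columns:
            raise ValueError(f"no {sess!r} session in data")
        missing = wide.index[wide[sess].isna()].get_level_values(0).tolist()
        if missing:
            raise ValueError(f"participants missing {sess!r} session: {missing}")
    groups = wide.index.get_level_values("group").to_numpy()
    return groups, wide["pre"].to_numpy(float), wide["post"].to_numpy(float)


def mixed_anova_2x2(data: pd.DataFrame) -> dict[str, AnovaResult]:
    """Two-group, two-occasion mixed ANOVA via its closed-form decomposition.

    ``data`` is a long table with columns ``participant_id, group,
    session (pre|post), score`` for a single measure; every participant
    must have both sessions and each group at least two members.
    Returns ``{"group": ..., "session": ..., "interaction": ...}``.

    The session and interaction tests are computed from change scores
    (Type-III style: the session effect is evaluated at the unweighted
    mean of the group change means, so it is orthogonal to the
    interaction under imbalance).
    """
    groups, pre, post = _pre_post_matrix(data)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(labels)}")
    g1, g2 = groups == labels[0], groups == labels[1]
    n1, n2 = int(g1.sum()), int(g2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 participants")
    n = n1 + n2

    # Between-subjects stratum: one-way ANOVA on subject means, doubled
    # because each subject mean summarises two observations.
    m = (pre + post) / 2.0
    grand = m.mean()
    ss_group = 2.0 * (n1 * (m[g1].mean() - grand) ** 2 + n2 * (m[g2].mean() - grand) ** 2)
    ss_subj = 2.0 * ((m[g1] - m[g1].mean()) ** 2).sum() + 2.0 * ((m[g2] - m[g2].mean()) ** 2).sum()

    # Within-subjects stratum: carried by the change scores.
    c = post - pre
    c1, c2 = c[g1].mean(), c[g2].mean()
    ss_werr = (((c[g1] - c1) ** 2).sum() + ((c[g2] - c2) ** 2).sum()) / 2.0
    h = n1 * n2 / (n1 + n2)          # harmonic weight
    ss_int = h * (c1 - c2) ** 2 / 2.0
    u = (c1 + c2) / 2.0              # unweighted mean change
    ss_sess = 2.0 * h * u ** 2

    return {
        "group": _f_result("group", ss_group, 1, ss_subj, n - 2),
        "session": _f_result("session", ss_sess, 1, ss_werr, n - 2),
        "interaction": _f_result("interaction", ss_int, 1, ss_werr, n - 2),
    }


def ancova_change(data: pd.DataFrame, covariate: pd.Series) -> AnovaResult:
    """Covariate-adjusted group effect on change scores.

    Fits ``change ~ group + centered covariate`` by OLS and F-tests the
    group term; with two occasions this equals the covariate-adjusted
    group x session interaction.  ``covariate`` is indexed by
    participant_id.

    Raises
    ------
    ValueError
        If the covariate has zero variance or is missing participants.
    """
    groups, pre, post = _pre_post_matrix(data)
    pids = (
        data.pivot_table(index=["participant_id", "group"], columns="session",
                         values="score", aggfunc="mean")
        .index.get_level_values(0)
    )
    cov = pd.Series(covariate).reindex(pids)
    if cov.isna().any():
        raise ValueError(
            f"covariate missing for participants: {list(pids[cov.isna()])}"
        )
    cov = cov.to_numpy(float)
    if not np.isfinite(cov).all():
        raise ValueError("covariate contains non-finite values")
    if np.var(cov) == 0.0:
        raise ValueError("covariate has zero variance")

    change = post - pre
    labels = np.unique(groups)
    x = np.column_stack([(groups == labels[1]).astype(float), cov - cov.mean()])
    fit = sm.OLS(change, sm.add_constant(x)).fit()
    restricted = sm.OLS(change, sm.add_constant(cov - cov.mean())).fit()
    df2 = int(fit.df_resid)
    ss_eff = float(restricted.ssr - fit.ssr)
    ss_err = float(fit.ssr)
    res = _f_result("group_adjusted", ss_eff, 1, ss_err, df2)
    return res


def hedges_j(df: int) -> float:
    """Hedges' small-sample correction factor J = 1 - 3/(4 df - 1)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_d(
    pre: np.ndarray | pd.Series,
    post: np.ndarray | pd.Series,
    sd: str = "pooled",
) -> EffectSize:
    """Hedges-corrected Cohen's d for a paired pre/post contrast.

    ``sd='pooled'`` (default) standardises by ``sqrt((var(pre) +
    var(post)) / 2)``; ``sd='change'`` standardises by the SD of the
    change scores.  Both use ``df = n - 1`` for the correction factor.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same length)")
    n = len(pre)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    diff = post.mean() - pre.mean()
    if sd == "pooled":
        denom = np.sqrt((pre.var(ddof=1) + post.var(ddof=1)) / 2.0)
    elif sd == "change":
        denom = (post - pre).std(ddof=1)
    else:
        raise ValueError(f"unknown sd convention {sd!r}")
    if denom == 0.0:
        if diff == 0.0:
            return EffectSize(0.0, hedges_j(n - 1), n - 1, sd)
        raise ValueError("zero standardiser with nonzero mean difference")
    j = hedges_j(n - 1)
    return EffectSize(float(diff / denom * j), j, n - 1, sd)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


#: rule label -> (required column, predicate on the value)
ELIGIBILITY_RULES: dict[str, tuple[str, object]] = {
    "depression screen": ("gds", lambda v: v > 9),
    "cognitive screen": ("mmse", lambda v: v < 24),
    "attendance": ("sessions_missed", lambda v: v > 2),
    "medication": ("cognition_medication", bool),
}


def apply_eligibility(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into retained and excluded participants.

    Exclusion rules (all boundaries exclusive of the retained side):
    depression screen score > 9, global-cognition screen score < 24,
    more than 2 of the 10 training sessions missed, or medication
    affecting cognition.  The excluded frame carries a ``reason`` column
    listing every triggered rule.
    """
    for rule, (col, _) in ELIGIBILITY_RULES.items():
        if col not in cohort:
            raise ValueError(f"missing column {col!r} (needed for rule {rule!r})")
    reasons = []
    for _, row in cohort.iterrows():
        hit = [rule for rule, (col, pred) in ELIGIBILITY_RULES.items() if pred(row[col])]
        reasons.append("; ".join(hit))
    reasons = pd.Series(reasons, index=cohort.index, name="reason")
    excluded = cohort[reasons != ""].copy()
    excluded["reason"] = reasons[reasons != ""]
    retained = cohort[reasons == ""].copy()
    return retained, excluded


def baseline_balance(
    scores: pd.DataFrame, participants: pd.DataFrame, session: str = "pre"
) -> pd.DataFrame:
    """Convenience report: one-way ANOVAs comparing groups at baseline.

    Runs a one-way F test per measure on the given session plus a plain
    contingency chi-square on gender if present.
    """
    merged = scores[scores["session"] == session]
    if "group" not in merged.columns:
        merged = merged.merge(
            participants[["participant_id", "group"]], on="participant_id"
        )
    rows = []
    for measure, grp in merged.groupby("measure"):
        samples = [g["score"].to_numpy() for _, g in grp.groupby("group")]
        f, p = stats.f_oneway(*samples)
        rows.append({"measure": measure, "statistic": float(f), "p": float(p),
                     "test": "one-way ANOVA"})
    if "gender" in participants:
        table = pd.crosstab(participants["group"], participants["gender"])
        if table.shape[1] > 1:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append({"measure": "gender", "statistic": float(chi2),
                         "p": float(p), "test": "chi-square"})
    return pd.DataFrame(rows)
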