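"""Synthetic two-arm pre/post training trial with a dual-process cohort.

This module generates a complete trial with the statistical structure
the analysis assumes: a cohort of older adults with latent recollection,
familiarity, criterion and span-capacity parameters; a two-arm random
assignment with a years-of-schooling imbalance; trial-level recognition
responses on frozen forms; span protocols; adaptive-training logs for
the experimental arm; and the long score table feeding the inference
stack.

Training transfer is injected as a post-test shift of the latent
parameters of the experimental group (recollection and span capacity by
default, familiarity optionally for falsification experiments) rather
than as mechanistic session-by-session learning: the design makes only
pre/post contrasts, so the latent shift is the quantity of interest.  A
small retest effect common to both arms produces the session main
effects typical of repeated testing.

The generator's defaults are chosen so that the experimental arm's
standardised pre/post gains on the recollection-specific measures sit in
the large-effect range (Hedges d near 0.9) at the design's sample sizes
(27 and 28 analysable participants out of a 60-person draw); see
docs/methods.md for how each default was fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design, dualprocess, inference, scoring, training

__all__ = [
    "StudyConfig",
    "MEASURES",
    "generate_cohort",
    "simulate_trial_run",
    "span_task_measures",
    "analyze_study",
    "replicate_interaction_rates",
]

MEASURES = scoring.ALL_MEASURES

READING_SPAN_SIZES = (2, 3, 4, 5, 6)
SIMPLE_SPAN_SIZES = (2, 3, 4, 5, 6, 7)
TRIALS_PER_SPAN_LEVEL = 2


@dataclass
class StudyConfig:
    """All tunable knobs of the synthetic trial.

    Only the effect deltas (applied to the experimental group at
    post-test) and the sample size are usually varied; the remaining
    fields fix the latent population.  ``scale`` multiplies the number of
    test items per truth class on every recognition form, for precision
    studies in which single-participant d' noise would otherwise dominate.
    """

    n_per_group: int = 30          # per arm at draw, before eligibility exclusions

    # latent dual-process population
    R_mean: float = 0.25
    R_sd: float = 0.12
    d_f_verbal_mean: float = 1.3   # verbal forms run near ceiling by design
    d_f_spatial_mean: float = 1.1
    d_f_sd: float = 0.25
    c_mean: float = 0.5
    c_sd: float = 0.2

    # span-limited trainee
    K_mean: float = 4.0
    K_sd: float = 0.8
    p_proc_mean: float = 0.90
    p_proc_sd: float = 0.05
    simple_span_mean: float = 7.0
    simple_span_sd: float = 0.9
    simple_K_loading: float = 0.15  # backward spans load only weakly on K
    span_slope: float = 1.5
    reading_slope: float = 1.2
    reading_R_weight: float = 1.5   # items of reading-span ability per unit recollection

    # demographics and screening
    schooling_mean: float = 15.4
    schooling_sd: float = 2.8
    schooling_gap: float = 1.5      # control minus experimental mean, years
    school_assoc: float = 0.35      # schooling loading on verbal latents
    age_mean: float = 72.0
    age_sd: float = 6.8
    p_male: float = 0.22
    p_depressed: float = 0.02
    p_impaired: float = 0.02
    p_medication: float = 0.017
    p_absent: float = 0.033

    # retest effects (both arms, post-test)
    retest_R: float = 0.06
    retest_K: float = 0.25

    # training-induced latent shifts (experimental arm only, post-test)
    delta_R_verbal: float = 0.22
    delta_R_spatial: float = 0.26
    delta_K: float = 0.35
    delta_d_f: float = 0.0

    # adaptive-training simulation
    training_growth_per_session: float = 0.2
    include_training: bool = True

    # design / scoring options
    scale: int = 1
    rate_correction: str = "loglinear"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)

    @classmethod
    def falsification_arm(cls, delta_d_f: float = 1.4, **kwargs) -> "StudyConfig":
        """A familiarity-only latent shift (no recollection, no capacity gain).

        If the d' estimators separate the processes, this arm must show
        group x session interactions on the inclusion/global measures and
        none on the exclusion/local ones — the mirror image of the
        recollection + capacity arm.  The default shift is sized so the
        small inclusion/global forms (6 old + 6 new images) still carry a
        detectable signal at the design's sample sizes.
        """
        return cls(
            delta_R_verbal=0.0, delta_R_spatial=0.0, delta_K=0.0,
            delta_d_f=delta_d_f, **kwargs,
        )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: StudyConfig, seed: int = 0) -> pd.DataFrame:
    """Draw latent participants for both arms, screening fields included.

    Schooling differs between arms by ``schooling_gap`` and loads on the
    verbal latents with coefficient ``school_assoc``, so the
    covariate-adjusted analysis has genuine work to do.  A small fraction
    of the draw fails the eligibility screens (depression, global
    cognition, attendance, medication), emulating the handful of
    exclusions expected from a volunteer cohort of this size.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    n = 2 * config.n_per_group
    group = np.array(["EG", "CG"]).repeat(config.n_per_group)
    group = group[rng.permutation(n)]

    z_school = rng.normal(size=n)
    schooling = config.schooling_mean + config.schooling_sd * z_school
    schooling += np.where(group == "CG", 0.5, -0.5) * config.schooling_gap
    z_school = (schooling - config.schooling_mean) / config.schooling_sd

    a = config.school_assoc
    mix = np.sqrt(max(0.0, 1.0 - a * a))

    def verbal_latent(mean: float, sd: float, lo: float, hi: float | None) -> np.ndarray:
        vals = mean + sd * (a * z_school + mix * rng.normal(size=n))
        return np.clip(vals, lo, hi)

    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(1, n + 1)],
            "group": group,
            "age": np.round(rng.normal(config.age_mean, config.age_sd, n), 1),
            "gender": np.where(rng.random(n) < config.p_male, "male", "female"),
            "schooling_years": np.round(np.clip(schooling, 4.0, None), 1),
            "memory_complaints": np.round(np.clip(rng.normal(3.8, 1.8, n), 0, 10), 1),
            "R_verbal": verbal_latent(config.R_mean, config.R_sd, 0.02, 0.95),
            "R_spatial": np.clip(
                rng.normal(config.R_mean, config.R_sd, n), 0.02, 0.95
            ),
            "d_f_verbal": verbal_latent(config.d_f_verbal_mean, config.d_f_sd, 0.05, None),
            "d_f_spatial": np.clip(
                rng.normal(config.d_f_spatial_mean, config.d_f_sd, n), 0.05, None
            ),
            "c": rng.normal(config.c_mean, config.c_sd, n),
            "K": np.clip(rng.normal(config.K_mean, config.K_sd, n), 1.5, None),
            "p_proc": np.clip(
                rng.normal(config.p_proc_mean, config.p_proc_sd, n), 0.5, 1.0
            ),
            "simple_digit": rng.normal(config.simple_span_mean, config.simple_span_sd, n),
            "simple_spatial": rng.normal(config.simple_span_mean, config.simple_span_sd, n),
        }
    )

    # screening fields; a small tail screens positive on each instrument
    gds = np.clip(np.round(rng.normal(2.5, 1.8, n)), 0, 9)
    depressed = rng.random(n) < config.p_depressed
    gds[depressed] = rng.integers(10, 16, depressed.sum())
    mmse = np.clip(np.round(rng.normal(28.0, 1.3, n)), 24, 30)
    impaired = rng.random(n) < config.p_impaired
    mmse[impaired] = rng.integers(18, 24, impaired.sum())
    missed = rng.choice([0, 1, 2], size=n, p=[0.75, 0.18, 0.07])
    absent = rng.random(n) < config.p_absent
    missed[absent] = rng.integers(3, 6, absent.sum())
    cohort["gds"] = gds.astype(int)
    cohort["mmse"] = mmse.astype(int)
    cohort["sessions_missed"] = missed.astype(int)
    cohort["cognition_medication"] = rng.random(n) < config.p_medication
    return cohort


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def _scale_form(form: design.RecognitionForm, scale: int) -> design.RecognitionForm:
    if scale == 1:
        return form
    items, truth, layout = [], [], []
    for rep in range(scale):
        items += [f"{w}#r{rep}" for w in form.test_items]
        truth += list(form.truth)
        if form.layout is not None:
            layout += list(form.layout)
    return dataclasses.replace(
        form,
        test_items=tuple(items),
        truth=tuple(truth),
        layout=tuple(layout) if form.layout is not None else None,
    )


def _build_forms(seed: int, scale: int) -> dict[tuple[int, str], design.RecognitionForm]:
    """Both versions of both tests, frozen for the whole trial."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    lexicon = design.default_lexicon(seed=int(rng.integers(2**31)))
    forms: dict[tuple[int, str], design.RecognitionForm] = {}
    for version in (1, 2):
        _, _, incl, excl = design.build_verbal_form(
            lexicon, version=version, seed=int(rng.integers(2**31))
        )
        _, glob, loc = design.build_spatial_form(
            design.default_image_pool(version), version=version,
            seed=int(rng.integers(2**31)),
        )
        for f in (incl, excl, glob, loc):
            forms[(version, f.condition)] = _scale_form(f, scale)
    return forms


def _session_params(
    row: pd.Series, session: str, modality: str, config: StudyConfig
) -> dualprocess.DualProcessParams:
    """Latent dual-process parameters of one participant at one session."""
    R = row[f"R_{modality}"]
    d_f = row[f"d_f_{modality}"]
    if session == "post":
        R = R + config.retest_R
        if row["group"] == "EG":
            R = R + getattr(config, f"delta_R_{modality}")
            d_f = d_f + config.delta_d_f
    return dualprocess.DualProcessParams(
        R=float(np.clip(R, 0.0, 1.0)), d_f=float(max(d_f, 0.0)), c=float(row["c"])
    )


def _span_abilities(latents: pd.DataFrame, session: str, config: StudyConfig) -> pd.DataFrame:
    """Effective span abilities (items) per participant for one session."""
    K = latents["K"].to_numpy(float).copy()
    R_v = latents["R_verbal"].to_numpy(float).copy()
    if session == "post":
        K += config.retest_K
        eg = (latents["group"] == "EG").to_numpy()
        K[eg] += config.delta_K
        R_v[eg] += config.delta_R_verbal
        R_v += config.retest_R
    reading = K + config.reading_R_weight * (R_v - config.R_mean)
    digit = config.simple_K_loading * (K - config.K_mean) + latents["simple_digit"].to_numpy(float)
    spatial = config.simple_K_loading * (K - config.K_mean) + latents["simple_spatial"].to_numpy(float)
    return pd.DataFrame(
        {"reading_span": reading, "digit_span": digit, "spatial_span": spatial},
        index=latents.index,
    )


def _simulate_protocols(
    latents: pd.DataFrame, session: str, config: StudyConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Span protocols for every participant at one session (vectorised)."""
    abilities = _span_abilities(latents, session, config)
    frames = []
    for task, sizes, slope in (
        ("reading_span", READING_SPAN_SIZES, config.reading_slope),
        ("digit_span", SIMPLE_SPAN_SIZES, config.span_slope),
        ("spatial_span", SIMPLE_SPAN_SIZES, config.span_slope),
    ):
        ability = abilities[task].to_numpy()
        for set_size in sizes:
            p_item = 1.0 / (1.0 + np.exp(-(ability - set_size) / slope))
            for _ in range(TRIALS_PER_SPAN_LEVEL):
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": latents["participant_id"].to_numpy(),
                            "session": session,
                            "task": task,
                            "set_size": set_size,
                            "n_recalled": rng.binomial(set_size, p_item),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def span_task_measures(
    cohort: pd.DataFrame, config: StudyConfig, seed: int = 0, session: str = "pre"
) -> pd.DataFrame:
    """Partial-credit reading/digit/spatial span scores for one session."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    protocols = _simulate_protocols(cohort, session, config, rng)
    return scoring.score_spans(protocols)


def _cg_training_log(
    model: training.SpanParticipantModel,
    participant_id: object,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pseudo-training log of a control participant.

    The control tasks ramp on a fixed schedule common to all participants
    (non-adaptive) and never update latent parameters; trial outcomes are
    still simulated so the log is structurally complete.
    """
    rows = []
    for session in range(1, training.N_SESSIONS + 1):
        level = min(training.START_LEVEL + (session - 1) // 2, 6)
        for task in training.TASKS:
            for block in range(1, training.N_BLOCKS + 1):
                results = [
                    training.simulate_trial(model, level, level, rng, task=task)
                    for _ in range(training.TRIALS_PER_BLOCK)
                ]
                n_correct = sum(r for r, _ in results)
                block_proc = float(np.mean([p for _, p in results]))
                for trial, (recall, proc) in enumerate(results, start=1):
                    rows.append(
                        {
                            "participant_id": participant_id,
                            "session": session,
                            "task": task,
                            "block": block,
                            "trial": trial,
                            "level": level,
                            "recall_correct": recall,
                            "proc_accuracy": proc,
                            "block_recall_correct": n_correct,
                            "block_proc_accuracy": block_proc,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_trial_run(
    cohort: pd.DataFrame,
    config: StudyConfig,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the whole synthetic trial on a generated cohort.

    Applies the eligibility screens, freezes both versions of both
    recognition tests, counterbalances version order, simulates pre- and
    post-test recognition responses and span protocols from the latent
    parameters (with the experimental arm's post-test latents shifted by
    the configured deltas), optionally simulates the ten training
    sessions, and scores everything.

    Returns a dict of long-format frames: ``participants`` (retained,
    with version assignment), ``excluded`` (with reasons), ``trials``,
    ``span_protocols``, ``training_log`` and ``scores``.
    """
    if not len(cohort):
        raise ValueError("cohort is empty")
    retained, excluded = inference.apply_eligibility(cohort)
    retained = retained.reset_index(drop=True)

    forms = _build_forms(seed, config.scale)
    versions = design.counterbalance_versions(
        retained["participant_id"].tolist(),
        seed=int(np.random.default_rng(np.random.SeedSequence([seed, 2])).integers(2**31)),
    )
    rng_resp = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    rng_span = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rng_train = np.random.default_rng(np.random.SeedSequence([seed, 5]))

    trial_frames = []
    for _, row in retained.iterrows():
        pid = row["participant_id"]
        pre_version, post_version = versions[pid]
        for session, version in (("pre", pre_version), ("post", post_version)):
            for modality, conditions in (
                ("verbal", ("inclusion", "exclusion")),
                ("spatial", ("global", "local")),
            ):
                params = _session_params(
                    row, session, modality, config
                )
                for cond in conditions:
                    trial_frames.append(
                        dualprocess.simulate_condition(
                            forms[(version, cond)], params, rng_resp,
                            participant_id=pid, session=session,
                        )
                    )
    trials = pd.concat(trial_frames, ignore_index=True)

    protocols = pd.concat(
        [
            _simulate_protocols(retained, "pre", config, rng_span),
            _simulate_protocols(retained, "post", config, rng_span),
        ],
        ignore_index=True,
    )

    if config.include_training:
        logs = []
        for _, row in retained.iterrows():
            model = training.SpanParticipantModel(
                K=float(row["K"]), p_proc=float(row["p_proc"])
            )
            if row["group"] == "EG":
                logs.append(
                    training.run_training(
                        model,
                        seed=int(rng_train.integers(2**31)),
                        growth_per_session=config.training_growth_per_session,
                        participant_id=row["participant_id"],
                    )
                )
            else:
                logs.append(
                    _cg_training_log(model, row["participant_id"], rng_train)
                )
        training_log = pd.concat(logs, ignore_index=True)
    else:
        training_log = pd.DataFrame(
            columns=[
                "participant_id", "session", "task", "block", "trial", "level",
                "recall_correct", "proc_accuracy", "block_recall_correct",
                "block_proc_accuracy",
            ]
        )

    scores = scoring.score_study(trials, protocols, correction=config.rate_correction)
    scores = scores.merge(retained[["participant_id", "group"]], on="participant_id")
    scores = scores[["participant_id", "group", "session", "measure", "score"]]

    participants = retained.copy()
    participants["pretest_version"] = [versions[p][0] for p in participants["participant_id"]]
    participants["posttest_version"] = [versions[p][1] for p in participants["participant_id"]]

    return {
        "participants": participants,
        "excluded": excluded,
        "trials": trials,
        "span_protocols": protocols,
        "training_log": training_log,
        "scores": scores,
        "forms": design.forms_to_frame(forms.values()),
    }


# ---------------------------------------------------------------------------
# Analysis and replication helpers
# ---------------------------------------------------------------------------

def analyze_study(
    scores: pd.DataFrame,
    participants: pd.DataFrame,
    covariate: str = "schooling_years",
    run_ancova: bool = True,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-measure mixed ANOVAs, covariate-adjusted tests and effect sizes.

    Returns ``{"anova": ..., "ancova": ..., "effect_sizes": ...}`` tidy
    frames.  Effect sizes are Hedges-corrected pre/post d per group
    (pooled-SD convention).
    """
    if "group" not in scores.columns:
        scores = scores.merge(
            participants[["participant_id", "group"]], on="participant_id"
        )
    anova_rows, ancova_rows, es_rows = [], [], []
    cov = (
        participants.set_index("participant_id")[covariate]
        if run_ancova and covariate in participants
        else None
    )
    for measure, data in scores.groupby("measure"):
        results = inference.mixed_anova_2x2(data)
        for eff, r in results.items():
            anova_rows.append(
                {"measure": measure, "effect": eff, "F": r.F, "df1": r.df1,
                 "df2": r.df2, "p": r.p, "eta_p2": r.eta_p2,
                 "significant": r.p < alpha}
            )
        if cov is not None:
            r = inference.ancova_change(data, cov)
            ancova_rows.append(
                {"measure": measure, "covariate": covariate, "F": r.F,
                 "df1": r.df1, "df2": r.df2, "p": r.p, "eta_p2": r.eta_p2,
                 "significant": r.p < alpha}
            )
        wide = data.pivot_table(
            index=["participant_id", "group"], columns="session", values="score"
        ).reset_index()
        for grp, g in wide.groupby("group"):
            es = inference.hedges_d(g["pre"], g["post"])
            es_rows.append(
                {"measure": measure, "group": grp, "d_hedges": es.d, "J": es.J,
                 "n": len(g), "convention": es.convention}
            )
    return {
        "anova": pd.DataFrame(anova_rows),
        "ancova": pd.DataFrame(ancova_rows),
        "effect_sizes": pd.DataFrame(es_rows),
    }


def replicate_interaction_rates(
    config: StudyConfig,
    n_reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group x session interaction rejection rates over seeded replications.

    Re-runs the full pipeline (recognition + spans; training logs are
    skipped as they do not feed the transfer measures) ``n_reps`` times
    and reports, per measure, the fraction of replications whose
    interaction test rejects at ``alpha``.
    """
    cfg = dataclasses.replace(config, include_training=False)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    hits: dict[str, int] = {m: 0 for m in MEASURES}
    for rep_seed in seeds:
        cohort = generate_cohort(cfg, int(rep_seed))
        run = simulate_trial_run(cohort, cfg, int(rep_seed))
        for measure, data in run["scores"].groupby("measure"):
            r = inference.mixed_anova_2x2(data)["interaction"]
            if r.p < alpha:
                hits[measure] += 1
    return pd.DataFrame(
        {
            "measure": list(hits),
            "rejection_rate": [hits[m] / n_reps for m in hits],
            "n_reps": n_reps,
        }
    )
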