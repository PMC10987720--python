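# Methods

This note documents the models, estimators and design choices behind
`wmtransfer`, in the order the pipeline runs.

## The design being simulated

A two-arm randomized pre/post trial of working-memory training in older
adults. The experimental group (EG) trains adaptively on seven complex
span tasks over ten sessions; the active control group (CG) performs
non-adaptive pseudo-training. Before and after training, both arms take
two recognition tests (verbal and visuospatial), each with a condition
pair that dissociates memory processes, and three span tests (complex
reading span, backward digit and spatial spans). The scientific question
the design answers is *which* shared cognitive resource carries
transfer: if training improves controlled retrieval (recollection), the
gains should appear only on measures that require it.

## Recognition forms

The verbal test pairs two 18-word study lists (12 targets in three
semantic categories, 4 per category, plus 6 fillers occupying the three
leading and trailing positions to absorb primacy/recency) with two
27-item recognition conditions: *inclusion* (6 list-A + 6 list-B +
15 new; "yes" to any studied word) and *exclusion* (same composition;
"yes" only to list-A words, making list-B words intrusion lures). The
two lists share exactly one category. Words are selected inside
lexical-availability bands — per category one target above index 25 and
three in [10, 25], fillers above 25, unstudied lures below 10 so
spontaneous false recognition stays rare — after dropping each
category's three most available words. The two conditions use disjoint
halves of the targets and disjoint new words, which is the only
partition consistent with 12 targets per list and 6 tested per list per
condition.

The visuospatial test pairs a 20-image study set (16 targets, exactly 4
per quadrant of the sheet; 4 fillers at positions 1, 2, 19, 20) with a
12-item *global* condition (6 old + 6 new, centred — context
irrelevant) and a 14-item *local* condition (6 old in their study
quadrant, 4 old displaced to a different quadrant, 4 new — context is
the question). The 16 targets are partitioned 6/6/4 across the
conditions so no target is tested twice.

Each form is materialised once per version from a seed and frozen:
every participant receives byte-identical item orders. Two parallel
versions exist per test, and version order over pre/post is
counterbalanced across participants as evenly as possible.

The synthetic lexicon draws availability indices from a log-normal
(mu = 2.7, sigma = 1.0) per category, 80 words per category; only the
band structure matters downstream, and this choice populates all three
bands with comfortable margins for every seed. The drop-the-top-3 step
preserves the shape of the real selection pipeline even though the
synthetic indices are arbitrary.

## Dual-process generative model

Responses arise from two independent processes:

* recollection retrieves item + context with probability `R` and is the
  only process that can *correctly reject* a studied-but-wrong-context
  lure;
* familiarity is an equal-variance Gaussian signal, `N(d_f, 1)` for
  studied and `N(0, 1)` for unstudied items, compared to criterion `c`.

In inclusive conditions a recollected studied item is accepted; in
exclusive conditions a recollected intrusion lure is rejected, while an
unrecollected one can still be accepted through familiarity. Closed
forms (exclusive conditions):

    P(hit)          = R + (1 - R) Phi(d_f - c)
    P(intrusion FA) =     (1 - R) Phi(d_f - c)
    P(new FA)       = Phi(-c)

The equal-variance Gaussian choice is the minimal signal-detection
model compatible with d′-based scoring. No generative equations exist
in the source literature for this exact design — only the estimators —
so this formalisation is the package's own; a high-threshold familiarity
model would change the expected rates but not the estimator code. The
same `R` governs list-A and list-B context links (one recollection
construct per modality), and recollection/familiarity independence is
the classical process-dissociation assumption.

## Adaptive training

Each task runs 5 blocks x 3 trials per session, starting every session
at 2 recall items. Between blocks: 3/3 lists recalled *and* >= 80%
processing accuracy -> level +1; 3/3 but processing < 80% -> hold; 0/3
-> level -1 (floored); 1-2/3 -> hold. Processing accuracy is pooled
over the block's three trials, matching feedback that is evaluated "at
the end of each block"; per-block (not cumulative) evaluation is
assumed. The floor equals the start level 2 — a one-item serial list is
degenerate and no explicit minimum is documented — and there is no
ceiling. One processing item accompanies each serial item, so a
level-k trial carries k processing items.

The simulated trainee recalls a whole list with probability
`logistic((K - level) / slope)` (default slope 0.75 items) and solves
each processing item with probability `p_proc` (default 0.90). This
makes the staircase equilibrate near `K`: with K = 4 the long-run
median block level stays within one item of 4. The seven tasks are
exchangeable up to an optional per-task difficulty offset (default 0);
task content differences are presentation-level. The trial-sequence
detail that the processing task always comes last is recorded as a
design flag (`PROCESSING_TASK_LAST`), not simulated. Control
pseudo-training ramps difficulty on a fixed schedule common to all
participants and never touches latent parameters.

Training gains are assessed between sessions 2 and 10 with paired
t-tests per task, per modality and overall, standardised by the
change-score convention (mean gain / SD of gains, times Hedges' J) —
the convention consistent with per-task training statistics — with a
Bonferroni threshold alpha/7 for the seven tasks.

## Scoring

Recognition: `d'(n) = z(H) - z(FA_new)` for inclusion/global,
`d'(i) = z(H) - z(FA_intrusion)` for exclusion/local. Because intrusion
lures are studied, their familiarity matches the targets', so at R = 0
the expected hit and intrusion-FA rates coincide and the expected d'(i)
is exactly 0 for *any* familiarity strength — the estimator's
recollection specificity. d'(n) responds to familiarity alone. With R
strictly positive a familiarity shift does leak into d'(i) slightly
(the z transform is nonlinear), which is the known imperfection of
d′-based process dissociation; the falsification experiments quantify
it.

Rates are corrected log-linearly, `(count + 0.5) / (n + 1)`, before the
quantile transform. The small real denominators (6 targets, 4–6
intrusion lures) make rates of 0 or 1 common — the verbal test runs
near ceiling by design — and the correction keeps every score finite
while preserving the midpoint. The raw proportion is available by
configuration and every score row records which correction produced it.
For the local condition the intrusion denominator is the 4 displaced-old
items.

Span tests use the partial-credit unit score: each level contributes
`recalled / set_size` irrespective of order, and the final score is the
mean over level-trials, bounded in [0, 1]. Reading span uses set sizes
2–6, the backward spans 2–7, two trials per level.

## Inference

The 2 x 2 mixed ANOVA is computed in closed form. With two occasions
the design decomposes exactly: the between stratum is a one-way ANOVA
on subject means (doubled), and the within stratum is carried by change
scores `c = post - pre`, where the interaction F equals the squared
pooled-variance two-sample t on `c` — an identity the test suite checks
to 1e-10 against an independent t-test, alongside a cross-check against
an established mixed-ANOVA implementation. The session effect is
evaluated at the unweighted mean of the group change means (Type-III
convention) so it stays orthogonal to the interaction under group-size
imbalance. Partial eta squared is `SS_eff / (SS_eff + SS_err)`. A
zero-error-SS stratum returns F = inf (p = 0) when the effect SS is
positive and F = 0 (p = 1) when it is not.

The covariate-adjusted analysis is an OLS ANCOVA on change scores,
`c ~ group + centered covariate`, equivalent in a two-occasion design
to the covariate-adjusted interaction; a detailed repeated-measures
ANCOVA parameterisation is not better identified by the design, and the
change-score form makes the estimand explicit.

Pre/post effect sizes use Cohen's d standardised by the pooled SD of
pre and post scores, times Hedges' `J = 1 - 3/(4 df - 1)` with
`df = n - 1`; the change-score denominator is available by option,
since published reports are frequently ambiguous between the two
conventions (training-gain statistics, by contrast, use the
change-score convention; see above).

Eligibility screening excludes participants with depression screen
score > 9, global-cognition screen score < 24, more than 2 missed
sessions, or medication affecting cognition; boundaries retain (9, 24
and 2 all pass) and every exclusion is labelled with the rules it
triggered.

## Synthetic cohort and what the defaults mean

Sixty participants are drawn (30 per arm) and screened, leaving about
55 analysable — the scale of a realistic single-site trial of this
kind. Latents: `R ~ N(0.25, 0.12)` clipped to [0.02, 0.95] per
modality; `d_f_verbal ~ N(1.3, 0.25)` (the verbal test is intentionally
near ceiling), `d_f_spatial ~ N(1.1, 0.25)`; `c ~ N(0.5, 0.2)`;
`K ~ N(4.0, 0.8)` clipped at 1.5 items; backward-span abilities
`~ N(7.0, 0.9)` with a weak capacity loading (0.15), so simple spans
share little trained variance by construction. Schooling is
`N(15.4, 2.8)` years with a 1.5-year control-arm advantage and loads on
the verbal latents with coefficient 0.35, giving the covariate-adjusted
analysis genuine work.

Training transfer enters as a post-test latent shift of the
experimental arm — recollection `+0.22` (verbal) / `+0.26` (spatial)
and capacity `+0.35` items, familiarity unchanged — plus a small retest
effect common to both arms (`R +0.06`, `K +0.25`). The deltas were
fixed by simulation so the experimental arm's Hedges d on the
recollection-specific measures and reading span lands in the
large-effect range (≈0.9–1.1); the true latent shifts behind published
standardised effects are not identifiable, so these defaults are
tuning, not estimation. The spatial shift exceeds the verbal one
because the local form's 10 + 4 items carry more binomial noise per
unit of latent change. The standard falsification configuration
(`StudyConfig.falsification_arm()`) moves only familiarity, by +1.4
evidence units — sized so the 12-item global form still carries a
detectable signal — and must reverse the recognition pattern if the
estimators separate the processes.

Training logs are simulated with a capacity growth of 0.2 items per
session for the experimental arm, so session-2 vs session-10 contrasts
show the large standardised gains typical of adaptive training;
transfer itself is *not* derived from these logs (no mechanistic growth
claim is made by the design).

`scale` multiplies every truth-class count on every form for precision
studies (parameter recovery uses scale 6); real form sizes make
single-participant d′ estimates noisy, which is honest to the design
being emulated.

## What the generator does and does not emulate

It emulates: the two-arm pre/post structure with realistic sample
sizes, trial-level yes/no responses from a recollection + familiarity
process, span-limited adaptive-training behaviour, screening
exclusions, a schooling imbalance correlated with verbal performance,
and retest effects. It does not emulate: serial-position effects,
fatigue or condition-order effects (condition order is fixed and
recorded as metadata only), strategy learning, dropout beyond the
stated exclusion rules, remember/know judgments, unequal-variance
familiarity, or any fitting of the latent population to a published
sample's means. Passing tests therefore certify the machinery —
estimator specificity, staircase behaviour, test calibration, pattern
recovery under known ground truth — not any claim about real
participants.

## Numerical choices and problem sizes

* Monte-Carlo validations use 10^4–10^5 draws per parameter point with
  3-standard-error agreement bands.
* The ANOVA identity is checked on 100 random datasets at 1e-10; null
  calibration of the interaction test uses 1,000 replications at the
  trial's group sizes (27/28), tolerance ±1.5 points around 5%; the
  full-pipeline null calibration uses 120 replications pooled over the
  seven measures.
* Qualitative pattern recovery runs 200 full-pipeline replications per
  arm.
* All randomness flows from numpy `SeedSequence`; the pipeline derives
  per-stage seeds from one master seed by a fixed counter scheme, so a
  run is reproducible to the byte.

## Known limitations

* The d′-based recollection estimate is only asymptotically null under
  familiarity-only change at R > 0 (z-nonlinearity leakage); algebraic
  process-dissociation estimators (R = I − E style) are deliberately
  out of scope.
* The 2 x 2 closed-form ANOVA does not generalise to more occasions or
  arms; that is the contract, not an accident.
* Availability indices, category labels and image ids are synthetic
  stand-ins; nothing lexical is modelled beyond the band structure.
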