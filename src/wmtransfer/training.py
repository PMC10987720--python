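"""Adaptive complex-span training: staircase scheduler and simulated trainee.

Seven complex-span tasks (four verbal, three visuospatial) are trained
over ten sessions.  Each task runs five blocks of three trials per
session; every task starts every session at a difficulty of two recall
items.  After each block the scheduler inspects the block's serial
recall and processing accuracy:

* all 3 trials recalled correctly *and* >= 80% of processing items
  correct -> difficulty + 1;
* all 3 correct but processing < 80% -> difficulty unchanged;
* 0 of 3 correct -> difficulty - 1 (never below the floor);
* 1 or 2 correct -> difficulty unchanged.

The simulated trainee is a span-limited responder: serial recall of a
whole list succeeds with probability ``sigmoid((K - level) / slope)``
(so the staircase equilibrates near the latent capacity ``K``), and each
interleaved processing item is solved independently with probability
``p_proc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TASKS",
    "VERBAL_TASKS",
    "SPATIAL_TASKS",
    "START_LEVEL",
    "LEVEL_FLOOR",
    "N_BLOCKS",
    "TRIALS_PER_BLOCK",
    "PROCESSING_CRITERION",
    "SpanParticipantModel",
    "next_level",
    "simulate_trial",
    "run_session",
    "run_training",
    "session_gain",
]

VERBAL_TASKS = ("counting_span", "digit_span", "operation_span", "lexical_span")
SPATIAL_TASKS = ("matrix_span", "alignment_span", "rotation_span")
TASKS = VERBAL_TASKS + SPATIAL_TASKS

START_LEVEL = 2
#: The floor equals the start level: a one-item "serial" list is degenerate
#: and the start level is the only anchor for a minimum.
LEVEL_FLOOR = 2
N_BLOCKS = 5
TRIALS_PER_BLOCK = 3
PROCESSING_CRITERION = 0.80
N_SESSIONS = 10

#: The last event of every trial is the processing task, so the final serial
#: item cannot linger in primary memory.  Recorded as a design flag; the
#: simulated trainee does not model it mechanistically.
PROCESSING_TASK_LAST = True


@dataclass(frozen=True)
class SpanParticipantModel:
    """Latent description of a simulated trainee.

    Parameters
    ----------
    K
        Span capacity in items: the list length at which whole-list serial
        recall succeeds half the time.
    slope
        Steepness of the logistic recall psychometric (items); smaller is
        steeper.
    p_proc
        Per-item accuracy on the interleaved processing task.
    task_offsets
        Optional per-task difficulty offsets added to the effective level
        (positive = harder); defaults to all tasks exchangeable.
    """

    K: float
    slope: float = 0.75
    p_proc: float = 0.90
    task_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not 0.0 <= self.p_proc <= 1.0:
            raise ValueError(f"p_proc must be in [0, 1], got {self.p_proc}")


def next_level(
    current_level: int,
    block_recall_correct: int,
    block_proc_accuracy: float,
    floor: int = LEVEL_FLOOR,
) -> int:
    """Staircase update applied between blocks.

    ``block_recall_correct`` counts trials (0-3) of the finished block in
    which the whole list was recalled in order; ``block_proc_accuracy`` is
    the block's pooled proportion of correct processing items.
    """
    if not 0 <= block_recall_correct <= TRIALS_PER_BLOCK:
        raise ValueError(f"recall count must be 0..{TRIALS_PER_BLOCK}")
    if not 0.0 <= block_proc_accuracy <= 1.0:
        raise ValueError("processing accuracy must be in [0, 1]")
    if block_recall_correct == TRIALS_PER_BLOCK:
        if block_proc_accuracy >= PROCESSING_CRITERION:
            return current_level + 1
        return current_level
    if block_recall_correct == 0:
        return max(current_level - 1, floor)
    return current_level


def simulate_trial(
    model: SpanParticipantModel,
    level: int,
    n_proc_items: int,
    rng: np.random.Generator,
    task: str | None = None,
) -> tuple[bool, float]:
    """Simulate one complex-span trial at a given difficulty level.

    Returns ``(recall_correct, proc_accuracy)``: whole-list serial recall
    succeeds with probability ``sigmoid((K - level) / slope)`` and the
    processing score is a binomial proportion over ``n_proc_items``.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if n_proc_items < 1:
        raise ValueError("n_proc_items must be >= 1")
    offset = model.task_offsets.get(task, 0.0) if task else 0.0
    x = (model.K - level - offset) / model.slope
    p_recall = 1.0 / (1.0 + np.exp(-x)) if x > -500 else 0.0
    recall_correct = bool(rng.random() < p_recall)
    proc_accuracy = rng.binomial(n_proc_items, model.p_proc) / n_proc_items
    return recall_correct, proc_accuracy


def run_session(
    model: SpanParticipantModel,
    session_index: int,
    seed: int | np.random.Generator = 0,
    tasks: tuple[str, ...] = TASKS,
    participant_id: object = 0,
) -> pd.DataFrame:
    """Run one full training session (all tasks, 5 blocks x 3 trials each).

    The first block of every task starts at the fixed start level; between
    blocks the level follows :func:`next_level`.  Each trial interleaves
    one processing item per serial item, so ``n_proc_items`` equals the
    current level.  Returns a long-format log, one row per trial, carrying
    the per-block feedback quantities (trials recalled, pooled processing
    accuracy) on each row of the block.
    """
    if not 1 <= session_index <= N_SESSIONS:
        raise ValueError(f"session_index must be 1..{N_SESSIONS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for task in tasks:
        level = START_LEVEL
        for block in range(1, N_BLOCKS + 1):
            results = [
                simulate_trial(model, level, n_proc_items=level, rng=rng, task=task)
                for _ in range(TRIALS_PER_BLOCK)
            ]
            n_correct = sum(r for r, _ in results)
            # feedback pools processing items over the block's three trials
            block_proc = float(np.mean([p for _, p in results]))
            for trial, (recall, proc) in enumerate(results, start=1):
                rows.append(
                    {
                        "participant_id": participant_id,
                        "session": session_index,
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
            level = next_level(level, n_correct, block_proc)
    return pd.DataFrame(rows)


def run_training(
    model: SpanParticipantModel,
    n_sessions: int = N_SESSIONS,
    seed: int = 0,
    growth_per_session: float = 0.0,
    tasks: tuple[str, ...] = TASKS,
    participant_id: object = 0,
) -> pd.DataFrame:
    """Run a full training course, optionally growing capacity across sessions.

    ``growth_per_session`` adds that many items to ``K`` per elapsed
    session (session s uses ``K + growth * (s - 1)``), emulating a trainee
    who improves over the course.
    """
    rng = np.random.default_rng(seed)
    logs = []
    for s in range(1, n_sessions + 1):
        m = SpanParticipantModel(
            K=model.K + growth_per_session * (s - 1),
            slope=model.slope,
            p_proc=model.p_proc,
            task_offsets=model.task_offsets,
        )
        logs.append(run_session(m, s, rng, tasks=tasks, participant_id=participant_id))
    return pd.concat(logs, ignore_index=True)


def _hedges_j(df: int) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def session_gain(
    logs: pd.DataFrame,
    early_session: int = 2,
    late_session: int = 10,
    alpha: float = 0.05,
    n_comparisons: int = len(TASKS),
) -> pd.DataFrame:
    """Training gains between an early and a late session.

    For every participant the mean achieved level per task per session is
    computed; gains (late - early) are tested with paired t-tests per
    task, per modality (verbal / visuospatial) and overall, with a
    Hedges-corrected standardised gain (change-score convention,
    d = mean(gain) / sd(gain) * J, df = n - 1) and a Bonferroni
    significance threshold ``alpha / n_comparisons``.

    Raises
    ------
    ValueError
        If a participant lacks either session.
    """
    need = {early_session, late_session}
    for pid, grp in logs.groupby("participant_id"):
        missing = need - set(grp["session"].unique())
        if missing:
            raise ValueError(
                f"participant {pid!r} is missing session(s) {sorted(missing)}"
            )
    sub = logs[logs["session"].isin(need)]
    means = (
        sub.groupby(["participant_id", "task", "session"])["level"]
        .mean()
        .unstack("session")
    )
    gains = (means[late_session] - means[early_session]).rename("gain").reset_index()

    scopes: dict[str, pd.DataFrame] = {t: gains[gains["task"] == t] for t in TASKS}
    scopes["verbal"] = gains[gains["task"].isin(VERBAL_TASKS)]
    scopes["visuospatial"] = gains[gains["task"].isin(SPATIAL_TASKS)]
    scopes["all"] = gains

    threshold = alpha / n_comparisons
    rows = []
    for scope, grp in scopes.items():
        per_part = grp.groupby("participant_id")["gain"].mean()
        n = len(per_part)
        mean_gain = float(per_part.mean()) if n else float("nan")
        if n >= 2 and per_part.std(ddof=1) > 0:
            # paired t on (late, early) levels == one-sample t on the gains
            t, p = stats.ttest_1samp(per_part.to_numpy(), 0.0)
            d = mean_gain / float(per_part.std(ddof=1)) * _hedges_j(n - 1)
            degenerate = False
        else:
            t, p, d = float("nan"), float("nan"), float("nan")
            degenerate = True
        rows.append(
            {
                "scope": scope,
                "n": n,
                "mean_gain": mean_gain,
                "t": float(t),
                "df": n - 1,
                "p": float(p),
                "d_hedges": d,
                "alpha_corrected": threshold,
                "significant": bool(p < threshold) if not degenerate else False,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
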