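"""Outcome measures: signal-detection sensitivities and span scores.

Recognition performance is summarised by two inverse-normal contrasts:

* ``d'(n) = z(hit rate) - z(false-alarm rate)`` in the inclusion/global
  condition — a sensitivity estimate to which both recollection and
  familiarity contribute;
* ``d'(i) = z(hit rate) - z(intrusion false-alarm rate)`` in the
  exclusion/local condition — because intrusion lures are studied items,
  their familiarity matches that of targets, and the contrast isolates
  the recollection contribution.

Extreme rates (0 or 1) would make the quantile infinite with the small
denominators of real forms (6 targets, 4-6 intrusion lures), so rates
are log-linearly corrected by default: ``(count + 0.5) / (n + 1)``.  The
raw proportion remains available by configuration and the choice is
recorded in every score.

Span protocols are scored with the partial-credit unit convention: each
difficulty level counts as one unit and contributes the proportion of
its items recalled, irrespective of order; the final score is the mean
over levels and ranges from 0 to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dualprocess import EXCLUSIVE_CONDITIONS, INCLUSIVE_CONDITIONS

__all__ = [
    "RateTable",
    "DPrimeScores",
    "SpanProtocol",
    "tabulate_rates",
    "corrected_rate",
    "dprime",
    "partial_credit_score",
    "score_recognition",
    "score_spans",
    "score_study",
]


@dataclass(frozen=True)
class RateTable:
    """Response counts for one participant x condition x session."""

    n_hits: int
    n_targets: int
    n_fa: int
    n_new_lures: int
    n_intrusion_fa: int = 0
    n_intrusion_lures: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_hits", "n_targets", "n_fa", "n_new_lures",
            "n_intrusion_fa", "n_intrusion_lures",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_hits > self.n_targets:
            raise ValueError("n_hits cannot exceed n_targets")
        if self.n_fa > self.n_new_lures:
            raise ValueError("n_fa cannot exceed n_new_lures")
        if self.n_intrusion_fa > self.n_intrusion_lures:
            raise ValueError("n_intrusion_fa cannot exceed n_intrusion_lures")


@dataclass(frozen=True)
class DPrimeScores:
    """Sensitivity estimates; the inapplicable one is ``None``."""

    d_n: float | None
    d_i: float | None
    correction_used: str


@dataclass(frozen=True)
class SpanProtocol:
    """Sequence of (set_size, n_recalled) pairs for one span test."""

    levels: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for set_size, n_recalled in self.levels:
            if set_size < 1:
                raise ValueError("set_size must be >= 1")
            if not 0 <= n_recalled <= set_size:
                raise ValueError("n_recalled must be in [0, set_size]")


def tabulate_rates(responses: pd.DataFrame, condition: str | None = None) -> RateTable:
    """Count hits and false alarms from trial-level responses.

    ``responses`` must cover exactly one participant x session x
    condition; denominators come from the truth labels (form
    composition).  "Yes" to a target is a hit, to a new lure a false
    alarm, to an intrusion lure an intrusion false alarm.
    """
    for col in ("participant_id", "session", "condition"):
        if col in responses and responses[col].nunique() > 1:
            raise ValueError(f"responses mix several values of {col!r}")
    if condition is not None:
        found = responses["condition"].iloc[0]
        if found != condition:
            raise ValueError(f"expected condition {condition!r}, found {found!r}")
    cond = responses["condition"].iloc[0]
    yes = responses["response"] == "yes"
    truth = responses["truth"]
    counts = {
        "n_hits": int((yes & (truth == "target")).sum()),
        "n_targets": int((truth == "target").sum()),
        "n_fa": int((yes & (truth == "new_lure")).sum()),
        "n_new_lures": int((truth == "new_lure").sum()),
        "n_intrusion_fa": int((yes & (truth == "intrusion_lure")).sum()),
        "n_intrusion_lures": int((truth == "intrusion_lure").sum()),
    }
    if cond in INCLUSIVE_CONDITIONS and counts["n_intrusion_lures"]:
        raise ValueError(f"{cond!r} responses contain intrusion lures")
    return RateTable(**counts)


def corrected_rate(count: int, n: int, method: str = "loglinear") -> float:
    """Proportion estimate kept inside (0, 1).

    ``loglinear`` (default) returns ``(count + 0.5) / (n + 1)``, which
    preserves the midpoint and never yields 0 or 1; ``raw`` returns
    ``count / n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError("count must be in [0, n]")
    if method == "loglinear":
        return (count + 0.5) / (n + 1.0)
    if method == "raw":
        return count / n
    raise ValueError(f"unknown correction method {method!r}")


def dprime(
    rates: RateTable,
    condition: str,
    correction: str = "loglinear",
    kind: str | None = None,
) -> DPrimeScores:
    """Inverse-normal sensitivity from a rate table.

    Inclusive conditions yield ``d_n = z(H) - z(FA_new)``; exclusive ones
    yield ``d_i = z(H) - z(FA_intrusion)``.  Requesting ``kind='d_i'``
    for an inclusive condition raises (no intrusion lures exist).
    """
    if condition in INCLUSIVE_CONDITIONS:
        default_kind = "d_n"
    elif condition in EXCLUSIVE_CONDITIONS:
        default_kind = "d_i"
    else:
        raise ValueError(f"unknown condition {condition!r}")
    kind = kind or default_kind
    if kind == "d_i" and condition in INCLUSIVE_CONDITIONS:
        raise ValueError(f"d'(i) is undefined for {condition!r}: no intrusion lures")
    if kind not in ("d_n", "d_i"):
        raise ValueError(f"unknown sensitivity kind {kind!r}")

    z = stats.norm.ppf
    h = z(corrected_rate(rates.n_hits, rates.n_targets, correction))
    if kind == "d_n":
        fa = z(corrected_rate(rates.n_fa, rates.n_new_lures, correction))
        return DPrimeScores(d_n=float(h - fa), d_i=None, correction_used=correction)
    if rates.n_intrusion_lures == 0:
        raise ValueError("d'(i) requires intrusion lures in the rate table")
    fa = z(corrected_rate(rates.n_intrusion_fa, rates.n_intrusion_lures, correction))
    return DPrimeScores(d_n=None, d_i=float(h - fa), correction_used=correction)


def partial_credit_score(protocol: SpanProtocol | Sequence[tuple[int, int]]) -> float:
    """Partial-credit unit score: mean over levels of items recalled / set size.

    Order of levels is immaterial; the score is bounded in [0, 1] and
    reaches 1 only when every item of every level is recalled.
    """
    levels = protocol.levels if isinstance(protocol, SpanProtocol) else tuple(protocol)
    if not levels:
        raise ValueError("protocol has no levels")
    return float(np.mean([n_recalled / set_size for set_size, n_recalled in levels]))


# ---------------------------------------------------------------------------
# Study-level scoring (long tables in, long tables out)
# ---------------------------------------------------------------------------

#: condition -> (measure suffix, sensitivity kind)
_CONDITION_MEASURE = {
    "inclusion": ("d_n_verbal", "d_n"),
    "exclusion": ("d_i_verbal", "d_i"),
    "global": ("d_n_spatial", "d_n"),
    "local": ("d_i_spatial", "d_i"),
}

SPAN_MEASURES = ("reading_span", "digit_span", "spatial_span")
RECOGNITION_MEASURES = tuple(m for m, _ in _CONDITION_MEASURE.values())
ALL_MEASURES = RECOGNITION_MEASURES + SPAN_MEASURES


def score_recognition(trials: pd.DataFrame, correction: str = "loglinear") -> pd.DataFrame:
    """Score every participant x session x condition of a trial table.

    Vectorised over participants; the per-table route through
    :func:`tabulate_rates` and :func:`dprime` gives identical numbers and
    serves as its cross-check in the test suite.
    """
    df = trials.assign(yes=(trials["response"] == "yes").astype(int))
    agg = (
        df.groupby(["participant_id", "session", "condition", "truth"])["yes"]
        .agg(["sum", "count"])
        .unstack("truth")
    )

    def rate(truth: str) -> np.ndarray:
        count = agg[("sum", truth)].to_numpy(float)
        n = agg[("count", truth)].to_numpy(float)
        if correction == "loglinear":
            return (count + 0.5) / (n + 1.0)
        if correction == "raw":
            return count / n
        raise ValueError(f"unknown correction method {correction!r}")

    z = stats.norm.ppf
    zh = z(rate("target"))
    conditions = agg.index.get_level_values("condition")
    exclusive = np.asarray([c in EXCLUSIVE_CONDITIONS for c in conditions])
    if ("count", "intrusion_lure") in agg.columns:
        z_int = z(rate("intrusion_lure"))  # NaN where the condition has none
    else:
        z_int = np.full(len(agg), np.nan)
    z_new = z(rate("new_lure"))
    score = np.where(exclusive, zh - z_int, zh - z_new)

    out = pd.DataFrame(
        {
            "participant_id": agg.index.get_level_values("participant_id"),
            "session": agg.index.get_level_values("session"),
            "measure": [_CONDITION_MEASURE[c][0] for c in conditions],
            "score": score,
            "correction": correction,
        }
    )
    return out.reset_index(drop=True)


def score_spans(protocols: pd.DataFrame) -> pd.DataFrame:
    """Partial-credit scores from a long span-protocol table.

    Expects columns ``participant_id, session, task, set_size,
    n_recalled`` with task in ``reading_span | digit_span | spatial_span``.
    """
    rows = []
    for (pid, session, task), grp in protocols.groupby(
        ["participant_id", "session", "task"], sort=False
    ):
        protocol = SpanProtocol(
            tuple(zip(grp["set_size"].astype(int), grp["n_recalled"].astype(int)))
        )
        rows.append(
            {
                "participant_id": pid,
                "session": session,
                "measure": task,
                "score": partial_credit_score(protocol),
                "correction": "",
            }
        )
    return pd.DataFrame(rows)


def score_study(
    trials: pd.DataFrame,
    span_protocols: pd.DataFrame | None = None,
    correction: str = "loglinear",
) -> pd.DataFrame:
    """All outcome measures, one row per participant x session x measure."""
    parts = [score_recognition(trials, correction=correction)]
    if span_protocols is not None and len(span_protocols):
        parts.append(score_spans(span_protocols))
    return pd.concat(parts, ignore_index=True)
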