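"""Generative dual-process model of yes/no recognition responses.

Recognition is modelled as the race of two processes, following the
process-dissociation logic of inclusion/exclusion (and global/local)
test conditions:

* **Recollection** retrieves an item together with its encoding context
  (which list, which quadrant) with probability ``R``.  It is the only
  process that can support correct responding when the context matters.
* **Familiarity** is a context-free strength signal: an equal-variance
  Gaussian evidence variable, ``Normal(d_f, 1)`` for studied items and
  ``Normal(0, 1)`` for unstudied ones, compared against a criterion
  ``c``.

The two processes are independent (Jacoby's independence assumption).
In *inclusive* conditions (inclusion, global) any studied item warrants
"yes", so recollection and familiarity both drive hits.  In *exclusive*
conditions (exclusion, local) only items from the target context warrant
"yes": a recollected intrusion lure is correctly rejected, while an
unrecollected one can still attract a "yes" through familiarity alone.
This makes the intrusion false-alarm rate a pure familiarity channel and
the hit-minus-intrusion contrast a recollection-specific signal.

``expected_rates`` provides the closed-form response probabilities, used
both as the simulator's Monte-Carlo oracle and for power/recovery
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import RecognitionForm

__all__ = [
    "DualProcessParams",
    "INCLUSIVE_CONDITIONS",
    "EXCLUSIVE_CONDITIONS",
    "respond",
    "response_probability",
    "expected_rates",
    "expected_dprime",
    "simulate_condition",
    "simulate_counts",
]

INCLUSIVE_CONDITIONS = frozenset({"inclusion", "global"})
EXCLUSIVE_CONDITIONS = frozenset({"exclusion", "local"})
_TRUTHS = frozenset({"target", "intrusion_lure", "new_lure"})


@dataclass(frozen=True)
class DualProcessParams:
    """Latent parameters of one participant (one modality).

    Parameters
    ----------
    R
        Recollection probability, in [0, 1].
    d_f
        Familiarity strength of studied items, in standard-normal units
        of the evidence axis; nonnegative.
    c
        Familiarity decision criterion on the same axis.
    """

    R: float
    d_f: float
    c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"R must be in [0, 1], got {self.R}")
        if self.d_f < 0.0:
            raise ValueError(f"d_f must be >= 0, got {self.d_f}")


def _check_condition(condition: str) -> bool:
    """Return True for inclusive conditions, False for exclusive ones."""
    if condition in INCLUSIVE_CONDITIONS:
        return True
    if condition in EXCLUSIVE_CONDITIONS:
        return False
    raise ValueError(
        f"unknown condition {condition!r}; expected one of "
        f"{sorted(INCLUSIVE_CONDITIONS | EXCLUSIVE_CONDITIONS)}"
    )


def response_probability(truth: str, condition: str, params: DualProcessParams) -> float:
    """Closed-form P("yes") for one item class under the dual-process model."""
    inclusive = _check_condition(condition)
    if truth not in _TRUTHS:
        raise ValueError(f"unknown truth label {truth!r}")
    phi_old = stats.norm.cdf(params.d_f - params.c)   # P(familiarity signal > c | studied)
    phi_new = stats.norm.cdf(-params.c)               # P(signal > c | unstudied)
    if truth == "new_lure":
        return float(phi_new)
    if truth == "intrusion_lure":
        if inclusive:
            raise ValueError(f"{condition!r} forms carry no intrusion lures")
        # recollected -> context known -> correctly rejected
        return float((1.0 - params.R) * phi_old)
    # target
    return float(params.R + (1.0 - params.R) * phi_old)


def respond(
    truth: str,
    condition: str,
    params: DualProcessParams,
    rng: np.random.Generator,
) -> str:
    """Draw one yes/no response by simulating the two processes explicitly.

    A recollection coin (probability ``R``) is flipped for studied items;
    if recollection fails (or the item is unstudied) the Gaussian
    familiarity signal is compared to the criterion.  This mechanistic
    path is deliberately independent of :func:`response_probability`,
    which serves as its closed-form oracle.
    """
    inclusive = _check_condition(condition)
    if truth not in _TRUTHS:
        raise ValueError(f"unknown truth label {truth!r}")
    studied = truth != "new_lure"
    if truth == "intrusion_lure" and inclusive:
        raise ValueError(f"{condition!r} forms carry no intrusion lures")

    if studied and rng.random() < params.R:
        # context retrieved: targets accepted, intrusion lures excluded
        return "no" if truth == "intrusion_lure" else "yes"
    signal = rng.normal(params.d_f if studied else 0.0, 1.0)
    return "yes" if signal > params.c else "no"


def expected_rates(params: DualProcessParams, condition: str) -> dict[str, float | None]:
    """Exact expectations of the hit, false-alarm and intrusion-FA rates.

    For inclusive conditions ``p_intrusion_fa`` is ``None`` (there are no
    intrusion lures).  For exclusive conditions:

    ``p_hit = R + (1 - R) * Phi(d_f - c)``;
    ``p_intrusion_fa = (1 - R) * Phi(d_f - c)``;
    ``p_fa = Phi(-c)``.
    """
    inclusive = _check_condition(condition)
    out: dict[str, float | None] = {
        "p_hit": response_probability("target", condition, params),
        "p_fa": response_probability("new_lure", condition, params),
        "p_intrusion_fa": None,
    }
    if not inclusive:
        out["p_intrusion_fa"] = response_probability("intrusion_lure", condition, params)
    return out


def expected_dprime(params: DualProcessParams, condition: str) -> float:
    """Population d' implied by the expected rates.

    Inclusive conditions give d'(n) = z(hit) - z(fa); exclusive ones give
    d'(i) = z(hit) - z(intrusion fa).  Rates of exactly 0 or 1 make the
    quantile infinite; callers probing limits should expect ``inf``.
    """
    rates = expected_rates(params, condition)
    if _check_condition(condition):
        return float(stats.norm.ppf(rates["p_hit"]) - stats.norm.ppf(rates["p_fa"]))
    return float(
        stats.norm.ppf(rates["p_hit"]) - stats.norm.ppf(rates["p_intrusion_fa"])
    )


def simulate_condition(
    form: RecognitionForm,
    params: DualProcessParams,
    rng: np.random.Generator,
    participant_id: object = 0,
    session: str = "pre",
) -> pd.DataFrame:
    """Simulate one participant's pass through a recognition form.

    Returns a long-format frame with one row per test item:
    ``participant_id, session, modality, condition, form_id, item_id,
    truth, response``.
    """
    if len(form) == 0:
        raise ValueError("form is empty")
    truths = np.asarray(form.truth)
    studied = truths != "new_lure"
    # vectorised draw mirroring respond(): recollection coin, then signal
    recollected = studied & (rng.random(len(form)) < params.R)
    signal = rng.normal(np.where(studied, params.d_f, 0.0), 1.0)
    familiar_yes = signal > params.c
    yes = np.where(
        recollected, truths != "intrusion_lure", familiar_yes
    )
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "session": session,
            "modality": form.modality,
            "condition": form.condition,
            "form_id": form.form_id,
            "item_id": form.test_items,
            "truth": form.truth,
            "response": np.where(yes, "yes", "no"),
        }
    )


def simulate_counts(
    params: DualProcessParams,
    condition: str,
    n_targets: int,
    n_intrusions: int,
    n_new: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Vectorised Monte-Carlo draw of response counts for large-n checks."""
    inclusive = _check_condition(condition)
    if inclusive and n_intrusions:
        raise ValueError(f"{condition!r} forms carry no intrusion lures")
    out = {"n_targets": n_targets, "n_intrusion_lures": n_intrusions, "n_new_lures": n_new}

    rec_t = rng.random(n_targets) < params.R
    sig_t = rng.normal(params.d_f, 1.0, n_targets)
    out["n_hits"] = int(np.sum(rec_t | (sig_t > params.c)))

    if n_intrusions:
        rec_i = rng.random(n_intrusions) < params.R
        sig_i = rng.normal(params.d_f, 1.0, n_intrusions)
        out["n_intrusion_fa"] = int(np.sum(~rec_i & (sig_i > params.c)))
    else:
        out["n_intrusion_fa"] = 0

    sig_n = rng.normal(0.0, 1.0, n_new)
    out["n_fa"] = int(np.sum(sig_n > params.c))
    return out
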