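"""CSV schemas, run configuration and table validation.

All artefacts of a simulated (or imported) trial are plain CSV tables
with a YAML manifest; the schemas are documented in docs/schemas.md.
Validation checks three layers: column schema, within-table invariants
(count bounds, form composition) and referential integrity (every trial
response names an item of its form).  Violations are collected and
reported rather than raised, unless strict mode is requested.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .study import StudyConfig

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "SchemaViolation",
    "validate_tables",
    "write_tables",
    "read_tables",
    "stage_seed",
    "get_logger",
]

log = logging.getLogger("wmtransfer")


def get_logger() -> logging.Logger:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    return log


#: table name -> required columns
SCHEMAS: dict[str, tuple[str, ...]] = {
    "participants": (
        "participant_id", "group", "age", "gender", "schooling_years",
        "gds", "mmse", "sessions_missed", "cognition_medication",
    ),
    "trials": (
        "participant_id", "session", "modality", "condition", "form_id",
        "item_id", "truth", "response",
    ),
    "span_protocols": ("participant_id", "session", "task", "set_size", "n_recalled"),
    "training_log": (
        "participant_id", "session", "task", "block", "trial", "level",
        "recall_correct", "proc_accuracy",
    ),
    "scores": ("participant_id", "group", "session", "measure", "score"),
    "forms": (
        "form_id", "modality", "condition", "version", "position",
        "item_id", "truth", "quadrant",
    ),
}

_VALID_TRUTH = {"target", "intrusion_lure", "new_lure"}
_VALID_RESPONSE = {"yes", "no"}


@dataclass
class RunConfig:
    """Master configuration of one pipeline run.

    Every stochastic stage receives a seed derived from ``seed`` via
    :func:`stage_seed`, so one master seed reproduces the whole run.
    Round-trips losslessly through YAML.
    """

    seed: int = 0
    out_dir: str = "study_out"
    study: StudyConfig = field(default_factory=StudyConfig)
    ancova: bool = True
    ancova_covariate: str = "schooling_years"
    bonferroni_m: int = 7
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        study = StudyConfig(**payload.pop("study", {}))
        return cls(study=study, **payload)


_STAGES = ("cohort", "design", "counterbalance", "spans", "responses", "training")


def stage_seed(master: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed.

    The scheme is a documented counter: stage *i* uses
    ``SeedSequence([master, i])`` with stages numbered in pipeline order
    (cohort=0, design=1, counterbalance=2, spans=3, responses=4,
    training=5).
    """
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SchemaViolation:
    table: str
    kind: str          # "schema" | "invariant" | "referential"
    message: str


def _check_trials(trials: pd.DataFrame, forms: pd.DataFrame | None) -> list[SchemaViolation]:
    out = []
    bad_truth = set(trials["truth"].unique()) - _VALID_TRUTH
    if bad_truth:
        out.append(SchemaViolation("trials", "invariant",
                                   f"unknown truth labels {sorted(bad_truth)}"))
    bad_resp = set(trials["response"].unique()) - _VALID_RESPONSE
    if bad_resp:
        out.append(SchemaViolation("trials", "invariant",
                                   f"unknown responses {sorted(bad_resp)}"))
    if forms is not None:
        known = forms.groupby("form_id")["item_id"].agg(set).to_dict()
        for form_id, grp in trials.groupby("form_id"):
            items = known.get(form_id)
            if items is None:
                out.append(SchemaViolation("trials", "referential",
                                           f"unknown form_id {form_id!r}"))
                continue
            orphans = set(grp["item_id"]) - items
            if orphans:
                out.append(
                    SchemaViolation(
                        "trials", "referential",
                        f"form {form_id!r}: items not on form: {sorted(orphans)[:5]}",
                    )
                )
    return out


def _check_forms(forms: pd.DataFrame) -> list[SchemaViolation]:
    from .design import (
        N_VERBAL_TEST_ITEMS, N_GLOBAL_OLD, N_GLOBAL_NEW,
        N_LOCAL_SAME, N_LOCAL_DIFFERENT, N_LOCAL_NEW,
    )
    expected_sizes = {
        "inclusion": N_VERBAL_TEST_ITEMS,
        "exclusion": N_VERBAL_TEST_ITEMS,
        "global": N_GLOBAL_OLD + N_GLOBAL_NEW,
        "local": N_LOCAL_SAME + N_LOCAL_DIFFERENT + N_LOCAL_NEW,
    }
    out = []
    for form_id, grp in forms.groupby("form_id"):
        cond = grp["condition"].iloc[0]
        base = expected_sizes.get(cond)
        if base is not None and len(grp) % base != 0:
            out.append(
                SchemaViolation(
                    "forms", "invariant",
                    f"form {form_id!r}: {len(grp)} items, expected a multiple of {base}",
                )
            )
        if cond in ("inclusion", "global") and (grp["truth"] == "intrusion_lure").any():
            out.append(SchemaViolation("forms", "invariant",
                                       f"form {form_id!r}: intrusion lures in {cond}"))
    return out


def _check_span_protocols(protocols: pd.DataFrame) -> list[SchemaViolation]:
    out = []
    if (protocols["set_size"] < 1).any():
        out.append(SchemaViolation("span_protocols", "invariant", "set_size < 1"))
    bad = protocols["n_recalled"].lt(0) | protocols["n_recalled"].gt(protocols["set_size"])
    if bad.any():
        out.append(
            SchemaViolation("span_protocols", "invariant",
                            "n_recalled outside [0, set_size]")
        )
    return out


def validate_tables(
    tables: dict[str, pd.DataFrame | str | Path], strict: bool = False
) -> list[SchemaViolation]:
    """Validate a set of pipeline tables (frames or CSV paths).

    Checks schema columns, table invariants and, when both trials and
    forms are given, referential integrity.  Returns the violations;
    raises ``ValueError`` listing them if ``strict``.
    """
    loaded: dict[str, pd.DataFrame] = {}
    violations: list[SchemaViolation] = []
    for name, obj in tables.items():
        df = pd.read_csv(obj) if isinstance(obj, (str, Path)) else obj
        loaded[name] = df
        required = SCHEMAS.get(name)
        if required is None:
            violations.append(SchemaViolation(name, "schema", "unknown table name"))
            continue
        missing = [c for c in required if c not in df.columns]
        if missing:
            violations.append(
                SchemaViolation(name, "schema", f"missing columns: {missing}")
            )
    if "trials" in loaded and not any(
        v.table == "trials" and v.kind == "schema" for v in violations
    ):
        violations += _check_trials(loaded["trials"], loaded.get("forms"))
    if "forms" in loaded and not any(
        v.table == "forms" and v.kind == "schema" for v in violations
    ):
        violations += _check_forms(loaded["forms"])
    if "span_protocols" in loaded and not any(
        v.table == "span_protocols" and v.kind == "schema" for v in violations
    ):
        violations += _check_span_protocols(loaded["span_protocols"])
    if strict and violations:
        raise ValueError(
            "table validation failed:\n"
            + "\n".join(f"  [{v.table}/{v.kind}] {v.message}" for v in violations)
        )
    return violations


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write pipeline frames as CSV files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        if not isinstance(df, pd.DataFrame):
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
        get_logger().info("wrote %s (%d rows)", path, len(df))
    return paths


def read_tables(in_dir: str | Path, names: tuple[str, ...]) -> dict[str, pd.DataFrame]:
    """Read the named pipeline tables from a directory, schema-checked."""
    loaded = {}
    for name in names:
        path = Path(in_dir) / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path)
        missing = [c for c in SCHEMAS[name] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        loaded[name] = df
    return loaded
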