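"""Domain types and plain-text I/O for the growth-modelling pipeline.

Long-format growth tables hold one row per measurement occasion per
trait; outcome tables hold one row per subject.  Both travel as CSV with
fixed, documented column names.  Fitted-model summaries are written as
JSON with full numeric precision so that predictions can be rebuilt
bit-for-bit from the file alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROWTH_COLUMNS = ["subject_id", "cohort_id", "sex", "age", "trait", "value", "source", "excluded"]

SEXES = ("male", "female")
TRAITS = ("height", "weight")
SOURCES = ("measured", "reported", "imputed_age")


class SchemaError(ValueError):
    """A table is missing required columns."""


class RowValidationError(ValueError):
    """One or more rows violate field-level invariants."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


@dataclass
class MeasurementRecord:
    """One growth observation: a subject's trait value at an exact age.

    ``value`` is in cm for height and kg for weight.  ``source`` flags
    self-reported values and sweeps whose measurement age was imputed;
    it is provenance only and does not affect fitting.  ``excluded`` is
    set by the model-based cleaning pass and keeps the record out of any
    refit likelihood while preserving it in output files.
    """

    subject_id: str
    cohort_id: str
    sex: str
    age: float
    trait: str
    value: float
    source: str = "measured"
    excluded: bool = False

    def validate(self) -> list[str]:
        problems = []
        if not (0 < self.age <= 40):
            problems.append(f"age {self.age} outside (0, 40]")
        if not self.value > 0:
            problems.append(f"value {self.value} not positive")
        if self.sex not in SEXES:
            problems.append(f"sex {self.sex!r} not in {SEXES}")
        if self.trait not in TRAITS:
            problems.append(f"trait {self.trait!r} not in {TRAITS}")
        if self.source not in SOURCES:
            problems.append(f"source {self.source!r} not in {SOURCES}")
        return problems


@dataclass
class OutcomeRecord:
    """Per-subject later-life outcomes on the log scale.

    ``outcomes`` maps outcome name to its log-scale value (e.g. log
    trabecular vBMD, log diaphysis CSA analogues).  Follow-up height and
    weight are stored in log cm / log kg for allometric adjustment.
    ``timing`` is a continuous puberty-timing score where lower means
    earlier puberty.
    """

    subject_id: str
    sex: str
    outcomes: dict[str, float]
    log_height_followup: float
    log_weight_followup: float
    timing: float

    def validate(self) -> list[str]:
        problems = []
        for name, v in self.outcomes.items():
            if not np.isfinite(v):
                problems.append(f"outcome {name!r} not finite")
        for name in ("log_height_followup", "log_weight_followup", "timing"):
            if not np.isfinite(getattr(self, name)):
                problems.append(f"{name} not finite")
        if self.sex not in SEXES:
            problems.append(f"sex {self.sex!r} not in {SEXES}")
        return problems


@dataclass
class SitarConfig:
    """Settings for one shape-invariant growth model fit.

    ``df`` is the spline degrees of freedom (basis columns).  Age enters
    the model log-transformed by default, which makes tempo and velocity
    effects proportional (interpretable as percentages when multiplied
    by 100).  ``cohort_effects`` switches the size/tempo/velocity fixed
    offsets for non-reference cohorts; ``per_cohort_residual`` allows
    each cohort its own residual SD.  ``spline_spec`` optionally pins
    the knots explicitly instead of the default quantile placement.
    """

    df: int = 5
    age_transform: str = "log"  # or "identity"
    cohort_effects: tuple[bool, bool, bool] = (True, True, True)  # size, tempo, velocity
    per_cohort_residual: bool = True
    active_random_effects: tuple[str, ...] = ("size", "tempo", "velocity")
    reference_cohort: str | None = None
    tol: float = 1e-6
    max_iter: int = 50
    seed: int = 0
    spline_spec: object | None = None
    # pivot of the velocity stretch on the transformed-age scale; defaults
    # to the mean transformed age of the fitted records (geometric mean age
    # under the log transform)
    age_center: float | None = None

    def __post_init__(self) -> None:
        if self.df < 3:
            raise ValueError("df must be >= 3")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.age_transform not in ("log", "identity"):
            raise ValueError("age_transform must be 'log' or 'identity'")
        bad = set(self.active_random_effects) - {"size", "tempo", "velocity"}
        if bad:
            raise ValueError(f"unknown random effects {sorted(bad)}")


# ---------------------------------------------------------------------------
# growth-table I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=GROWTH_COLUMNS)
    return pd.DataFrame(rows, columns=GROWTH_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns and c != "excluded"]
    if missing:
        raise SchemaError(f"growth table missing column(s): {', '.join(missing)}")
    recs = []
    excluded = df["excluded"] if "excluded" in df.columns else pd.Series(False, index=df.index)
    for i, row in enumerate(df.itertuples(index=False)):
        recs.append(
            MeasurementRecord(
                subject_id=str(row.subject_id),
                cohort_id=str(row.cohort_id),
                sex=str(row.sex),
                age=float(row.age),
                trait=str(row.trait),
                value=float(row.value),
                source=str(row.source),
                excluded=bool(excluded.iloc[i]),
            )
        )
    bad = {}
    for i, r in enumerate(recs):
        problems = r.validate()
        if problems:
            bad[i] = problems
    if bad:
        detail = "; ".join(f"row {i}: {', '.join(p)}" for i, p in list(bad.items())[:10])
        raise RowValidationError(
            f"{len(bad)} invalid row(s): {detail}", rows=list(bad)
        )
    return recs


def read_growth_table(path) -> list[MeasurementRecord]:
    """Read a long-format growth CSV into validated records.

    Row order is preserved.  Missing columns raise :class:`SchemaError`;
    invalid field values raise :class:`RowValidationError` naming the
    offending rows.
    """
    df = pd.read_csv(path, comment="#")
    recs = frame_to_records(df)
    logger.info("read %d growth records from %s", len(recs), path)
    return recs


def write_growth_table(records: Iterable[MeasurementRecord], path, header_lines: Sequence[str] = ()) -> None:
    """Write records as CSV (lossless round-trip, including ``excluded``)."""
    df = records_to_frame(records)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# outcome-table I/O
# ---------------------------------------------------------------------------

_OUTCOME_FIXED = ["subject_id", "sex", "log_height_followup", "log_weight_followup", "timing"]


def read_outcome_table(path) -> list[OutcomeRecord]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _OUTCOME_FIXED if c not in df.columns]
    if missing:
        raise SchemaError(f"outcome table missing column(s): {', '.join(missing)}")
    outcome_cols = [c for c in df.columns if c not in _OUTCOME_FIXED]
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(
            OutcomeRecord(
                subject_id=str(d["subject_id"]),
                sex=str(d["sex"]),
                outcomes={c: float(d[c]) for c in outcome_cols},
                log_height_followup=float(d["log_height_followup"]),
                log_weight_followup=float(d["log_weight_followup"]),
                timing=float(d["timing"]),
            )
        )
    bad = {i: p for i, r in enumerate(recs) if (p := r.validate())}
    if bad:
        detail = "; ".join(f"row {i}: {', '.join(p)}" for i, p in list(bad.items())[:10])
        raise RowValidationError(f"{len(bad)} invalid row(s): {detail}", rows=list(bad))
    logger.info("read %d outcome records from %s", len(recs), path)
    return recs


def write_outcome_table(records: Iterable[OutcomeRecord], path, header_lines: Sequence[str] = ()) -> None:
    records = list(records)
    outcome_cols: list[str] = []
    for r in records:
        for name in r.outcomes:
            if name not in outcome_cols:
                outcome_cols.append(name)
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            **{c: r.outcomes.get(c, np.nan) for c in outcome_cols},
            "log_height_followup": r.log_height_followup,
            "log_weight_followup": r.log_weight_followup,
            "timing": r.timing,
        }
        rows.append(row)
    cols = ["subject_id", "sex", *outcome_cols, "log_height_followup", "log_weight_followup", "timing"]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
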