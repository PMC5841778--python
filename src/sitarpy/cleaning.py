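"""Model-based outlier exclusion.

After a preliminary model fit, any observation whose standardized
residual (residual over the cohort's residual SD) exceeds a threshold
in absolute value is flagged and excluded from the refit.  One
preliminary-fit / flag / refit cycle — the pass is not iterated to a
fixed point.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SitarFit, fit_sitar
from .records import MeasurementRecord, SitarConfig

logger = logging.getLogger(__name__)

__all__ = ["ExclusionReport", "flag_outliers", "clean_and_refit"]


@dataclass
class ExclusionReport:
    """Per-record standardized residuals and flags from one cleaning pass."""

    table: pd.DataFrame  # subject_id, cohort_id, age, trait, value, standardized_residual, flagged
    n_total: int
    n_flagged: int
    threshold: float

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_total if self.n_total else 0.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _standardized_residuals(records: list[MeasurementRecord], fit: SitarFit) -> np.ndarray:
    """Residuals standardized by the cohort-specific residual SD."""
    from . import spline as spl

    blup = {b.subject_id: b.as_array() for b in fit.blups}
    zero = np.zeros(3)
    g_shift = np.array([0.0, fit.global_shift[0], fit.global_shift[1]])
    eff = np.array([
        fit.cohort_offsets[r.cohort_id] + g_shift + blup.get(r.subject_id, zero)
        for r in records
    ])
    ages = np.array([r.age for r in records])
    raw = np.log(ages) if fit.config.age_transform == "log" else ages
    t = raw - fit.age_center
    u = np.exp(eff[:, 2]) * (t - eff[:, 1])
    pred = fit.intercept + spl.basis(fit.spline_spec, u) @ fit.spline_coefs + eff[:, 0]
    sd = np.array([fit.residual_sd[r.cohort_id] for r in records])
    values = np.array([r.value for r in records])
    return (values - pred) / sd


def flag_outliers(records: list[MeasurementRecord], fit: SitarFit,
                  z_threshold: float = 3.0) -> tuple[list[MeasurementRecord], ExclusionReport]:
    """Set ``excluded`` on records with |standardized residual| > threshold.

    Flagging is a pure function of the residuals and the threshold;
    non-flagged records are returned untouched (already-excluded
    records keep their flag and are not re-scored against the fit).
    Returns new record objects plus a report.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    zs = _standardized_residuals(records, fit)
    flagged = np.abs(zs) > z_threshold
    out = [
        dataclasses.replace(r, excluded=bool(fl or r.excluded))
        for r, fl in zip(records, flagged)
    ]
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "cohort_id": [r.cohort_id for r in records],
            "age": [r.age for r in records],
            "trait": [r.trait for r in records],
            "value": [r.value for r in records],
            "standardized_residual": zs,
            "flagged": flagged,
        }
    )
    report = ExclusionReport(
        table=table, n_total=len(records), n_flagged=int(flagged.sum()),
        threshold=float(z_threshold),
    )
    logger.info(
        "flagged %d of %d records (%.2f%%) at |z| > %g",
        report.n_flagged, report.n_total, 100 * report.fraction_flagged, z_threshold,
    )
    return out, report


def clean_and_refit(records: list[MeasurementRecord], config: SitarConfig,
                    z_threshold: float = 3.0) -> tuple[SitarFit, SitarFit, ExclusionReport]:
    """Preliminary fit, one flagging pass, refit on the retained records.

    Returns (preliminary fit, refit, exclusion report).  Excluded
    records never enter the refit likelihood but are preserved (with
    their flag) in the returned report's table.
    """
    prelim = fit_sitar(records, config)
    flagged_records, report = flag_outliers(records, prelim, z_threshold)
    refit = fit_sitar(flagged_records, config)
    return prelim, refit, report
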