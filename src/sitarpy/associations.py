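"""Second-stage analysis: growth parameters versus later-life outcomes.

Log-scale outcomes are regressed on the six growth random effects
(size, tempo, velocity for height and for weight) with sex as a main
effect (Model 1), optionally further adjusted for log follow-up height
and weight (Model 2).  Because the outcomes are logged, coefficients
multiplied by 100 read as percentage differences, and the growth-impact
statistic — four times the SD of the linear predictor over the six
random-effect columns — is the percentage contrast in outcome between
growth patterns 2 SD below and 2 SD above the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .engine import RandomEffects, SitarFit
from .records import OutcomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "associate",
    "growth_impact",
    "correlate_re_timing",
    "compare_fits",
]

RE_COLS = ["height_size", "height_tempo", "height_velocity",
           "weight_size", "weight_tempo", "weight_velocity"]


@dataclass
class AssociationResult:
    """One outcome's regression on the six growth random effects."""

    model: str                     # "Model1" or "Model2"
    outcome: str
    coef: pd.Series                # estimate per regressor
    se: pd.Series
    tvalues: pd.Series
    r2: float                      # raw R^2
    adj_r2_pct: float              # adjusted R^2 in percent
    growth_impact_pct: float
    n: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.coef, "se": self.se, "t": self.tvalues})


def _re_frame(res: list[RandomEffects], prefix: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [b.subject_id for b in res],
            f"{prefix}_size": [b.size for b in res],
            f"{prefix}_tempo": [b.tempo for b in res],
            f"{prefix}_velocity": [b.velocity for b in res],
        }
    ).set_index("subject_id")


def growth_impact(coefs, re_matrix, ddof: int = 0) -> float:
    """Percent impact of a growth pattern: 100 x 4 x SD of the linear predictor.

    ``coefs`` aligns with the columns of ``re_matrix`` (subjects x
    effects).  For a single column this reduces to 100 x |coef| x 4 x
    SD(effect).  The SD uses divisor ``n`` by default (population SD);
    set ``ddof=1`` for the sample version.
    """
    coefs = np.asarray(coefs, dtype=float)
    re_matrix = np.asarray(re_matrix, dtype=float)
    if re_matrix.ndim == 1:
        re_matrix = re_matrix[:, None]
    if re_matrix.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a growth-impact SD")
    if coefs.shape != (re_matrix.shape[1],):
        raise ValueError(
            f"coefficient vector of length {coefs.size} does not align with "
            f"{re_matrix.shape[1]} random-effect columns"
        )
    lin = re_matrix @ coefs
    return float(100.0 * 4.0 * np.std(lin, ddof=ddof))


def associate(outcomes: list[OutcomeRecord], re_height: list[RandomEffects],
              re_weight: list[RandomEffects], model: str, outcome_name: str,
              impact_ddof: int = 0) -> AssociationResult:
    """OLS of one log outcome on the six growth random effects.

    ``model`` is "Model1" (six effects + sex) or "Model2" (Model 1 plus
    log follow-up height and weight).  Complete cases only: subjects
    present in the outcome table and in both random-effect sets.
    """
    if model not in ("Model1", "Model2"):
        raise ValueError("model must be 'Model1' or 'Model2'")
    h = _re_frame(re_height, "height")
    w = _re_frame(re_weight, "weight")
    rows = []
    for o in outcomes:
        if o.subject_id in h.index and o.subject_id in w.index and outcome_name in o.outcomes:
            y = o.outcomes[outcome_name]
            if not np.isfinite(y):
                continue
            rows.append(
                {
                    "subject_id": o.subject_id,
                    "y": y,
                    "female": 1.0 if o.sex == "female" else 0.0,
                    "log_height_followup": o.log_height_followup,
                    "log_weight_followup": o.log_weight_followup,
                }
            )
    df = pd.DataFrame(rows).set_index("subject_id")
    df = df.join(h).join(w).dropna()
    regs = RE_COLS + ["female"]
    if model == "Model2":
        regs = regs + ["log_height_followup", "log_weight_followup"]
    # constant covariates (e.g. sex in a single-sex sample) carry no
    # information and would alias the intercept
    dropped = [r for r in regs if r not in RE_COLS and df[r].nunique() <= 1]
    if dropped:
        logger.info("dropping constant regressor(s): %s", dropped)
        regs = [r for r in regs if r not in dropped]
    n = len(df)
    if n <= len(regs) + 5:
        raise ValueError(f"only {n} complete cases for {len(regs)} regressors")
    X = sm.add_constant(df[regs])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        bad = []
        cols = X.to_numpy()
        for j, name in enumerate(X.columns):
            others = np.delete(cols, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    res = sm.OLS(df["y"], X).fit()
    impact = growth_impact(res.params[RE_COLS].to_numpy(),
                           df[RE_COLS].to_numpy(), ddof=impact_ddof)
    logger.info("associate %s %s: n=%d complete cases", outcome_name, model, n)
    return AssociationResult(
        model=model,
        outcome=outcome_name,
        coef=res.params,
        se=res.bse,
        tvalues=res.tvalues,
        r2=float(res.rsquared),
        adj_r2_pct=float(100 * res.rsquared_adj),
        growth_impact_pct=impact,
        n=n,
    )


def correlate_re_timing(re_sets: dict[str, list[RandomEffects]],
                        timing: dict[str, float],
                        sex_by_subject: dict[str, str] | None = None) -> pd.DataFrame:
    """Pearson correlations of each random effect with the timing score.

    ``re_sets`` maps a label (e.g. trait or trait/model) to a
    random-effect collection; ``timing`` maps subject to score.  With a
    sex map the correlations are additionally reported per sex.
    Requires at least 3 complete cases per cell.
    """
    rows = []
    for label, res in re_sets.items():
        recs = [(b.subject_id, b.size, b.tempo, b.velocity) for b in res
                if b.subject_id in timing]
        if len(recs) < 3:
            raise ValueError(f"fewer than 3 complete cases for {label!r}")
        ids = [r[0] for r in recs]
        arr = np.array([r[1:] for r in recs])
        tvec = np.array([timing[i] for i in ids])
        groups = {"all": np.ones(len(ids), dtype=bool)}
        if sex_by_subject is not None:
            for s in sorted({sex_by_subject.get(i, "?") for i in ids}):
                groups[s] = np.array([sex_by_subject.get(i, "?") == s for i in ids])
        for gname, mask in groups.items():
            if mask.sum() < 3:
                continue
            for j, param in enumerate(("size", "tempo", "velocity")):
                r = np.corrcoef(arr[mask, j], tvec[mask])[0, 1]
                rows.append({"set": label, "sex": gname, "parameter": param,
                             "correlation": r, "n": int(mask.sum())})
    return pd.DataFrame(rows)


def compare_fits(fit_sole: SitarFit, fit_joint: SitarFit, cohort_id: str) -> pd.DataFrame:
    """Agreement between two fits' random effects for one cohort's subjects.

    Reports, per parameter, the Pearson correlation between the two
    fits' BLUPs over the shared subjects of ``cohort_id``, plus the two
    model-SD estimates and their ratio.
    """
    sole = {b.subject_id: b.as_array() for b in fit_sole.blups}
    joint = {b.subject_id: b.as_array() for b in fit_joint.blups}
    shared = [s for s in sole if s in joint]
    if cohort_id is not None:
        shared = [
            s for s in shared
            if fit_joint.subject_cohorts.get(s, fit_sole.subject_cohorts.get(s)) == cohort_id
        ]
    if not shared:
        raise ValueError(f"no shared subjects for cohort {cohort_id!r}")
    A = np.array([sole[s] for s in shared])
    B = np.array([joint[s] for s in shared])
    sd_sole = np.sqrt(np.clip(np.diag(fit_sole.re_cov), 0, None))
    sd_joint = np.sqrt(np.clip(np.diag(fit_joint.re_cov), 0, None))
    rows = []
    for j, param in enumerate(("size", "tempo", "velocity")):
        a, b = A[:, j], B[:, j]
        if a.std() == 0 or b.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        ratio = sd_joint[j] / sd_sole[j] if sd_sole[j] > 0 else np.nan
        rows.append({"parameter": param, "blup_correlation": r,
                     "sd_sole": float(sd_sole[j]), "sd_joint": float(sd_joint[j]),
                     "sd_ratio": float(ratio), "n": len(shared)})
    return pd.DataFrame(rows)
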