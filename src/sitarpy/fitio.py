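"""Serialisation of fitted models to structured text (JSON).

The summary carries every quantity needed to rebuild predictions
bit-for-bit: knot layout, intercept and spline coefficients, cohort
offsets with standard errors, random-effect covariance, residual SDs,
per-subject BLUPs and the fit's configuration.  Floats round-trip
exactly through JSON (repr-based shortest representation).
"""

from __future__ import annotations

import json

import numpy as np

from .engine import RandomEffects, SitarFit
from .records import SitarConfig
from .spline import SplineSpec

__all__ = ["write_fit_summary", "read_fit_summary", "fit_to_dict", "fit_from_dict"]


def fit_to_dict(fit: SitarFit) -> dict:
    cfg = fit.config
    return {
        "format": "sitarpy-fit/1",
        "trait": fit.trait,
        "sex": fit.sex,
        "config": {
            "df": cfg.df,
            "age_transform": cfg.age_transform,
            "cohort_effects": list(cfg.cohort_effects),
            "per_cohort_residual": cfg.per_cohort_residual,
            "active_random_effects": list(cfg.active_random_effects),
            "reference_cohort": cfg.reference_cohort,
            "tol": cfg.tol,
            "max_iter": cfg.max_iter,
            "seed": cfg.seed,
        },
        "spline_spec": fit.spline_spec.to_dict(),
        "intercept": fit.intercept,
        "spline_coefs": fit.spline_coefs.tolist(),
        "cohort_ids": fit.cohort_ids,
        "cohort_offsets": {c: v.tolist() for c, v in fit.cohort_offsets.items()},
        "offset_se": {c: v.tolist() for c, v in fit.offset_se.items()},
        "re_cov": fit.re_cov.tolist(),
        "residual_sd": fit.residual_sd,
        "blups": [
            {"subject_id": b.subject_id, "size": b.size, "tempo": b.tempo,
             "velocity": b.velocity}
            for b in fit.blups
        ],
        "subject_cohorts": fit.subject_cohorts,
        "global_shift": list(fit.global_shift),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "geometric_mean_age": fit.geometric_mean_age,
        "age_center": fit.age_center,
        "n_subjects": fit.n_subjects,
        "n_records": fit.n_records,
    }


def fit_from_dict(d: dict) -> SitarFit:
    cfg = d["config"]
    config = SitarConfig(
        df=cfg["df"],
        age_transform=cfg["age_transform"],
        cohort_effects=tuple(cfg["cohort_effects"]),
        per_cohort_residual=cfg["per_cohort_residual"],
        active_random_effects=tuple(cfg["active_random_effects"]),
        reference_cohort=cfg["reference_cohort"],
        tol=cfg["tol"],
        max_iter=cfg["max_iter"],
        seed=cfg["seed"],
    )
    return SitarFit(
        trait=d["trait"],
        sex=d["sex"],
        config=config,
        spline_spec=SplineSpec.from_dict(d["spline_spec"]),
        intercept=float(d["intercept"]),
        spline_coefs=np.array(d["spline_coefs"], dtype=float),
        cohort_ids=list(d["cohort_ids"]),
        cohort_offsets={c: np.array(v, dtype=float) for c, v in d["cohort_offsets"].items()},
        offset_se={c: np.array(v, dtype=float) for c, v in d["offset_se"].items()},
        re_cov=np.array(d["re_cov"], dtype=float),
        residual_sd={c: float(v) for c, v in d["residual_sd"].items()},
        blups=[
            RandomEffects(b["subject_id"], float(b["size"]), float(b["tempo"]),
                          float(b["velocity"]))
            for b in d["blups"]
        ],
        subject_cohorts=dict(d["subject_cohorts"]),
        global_shift=tuple(d.get("global_shift", (0.0, 0.0))),
        loglik=float(d["loglik"]),
        converged=bool(d["converged"]),
        n_iter=int(d["n_iter"]),
        geometric_mean_age=float(d["geometric_mean_age"]),
        age_center=float(d["age_center"]),
        n_subjects=int(d["n_subjects"]),
        n_records=int(d["n_records"]),
    )


class _NanEncoder(json.JSONEncoder):
    def default(self, o):  # pragma: no cover - only hit for numpy scalars
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_fit_summary(fit: SitarFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1, cls=_NanEncoder)
        fh.write("\n")


def read_fit_summary(path) -> SitarFit:
    with open(path) as fh:
        return fit_from_dict(json.load(fh))
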