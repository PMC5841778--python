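import numpy as np
import pytest

from sitarpy import (
    CohortSpec,
    SimConfig,
    SitarConfig,
    SplineSpec,
    fit_sitar,
    simulate_cohorts,
    template_knots,
)

RE_CORR_DEFAULT = np.array([[1.0, 0.1, 0.76], [0.1, 1.0, 0.1], [0.76, 0.1, 1.0]])


def template_spline_spec(trait: str = "height") -> SplineSpec:
    """Spline spec whose knots coincide with the packaged template's knots
    (on the plain log-age scale), so the template lies exactly in the
    fitted model family."""
    kn = np.log(np.array([k[0] for k in template_knots(trait)]))
    return SplineSpec(
        boundary_knots=(float(kn[0]), float(kn[-1])),
        interior_knots=tuple(float(k) for k in kn[1:-1]),
        df=len(kn) - 1,
    )


@pytest.fixture(scope="session")
def dense_sim_small():
    """Small single dense cohort with known truth (fast fits)."""
    coh = CohortSpec("dense", 80, schedule=tuple(range(5, 17)), residual_sd=0.8,
                     jitter=0.25)
    sim = SimConfig(trait="height", cohorts=(coh,), re_sd=(5.7, 0.055, 0.09),
                    re_corr=RE_CORR_DEFAULT, seed=42)
    return simulate_cohorts(sim)


@pytest.fixture(scope="session")
def dense_fit_small(dense_sim_small):
    recs, truth = dense_sim_small
    cfg = SitarConfig(df=6, cohort_effects=(False, False, False),
                      per_cohort_residual=False)
    return fit_sitar(recs, cfg), truth


@pytest.fixture(scope="session")
def joint_sim_small():
    """Two small cohorts (sparse + dense) with planted offsets."""
    sparse = CohortSpec("sparse46", 50, schedule=(2, 4, 6, 7, 11, 15, 20, 26),
                        residual_sd=2.5, jitter=0.25, imputed_ages=(2.0, 20.0),
                        reported_ages=(20.0, 26.0))
    dense = CohortSpec("dense91", 70,
                       schedule=(5, 6, 7, 8, 9, 10, 11, 12, 13, 15, 17),
                       residual_sd=2.5 / 1.6, offsets=(2.3, -0.048, 0.068))
    sim = SimConfig(trait="height", cohorts=(sparse, dense),
                    re_sd=(5.7, 0.055, 0.09), re_corr=RE_CORR_DEFAULT, seed=7)
    return simulate_cohorts(sim)


@pytest.fixture(scope="session")
def joint_fit_small(joint_sim_small):
    recs, truth = joint_sim_small
    cfg = SitarConfig(df=6, reference_cohort="sparse46")
    return fit_sitar(recs, cfg), truth
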