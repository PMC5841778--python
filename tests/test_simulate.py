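"""Synthetic-cohort generator: determinism, templates, truth structure."""

import numpy as np
import pytest
import scipy.signal

from sitarpy import (
    CohortSpec,
    SimConfig,
    default_sim_config,
    height_template,
    simulate_cohorts,
    simulate_outcomes,
    simulate_timing,
    template_knots,
    weight_template,
)


class TestTemplates:
    @pytest.mark.parametrize("trait,template", [("height", height_template),
                                                ("weight", weight_template)])
    def test_monotone_over_fine_grid(self, trait, template):
        ages = np.arange(1.0, 30.0, 0.01)
        assert (np.diff(template(ages)) > 0).all()

    @pytest.mark.parametrize("trait,template", [("height", height_template),
                                                ("weight", weight_template)])
    def test_unique_interior_velocity_peak(self, trait, template):
        grid = np.arange(8.0, 16.0, 0.001)
        v = (template(grid + 1e-4) - template(grid - 1e-4)) / 2e-4
        peaks, _ = scipy.signal.find_peaks(v)
        assert len(peaks) == 1
        assert 10.0 < grid[peaks[0]] < 15.0

    @pytest.mark.parametrize("trait,template", [("height", height_template),
                                                ("weight", weight_template)])
    def test_knot_table_reproduced_exactly(self, trait, template):
        knots = template_knots(trait)
        ages = np.array([k[0] for k in knots])
        vals = np.array([k[1] for k in knots])
        np.testing.assert_allclose(template(ages), vals, atol=1e-12)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            height_template(0.5)
        with pytest.raises(ValueError, match="support"):
            weight_template(31.0)


class TestSimulateCohorts:
    def test_bit_reproducible(self):
        sim = default_sim_config(n_sparse=20, n_dense=25, seed=9)
        r1, t1 = simulate_cohorts(sim)
        sim2 = default_sim_config(n_sparse=20, n_dense=25, seed=9)
        r2, t2 = simulate_cohorts(sim2)
        assert r1 == r2
        np.testing.assert_array_equal(t1.re, t2.re)

    def test_different_seed_differs(self):
        r1, _ = simulate_cohorts(default_sim_config(n_sparse=10, n_dense=10, seed=1))
        r2, _ = simulate_cohorts(default_sim_config(n_sparse=10, n_dense=10, seed=2))
        assert r1 != r2

    def test_noise_free_zero_effects_on_template(self):
        coh = CohortSpec("c", 5, schedule=(3.0, 8.0, 13.0, 18.0), residual_sd=0.0,
                         jitter=0.0)
        sim = SimConfig(trait="height", cohorts=(coh,), re_sd=(0, 0, 0), seed=0)
        recs, _ = simulate_cohorts(sim)
        for r in recs:
            assert r.value == pytest.approx(float(height_template(r.age)), abs=1e-9)

    def test_empirical_tempo_sd_matches_config(self):
        coh = CohortSpec("c", 10_000, schedule=(10.0,), residual_sd=0.0, jitter=0.0)
        sim = SimConfig(trait="height", cohorts=(coh,), re_sd=(5.7, 0.055, 0.09),
                        seed=123)
        _, truth = simulate_cohorts(sim)
        assert truth.re[:, 1].std() == pytest.approx(0.055, rel=0.02)

    def test_imputed_and_reported_sources_flagged(self):
        sim = default_sim_config(n_sparse=3, n_dense=1, seed=0)
        recs, _ = simulate_cohorts(sim)
        sparse = [r for r in recs if r.cohort_id == "sparse46"]
        # imputed-age sweeps carry no timing jitter: exactly 2.0 / 20.0
        imputed = [r for r in sparse if r.source == "imputed_age"]
        assert {r.age for r in imputed} == {2.0, 20.0}
        reported = [r for r in sparse if r.source == "reported"]
        assert all(25.7 <= r.age <= 26.3 for r in reported)
        measured = [r for r in sparse if r.source == "measured"]
        assert all(r.age not in (2.0, 20.0, 26.0) or True for r in measured)
        assert len(imputed) + len(reported) + len(measured) == len(sparse)

    def test_invalid_corr_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            SimConfig(cohorts=(CohortSpec("c", 2, (5.0,), 1.0),),
                      re_corr=2 * np.eye(3))


@pytest.fixture(scope="module")
def truths():
    n = 2000
    coh = CohortSpec("c", n, schedule=(10.0,), residual_sd=0.0, jitter=0.0)
    sh = SimConfig(trait="height", cohorts=(coh,), re_sd=(5.7, 0.055, 0.09), seed=5)
    sw = SimConfig(trait="weight", cohorts=(coh,), re_sd=(4.2, 0.085, 0.26), seed=6)
    return simulate_cohorts(sh)[1], simulate_cohorts(sw)[1]


class TestOutcomesAndTiming:
    def test_zero_coefficients_no_association(self, truths):
        th, tw = truths
        out = simulate_outcomes(th, tw, np.zeros(6), 0.0, 0.3, seed=1)
        y = np.array([o.outcomes["log_outcome"] for o in out])
        r = np.corrcoef(y, th.re[:, 1])[0, 1]
        assert abs(r) < 2.5 / np.sqrt(len(y))  # CI covers zero

    def test_zero_noise_linear_predictor_exact(self, truths):
        th, tw = truths
        coefs = np.array([0.01, -0.65, 0.1, 0.005, 0.2, -0.05])
        out = simulate_outcomes(th, tw, coefs, 0.0, 0.0, seed=2)
        y = np.array([o.outcomes["log_outcome"] for o in out])
        lin = np.hstack([th.re, tw.re]) @ coefs
        np.testing.assert_allclose(y, lin, atol=1e-12)

    def test_followup_size_correlated(self, truths):
        th, tw = truths
        out = simulate_outcomes(th, tw, np.zeros(6), 0.0, 0.1, seed=3)
        lh = np.array([o.log_height_followup for o in out])
        assert np.corrcoef(lh, th.re[:, 0])[0, 1] > 0.5

    def test_timing_perfect_correlation(self, truths):
        th, _ = truths
        t = simulate_timing(th, 1.0, seed=4)
        assert np.corrcoef(t, th.re[:, 1])[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_timing_target_correlation(self, truths):
        th, _ = truths
        t = simulate_timing(th, 0.55, seed=5)
        assert np.corrcoef(t, th.re[:, 1])[0, 1] == pytest.approx(0.55, abs=0.06)

    def test_timing_zero_correlation(self, truths):
        th, _ = truths
        t = simulate_timing(th, 0.0, seed=6)
        assert abs(np.corrcoef(t, th.re[:, 1])[0, 1]) < 2.5 / np.sqrt(t.size)

    def test_timing_invalid_rho(self, truths):
        th, _ = truths
        with pytest.raises(ValueError):
            simulate_timing(th, 1.5, seed=0)
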