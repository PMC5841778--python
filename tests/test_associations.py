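"""Second-stage regressions, growth impact, timing correlations."""

import numpy as np
import pytest

from sitarpy import (
    CohortSpec,
    RandomEffects,
    SimConfig,
    associate,
    compare_fits,
    correlate_re_timing,
    growth_impact,
    simulate_cohorts,
    simulate_outcomes,
    simulate_timing,
)


@pytest.fixture(scope="module")
def truth_pair():
    n = 800
    coh = CohortSpec("c", n, schedule=(10.0,), residual_sd=0.0, jitter=0.0)
    th = simulate_cohorts(SimConfig(trait="height", cohorts=(coh,),
                                    re_sd=(5.7, 0.055, 0.09), seed=21))[1]
    tw = simulate_cohorts(SimConfig(trait="weight", cohorts=(coh,),
                                    re_sd=(4.2, 0.085, 0.26), seed=22))[1]
    return th, tw


def _re_list(truth):
    return [RandomEffects(s, *truth.re[i]) for i, s in enumerate(truth.subject_ids)]


class TestGrowthImpact:
    def test_single_parameter_identity(self):
        """Impact reduces to 100 * |coef| * 4 * SD for one parameter."""
        rng = np.random.default_rng(0)
        re = rng.normal(0, 0.055, 500)
        coef = -0.65
        expected = 100 * abs(coef) * 4 * re.std()
        assert growth_impact([coef], re) == pytest.approx(expected, rel=1e-10)

    def test_plausible_magnitude_for_tempo(self):
        # 4 SD of a 0.055 tempo spread times a -0.65 log-coefficient is a
        # ~14% contrast between extreme growth patterns
        assert 100 * 4 * 0.055 * 0.65 == pytest.approx(14.3, abs=0.05)

    def test_multiparameter_brute_force(self):
        re = np.array([
            [1.0, 0.5], [0.2, -0.1], [-0.8, 0.4], [0.1, 0.9], [-0.5, -1.7],
        ])
        coefs = np.array([0.3, -1.2])
        lin = re @ coefs
        expected = 100 * 4 * np.sqrt(np.mean((lin - lin.mean()) ** 2))
        assert growth_impact(coefs, re) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_column_shift(self):
        rng = np.random.default_rng(1)
        re = rng.normal(size=(50, 3))
        coefs = np.array([0.5, -0.2, 1.0])
        base = growth_impact(coefs, re)
        shifted = re + np.array([10.0, -3.0, 0.7])
        assert growth_impact(coefs, shifted) == pytest.approx(base, rel=1e-12)

    def test_linear_in_single_coefficient(self):
        rng = np.random.default_rng(2)
        re = rng.normal(size=(50, 1))
        assert growth_impact([2.0], re) == pytest.approx(2 * growth_impact([1.0], re))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            growth_impact([1.0], np.array([[1.0], [2.0]]))


class TestAssociate:
    def test_planted_coefficients_recovered(self, truth_pair):
        th, tw = truth_pair
        coefs = np.array([0.002, -0.65, 0.1, 0.004, 0.3, -0.08])
        out = simulate_outcomes(th, tw, coefs, sex_effect=0.0, noise_sd=0.2, seed=5)
        res = associate(out, _re_list(th), _re_list(tw), "Model1", "log_outcome")
        names = ["height_size", "height_tempo", "height_velocity",
                 "weight_size", "weight_tempo", "weight_velocity"]
        within = [abs(res.coef[n] - c) <= 2 * res.se[n] for n, c in zip(names, coefs)]
        assert sum(within) >= 5

    def test_null_t_values_small(self, truth_pair):
        th, tw = truth_pair
        out = simulate_outcomes(th, tw, np.zeros(6), 0.0, 0.3, seed=6)
        res = associate(out, _re_list(th), _re_list(tw), "Model1", "log_outcome")
        re_t = res.tvalues[["height_size", "height_tempo", "height_velocity",
                            "weight_size", "weight_tempo", "weight_velocity"]]
        assert (np.abs(re_t) < 4).all()
        assert res.adj_r2_pct < 2.0

    def test_t_invariant_to_regressor_standardization(self, truth_pair):
        th, tw = truth_pair
        coefs = np.array([0.002, -0.65, 0.1, 0.004, 0.3, -0.08])
        out = simulate_outcomes(th, tw, coefs, 0.0, 0.2, seed=7)
        res_raw = associate(out, _re_list(th), _re_list(tw), "Model1", "log_outcome")
        # standardize the height random effects by scaling
        th_scaled = [RandomEffects(b.subject_id, b.size / 5.7, b.tempo / 0.055,
                                   b.velocity / 0.09) for b in _re_list(th)]
        res_std = associate(out, th_scaled, _re_list(tw), "Model1", "log_outcome")
        for n in ("height_size", "height_tempo", "height_velocity"):
            assert res_std.tvalues[n] == pytest.approx(res_raw.tvalues[n], rel=1e-8)

    def test_model2_raw_r2_not_smaller(self, truth_pair):
        th, tw = truth_pair
        coefs = np.array([0.002, -0.65, 0.1, 0.004, 0.3, -0.08])
        out = simulate_outcomes(th, tw, coefs, 0.0, 0.2, seed=8)
        r1 = associate(out, _re_list(th), _re_list(tw), "Model1", "log_outcome")
        r2 = associate(out, _re_list(th), _re_list(tw), "Model2", "log_outcome")
        assert r2.r2 >= r1.r2 - 1e-12

    def test_unknown_model_rejected(self, truth_pair):
        th, tw = truth_pair
        out = simulate_outcomes(th, tw, np.zeros(6), 0.0, 0.3, seed=9)
        with pytest.raises(ValueError):
            associate(out, _re_list(th), _re_list(tw), "Model3", "log_outcome")


class TestTimingCorrelations:
    def test_planted_correlation_recovered(self, truth_pair):
        th, _ = truth_pair
        timing = simulate_timing(th, 0.55, seed=11)
        tmap = dict(zip(th.subject_ids, timing))
        tab = correlate_re_timing({"height": _re_list(th)}, tmap)
        row = tab[(tab.set == "height") & (tab.parameter == "tempo")
                  & (tab.sex == "all")]
        assert row.correlation.iloc[0] == pytest.approx(0.55, abs=0.08)

    def test_independent_timing_uncorrelated(self, truth_pair):
        th, _ = truth_pair
        rng = np.random.default_rng(12)
        tmap = {s: rng.standard_normal() for s in th.subject_ids}
        tab = correlate_re_timing({"height": _re_list(th)}, tmap)
        n = len(th.subject_ids)
        assert (np.abs(tab.correlation) < 3 / np.sqrt(n)).all()

    def test_too_few_cases(self, truth_pair):
        th, _ = truth_pair
        with pytest.raises(ValueError):
            correlate_re_timing({"h": _re_list(th)[:2]},
                                {s: 0.0 for s in th.subject_ids[:2]})


class TestCompareFits:
    def test_fit_with_itself_is_perfect(self, dense_fit_small):
        fit, _ = dense_fit_small
        tab = compare_fits(fit, fit, "dense")
        assert np.allclose(tab["blup_correlation"], 1.0)
        assert np.allclose(tab["sd_ratio"], 1.0)

    def test_missing_cohort_rejected(self, dense_fit_small):
        fit, _ = dense_fit_small
        with pytest.raises(ValueError):
            compare_fits(fit, fit, "nope")
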