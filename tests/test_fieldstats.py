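import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit, logit

import graywhale_sdp as g
from graywhale_sdp import fieldstats as fs

FAST = dict(n_walkers=24, n_steps=500, n_burn=200)


class TestZibLoglik:
    def test_all_zero_branch(self):
        ll = g.zib_loglik(np.zeros(7), alpha=0.3, mu=0.5, phi=2.0)
        assert ll == pytest.approx(7 * math.log(0.7))

    def test_uniform_beta_case(self):
        # Beta(mean 0.5, precision 2) is Beta(1, 1): the uniform density
        ll = g.zib_loglik(np.array([0.5]), alpha=0.4, mu=0.5, phi=2.0)
        assert ll == pytest.approx(math.log(0.4))

    def test_value_one_outside_support(self):
        with pytest.raises(ValueError):
            g.zib_loglik(np.array([1.0]), 0.5, 0.5, 2.0)

    def test_density_normalizes(self):
        alpha, mu, phi = 0.65, 0.3, 7.5
        pdf = lambda y: math.exp(g.zib_loglik(np.array([y]), alpha, mu, phi))
        cont, _ = integrate.quad(pdf, 1e-12, 1 - 1e-12)
        atom = math.exp(g.zib_loglik(np.array([0.0]), alpha, mu, phi))
        assert atom + cont == pytest.approx(1.0, abs=1e-6)


class TestHurdleGammaLoglik:
    def test_all_zero_branch(self):
        ll = g.hurdle_gamma_loglik(np.zeros(5), 0.25, 1.0, 2.0)
        assert ll == pytest.approx(5 * math.log(0.75))

    def test_exponential_case_at_mean(self):
        # shape omega=1 is exponential with rate 1/mu
        mu = 3.0
        ll = g.hurdle_gamma_loglik(np.array([mu]), 0.6, mu, 1.0)
        assert ll == pytest.approx(math.log(0.6) + math.log(math.exp(-1) / mu))

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            g.hurdle_gamma_loglik(np.array([-0.1]), 0.5, 1.0, 1.0)

    def test_density_normalizes(self):
        alpha, mu, om = 0.45, 2.0, 3.0
        pdf = lambda y: math.exp(
            g.hurdle_gamma_loglik(np.array([y]), alpha, mu, om))
        cont, _ = integrate.quad(pdf, 1e-12, 60, limit=200)
        atom = math.exp(g.hurdle_gamma_loglik(np.array([0.0]), alpha, mu, om))
        assert atom + cont == pytest.approx(1.0, abs=1e-6)


class TestCohensD:
    def test_hand_computation_large(self):
        es = g.cohens_d(1.0, 0.5, 30, 0.5, 0.5, 30)
        assert es.d == pytest.approx(1.0)
        assert es.category == "large"

    def test_equal_means(self):
        es = g.cohens_d(0.3, 0.1, 10, 0.3, 0.2, 10)
        assert es.d == 0.0 and es.category == "none"

    def test_antisymmetry(self):
        a = g.cohens_d(1.2, 0.4, 12, 0.7, 0.3, 15)
        b = g.cohens_d(0.7, 0.3, 15, 1.2, 0.4, 12)
        assert a.d == pytest.approx(-b.d)

    def test_zero_sd_cases(self):
        assert g.cohens_d(1.0, 0.0, 5, 1.0, 0.0, 5).d == 0.0
        es = g.cohens_d(1.0, 0.0, 5, 0.0, 0.0, 5)
        assert es.infinite and math.isinf(es.d)

    @pytest.mark.parametrize("d,cat", [
        (0.19, "none"), (0.2, "small"), (0.49, "small"), (0.5, "intermediate"),
        (0.79, "intermediate"), (0.8, "large"), (-0.6, "intermediate"),
    ])
    def test_category_boundaries(self, d, cat):
        assert fs.classify_effect(d) == cat


class TestReproductiveBookkeeping:
    def test_known_reproductive_females(self):
        assert round(g.reproductive_rate(27, 11, 14), 2) == 0.88

    def test_including_extra_females(self):
        assert round(g.reproductive_rate(33, 11, 14), 2) == 0.64

    def test_no_calves(self):
        assert g.reproductive_rate(20, 0, 0) == 0.0

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            g.reproductive_rate(11, 11, 5)

    def test_mother_match_percentages(self):
        assert g.mother_match_fraction(9, 11) == 82
        assert g.mother_match_fraction(8, 14) == 57
        assert g.mother_match_fraction(0, 9) == 0
        with pytest.raises(ValueError):
            g.mother_match_fraction(1, 0)


class TestBlockAggregation:
    def test_single_block_identity(self):
        df = pd.DataFrame({"survey_id": [0], "cell": [3], "density": [2.0],
                           "area_km2": [1.0]})
        out = g.aggregate_block_density(df)
        assert out["density"].iloc[0] == pytest.approx(2.0)

    def test_weighted_hand_computation(self):
        df = pd.DataFrame({"survey_id": 0, "cell": 3,
                           "density": [2.0, 1.0], "area_km2": [0.5, 1.5]})
        out = g.aggregate_block_density(df)
        assert out["density"].iloc[0] == pytest.approx(1.25)

    def test_missing_cell_absent_not_zero(self):
        df = pd.DataFrame({"survey_id": [0], "cell": [3], "density": [1.0],
                           "area_km2": [1.0]})
        out = g.aggregate_block_density(df)
        assert set(out["cell"]) == {3}

    def test_repartition_invariance(self, rng):
        base = pd.DataFrame({"survey_id": 0, "cell": 5,
                             "density": [1.2, 0.4], "area_km2": [2.0, 1.0]})
        # split each block into random sub-blocks preserving counts
        rows = []
        for r in base.itertuples():
            w = rng.dirichlet(np.ones(3))
            for frac in w:
                rows.append({"survey_id": 0, "cell": 5, "density": r.density,
                             "area_km2": r.area_km2 * frac})
        split = pd.DataFrame(rows)
        a = g.aggregate_block_density(base)["density"].iloc[0]
        b = g.aggregate_block_density(split)["density"].iloc[0]
        assert a == pytest.approx(b)


class TestDensityScaling:
    def test_field_side_identity_when_all_pregnant(self):
        d = pd.DataFrame({"cell": [1, 1], "week": [4, 5],
                          "density": [0.4, 0.2]})
        p = pd.DataFrame({"week": [4, 5], "p_preg": [1.0, 1.0]})
        out = fs.field_pregnant_density(d, p)
        np.testing.assert_allclose(out["d_preg"], [0.4, 0.2])

    def test_model_side_arithmetic(self, area):
        wc = pd.DataFrame({"cell": [1], "week": [4], "mean": [0.2]})
        out = fs.model_pregnant_density(wc, n_group=10, area=area)
        assert out["d_preg"].iloc[0] == pytest.approx(
            0.2 * 10 / area.cell(1).area_km2)


class TestRegressions:
    def test_logit_intercept_recovery(self, rng):
        n = 400
        X = np.column_stack([np.ones(n)])
        y = np.column_stack([rng.binomial(20, 0.25, n), np.full(n, 20.0)])
        m = fs.BinomialLogitRegression(seed=1, **FAST).fit(X, y)
        assert m.draws_[:, 0].mean() == pytest.approx(logit(0.25), abs=0.1)
        assert m.converged_

    def test_ushaped_week_sign_recovered(self, rng, truth, season):
        from graywhale_sdp.synth import gen_ppreg_daily

        daily = gen_ppreg_daily(truth, season, rng, n_days=150)
        m = g.fit_ppreg(daily, seed=2, **FAST)
        # truth has a positive week^2 coefficient (U shape over season)
        i = m.param_names_.index("week2")
        assert m.draws_[:, i].mean() > 0

    def test_zib_all_zero_data(self, rng):
        days = pd.DataFrame({
            "p_near": np.zeros(40),
            "week": rng.integers(0, 25, 40),
            "beaufort": rng.uniform(0, 4, 40),
            "visibility": rng.uniform(0.3, 1, 40),
        })
        m = g.fit_zib(days, seed=3, **FAST)
        alpha = expit(m.draws_[:, 0])  # intercept at mean covariates ~ alpha
        assert np.quantile(alpha, 0.9) < 0.2

    def test_zib_null_week_coefficient(self, rng):
        n = 250
        days = pd.DataFrame({
            "week": rng.integers(0, 25, n),
            "beaufort": rng.uniform(0, 4, n),
            "visibility": rng.uniform(0.3, 1, n),
        })
        alpha, mu, phi = 0.7, 0.25, 12.0
        nz = rng.uniform(size=n) < alpha
        p = np.where(nz, rng.beta(mu * phi, (1 - mu) * phi, n), 0.0)
        days["p_near"] = p
        m = g.fit_zib(days, seed=4, **FAST)
        i = m.param_names_.index("alpha_week")
        draws = m.draws_[:, i]
        assert abs(draws.mean()) < 2 * draws.std()

    def test_hurdle_gamma_coverage_effect_sign(self, rng, truth, season):
        from graywhale_sdp.synth import gen_scan_surveys

        area = g.StudyArea.default()
        scans = gen_scan_surveys(truth, area, season, rng, n_surveys=250)
        agg = g.aggregate_block_density(scans)
        fits = g.fit_hurdle_gamma(agg[agg.cell == 3], seed=5, **FAST)
        info = fits[3]
        assert info["kind"] == "full"
        m = info["fit"]
        i = m.param_names_.index("alpha_coverage")
        # occupancy odds rise with the fraction of the cell covered
        assert m.draws_[:, i].mean() > 0

    def test_degenerate_design_flagged(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), np.zeros(n)])  # zero-variance column
        y = np.column_stack([rng.binomial(10, 0.4, n), np.full(n, 10.0)])
        m = fs.BinomialLogitRegression(seed=6, **FAST).fit(X, y)
        assert m.prior_truncated_ or not m.converged_

    def test_ppreg_drops_zero_totals(self, rng, truth, season):
        from graywhale_sdp.synth import gen_ppreg_daily

        daily = gen_ppreg_daily(truth, season, rng, n_days=60)
        daily.loc[:3, "n_identified"] = 0
        daily.loc[:3, "n_pregnant"] = 0
        m = g.fit_ppreg(daily, seed=7, **FAST)
        assert m.n_features_in_ == 5

    def test_fit_zib_needs_enough_days(self):
        with pytest.raises(ValueError):
            g.fit_zib(pd.DataFrame({"p_near": [0.1], "week": [1],
                                    "beaufort": [1.0], "visibility": [0.5]}))
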