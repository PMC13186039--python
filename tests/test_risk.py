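"""Risk engine: dose algebra, Monte Carlo propagation, adjustment
comparison, sensitivity analysis, lognormal fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cdbiorisk as cb

TOX = cb.DEFAULT_TOXICITY


def make_ctx(**over):
    base = dict(C=1.0, BA=1.0, IngR=100.0, InhR=14.5, EF=350.0, ED=6.0,
                BW=15.0, AT=2190.0, SA=2800.0, AF=0.2, ABF=0.001, PEF=1.36e9)
    base.update(over)
    return cb.ExposureContext(**base)


class TestDailyDoses:
    def test_hand_computed_ingestion_dose(self):
        add_ing, _, _ = cb.compute_daily_doses(make_ctx())
        expected = (1 * 1 * 100 * 1e-6 * 350 * 6) / (15 * 2190)
        assert add_ing == pytest.approx(6.3927e-6, rel=1e-4)
        assert add_ing == pytest.approx(expected, rel=1e-12)

    def test_zero_bioaccessibility_only_zeroes_ingestion(self):
        full = cb.compute_daily_doses(make_ctx())
        ba0 = cb.compute_daily_doses(make_ctx(BA=1e-300))
        assert ba0[0] == pytest.approx(0.0, abs=1e-30)
        assert ba0[1] == full[1] and ba0[2] == full[2]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), scale=st.floats(0.1, 10.0))
    def test_linear_in_concentration(self, c, scale):
        d1 = cb.compute_daily_doses(make_ctx(C=c))
        d2 = cb.compute_daily_doses(make_ctx(C=c * scale))
        for a, b in zip(d1, d2):
            assert b == pytest.approx(a * scale, rel=1e-12)

    def test_zero_body_weight_rejected(self):
        with pytest.raises(ValueError):
            cb.compute_daily_doses(dict(C=1, BA=1, IngR=1, InhR=1, EF=1, ED=1,
                                        BW=0, AT=1, SA=1, AF=1, ABF=1, PEF=1))


class TestRiskIndices:
    def test_hq_threshold_case(self):
        tox = cb.ToxicityValues(rfd={"ingestion": 2.5e-4})
        hq, cr = cb.compute_risk_indices((2.5e-4, 0.0, 0.0), tox)
        assert hq == pytest.approx(1.0, rel=1e-12)
        assert cr == 0.0

    def test_hand_computed_cr(self):
        tox = cb.ToxicityValues(sf={"ingestion": 6.1})
        _, cr = cb.compute_risk_indices((1e-4, 0.0, 0.0), tox)
        assert cr == pytest.approx(6.1e-4, rel=1e-12)

    def test_zero_doses(self):
        hq, cr = cb.compute_risk_indices((0.0, 0.0, 0.0), TOX)
        assert hq == 0.0 and cr == 0.0

    def test_nonpositive_rfd_rejected(self):
        with pytest.raises(ValueError):
            cb.ToxicityValues(rfd={"ingestion": 0.0})


class TestFitLognormal:
    def test_degenerate_constant_sample(self):
        spec, report = cb.fit_lognormal([3.0, 3.0, 3.0])
        assert spec.p1 == pytest.approx(np.log(3.0))
        assert spec.p2 == 0.0
        assert report["qq_r"] == 1.0

    def test_hand_computed_two_point_moments(self):
        spec, _ = cb.fit_lognormal([np.e, np.e ** 3, np.e, np.e ** 3])
        assert spec.p1 == pytest.approx(2.0)
        # sd of {1,3,1,3} with ddof=1
        assert spec.p2 == pytest.approx(np.std([1, 3, 1, 3], ddof=1))

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1.2, 0.6, 10_000)
        spec, report = cb.fit_lognormal(x)
        assert spec.p1 == pytest.approx(1.2, rel=0.02)
        assert spec.p2 == pytest.approx(0.6, rel=0.02)
        assert report["qq_r"] > 0.99

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cb.fit_lognormal([1.0, -1.0, 2.0])


class TestMonteCarlo:
    def test_point_masses_reproduce_deterministic_result(self, point_specs):
        res = cb.run_monte_carlo(point_specs, TOX, n_iter=200, seed=0)
        add = cb.compute_daily_doses(make_ctx())
        hq, cr = cb.compute_risk_indices(add, TOX)
        np.testing.assert_allclose(res.add_ing, add[0], rtol=1e-12)
        np.testing.assert_allclose(res.hq, hq, rtol=1e-12)
        np.testing.assert_allclose(res.cr, cr, rtol=1e-12)

    def test_same_seed_identical_draws(self):
        specs = cb.generate_exposure_distributions("adult")
        specs["C"] = cb.DistributionSpec("C", "lognormal", 0.0, 0.5)
        a = cb.run_monte_carlo(specs, TOX, n_iter=500, seed=42)
        b = cb.run_monte_carlo(specs, TOX, n_iter=500, seed=42)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_missing_spec_named(self, point_specs):
        specs = dict(point_specs)
        del specs["PEF"]
        with pytest.raises(ValueError, match="PEF"):
            cb.run_monte_carlo(specs, TOX, n_iter=200, seed=0)

    def test_mc_mean_matches_analytic_product(self, point_specs):
        # C lognormal and IngR lognormal, everything else fixed:
        # E[ADD_ing] is the product of the means (independence)
        specs = dict(point_specs)
        specs["C"] = cb.DistributionSpec("C", "lognormal", 0.5, 0.4)
        specs["IngR"] = cb.DistributionSpec("IngR", "lognormal",
                                            np.log(100), 0.3)
        res = cb.run_monte_carlo(specs, TOX, n_iter=20_000, seed=1)
        mean_c = np.exp(0.5 + 0.4 ** 2 / 2)
        mean_ingr = np.exp(np.log(100) + 0.3 ** 2 / 2)
        analytic = mean_c * mean_ingr * 1e-6 * 350 * 6 / (15 * 2190)
        se = res.add_ing.std(ddof=1) / np.sqrt(res.n_iter)
        assert abs(res.add_ing.mean() - analytic) < 3 * se

    def test_truncation_respected(self):
        spec = cb.DistributionSpec("BW", "normal", 60, 30, lower=40, upper=80)
        draws = spec.sample(np.random.default_rng(0), 5000)
        assert draws.min() >= 40 and draws.max() <= 80

    def test_impossible_truncation_errors(self):
        spec = cb.DistributionSpec("X", "normal", 0, 1e-4, lower=50, upper=51)
        with pytest.raises(RuntimeError, match="rejection"):
            spec.sample(np.random.default_rng(0), 1000)

    def test_homogeneity_in_c_and_ba(self, point_specs):
        res = cb.run_monte_carlo(point_specs, TOX, n_iter=100, seed=0)
        for par, col in (("C", "C"), ("BA", "BA")):
            specs2 = dict(point_specs)
            specs2[par] = cb.DistributionSpec(par, "point",
                                              point_specs[par].p1 * 2.0)
            res2 = cb.run_monte_carlo(specs2, TOX, n_iter=100, seed=0)
            if par == "C":
                np.testing.assert_allclose(res2.cr, 2.0 * res.cr, rtol=1e-12)
                np.testing.assert_allclose(res2.hq, 2.0 * res.hq, rtol=1e-12)
            else:
                np.testing.assert_allclose(res2.add_ing, 2.0 * res.add_ing,
                                           rtol=1e-12)


class TestSummaries:
    def test_constant_draws(self, point_specs):
        res = cb.run_monte_carlo(point_specs, TOX, n_iter=150, seed=0)
        s = cb.summarize_risk(res)
        assert s.loc["HQ", "cv_percent"] == pytest.approx(0.0)
        assert s.loc["HQ", "p95"] == pytest.approx(s.loc["HQ", "mean"])

    def test_percentile_rule_on_known_sequence(self):
        y = np.arange(1.0, 101.0)
        p95 = np.percentile(y, 95, method="linear")
        assert 95.0 <= p95 <= 96.0

    def test_exceedance_probabilities(self, point_specs):
        res = cb.run_monte_carlo(point_specs, TOX, n_iter=150, seed=0)
        s = cb.summarize_risk(res)
        assert s.loc["HQ", "p_exceed"] == 0.0  # HQ << 1 here
        assert 0.0 <= s.loc["CR", "p_exceed"] <= 1.0
        assert (s.loc["HQ", ["p5", "p25", "p50", "p75", "p95"]].diff()
                .dropna() >= 0).all()

    def test_child_risk_exceeds_adult(self):
        tox = TOX
        c = cb.DistributionSpec("C", "lognormal", np.log(2.0), 0.5,
                                lower=1e-3, upper=1e4)
        out = {}
        for pop in ("adult", "child"):
            specs = cb.generate_exposure_distributions(pop)
            specs["C"] = c
            res = cb.run_monte_carlo(specs, tox, n_iter=4000, seed=11)
            out[pop] = cb.summarize_risk(res)
        assert out["child"].loc["HQ", "p50"] > out["adult"].loc["HQ", "p50"]
        assert out["child"].loc["CR", "p50"] > out["adult"].loc["CR", "p50"]


class TestCompareAdjustment:
    def _specs(self):
        vals = dict(C=5.0, IngR=100.0, InhR=0.0, EF=350.0, ED=6.0, BW=15.0,
                    AT=2190.0, SA=0.0, AF=0.0, ABF=0.0, PEF=1.36e9)
        specs = {p: cb.DistributionSpec(p, "point", v) for p, v in vals.items()}
        specs["C"] = cb.DistributionSpec("C", "lognormal", np.log(5), 0.6)
        specs["BA"] = cb.DistributionSpec("BA", "point", 1.0)
        return specs

    def test_point_mass_ba_gives_exact_fivefold_reduction(self):
        ba = cb.DistributionSpec("BA", "point", 0.2, lower=0.01, upper=1.0)
        out = cb.compare_adjustment(self._specs(), TOX, ba, n_iter=2000, seed=3)
        for metric in ("HQ", "CR"):
            assert out.loc[metric, "mean_ratio"] == pytest.approx(5.0, rel=1e-12)
            assert out.loc[metric, "p95_ratio"] == pytest.approx(5.0, rel=1e-12)

    def test_ba_one_is_identity(self):
        ba = cb.DistributionSpec("BA", "point", 1.0, lower=0.5, upper=1.0)
        out = cb.compare_adjustment(self._specs(), TOX, ba, n_iter=1000, seed=1)
        assert out["mean_ratio"].to_numpy() == pytest.approx(1.0)
        assert out["p95_decrease_percent"].to_numpy() == pytest.approx(0.0)

    def test_stochastic_ba_never_increases_percentiles(self):
        ba = cb.DistributionSpec("BA", "lognormal", np.log(0.2), 0.5,
                                 lower=1e-4, upper=1.0)
        out = cb.compare_adjustment(self._specs(), TOX, ba, n_iter=3000, seed=7)
        assert (out["p95_adjusted"] <= out["p95_unadjusted"]).all()
        assert (out["mean_ratio"] >= 1.0).all()

    def test_unsupported_ba_rejected(self):
        ba = cb.DistributionSpec("BA", "uniform", 0.5, 1.5)
        with pytest.raises(ValueError):
            cb.compare_adjustment(self._specs(), TOX, ba, n_iter=500, seed=0)


class TestVarianceContributions:
    def test_single_stochastic_input_gets_everything(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 2000)
        inputs = pd.DataFrame({"C": x, "BW": np.full(2000, 60.0)})
        with pytest.warns(UserWarning, match="constant"):
            out = cb.variance_contributions(inputs, 3.0 * x)
        assert out.loc["C", "contribution_percent"] == pytest.approx(100.0)
        assert out.loc["BW", "contribution_percent"] == 0.0

    def test_symmetric_sum_splits_evenly(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"X1": rng.normal(size=10_000),
                          "X2": rng.normal(size=10_000)})
        out = cb.variance_contributions(X, X["X1"] + X["X2"])
        assert out.loc["X1", "contribution_percent"] == pytest.approx(50, abs=3)
        assert out.loc["X2", "contribution_percent"] == pytest.approx(50, abs=3)

    def test_contributions_sum_to_hundred(self):
        specs = cb.generate_exposure_distributions("child")
        specs["C"] = cb.DistributionSpec("C", "lognormal", 0.0, 0.5)
        res = cb.run_monte_carlo(specs, TOX, n_iter=2000, seed=5)
        with pytest.warns(UserWarning):
            out = res.sensitivity("CR")
        assert out["contribution_percent"].sum() == pytest.approx(100.0,
                                                                  abs=0.1)
        assert (out["contribution_percent"] >= 0).all()

    def test_signs_reported(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=3000)
        out = cb.variance_contributions(pd.DataFrame({"up": x, "down": -x}),
                                        x)
        assert out.loc["up", "sign"] == 1
        assert out.loc["down", "sign"] == -1
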