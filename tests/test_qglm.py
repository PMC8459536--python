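"""Quasibinomial IRLS: closed forms, a frozen R oracle, and model simplification.

The frozen reference values below were produced by R's
``glm(cbind(k, n-k) ~ gd + pop, family = quasibinomial)`` with
``summary()`` and ``anova(..., test = "F")`` on the small dataset defined
in ``_oracle_data`` (R 4.3, stats package).
"""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from haplocross import DesignSpec, fit, gd_only_fit, sequential_f_tests, simplify_and_refit
from haplocross.indices import BarrierObservation
from haplocross.qglm import RankDeficiencyError, build_design
from haplocross.simulate import BarrierParams, SimulationConfig, simulate_study
from haplocross import observations, table2_fixture


def _obs(ks, ns, gds, pops, barrier="prezygotic"):
    return tuple(
        BarrierObservation(barrier, k, n, g, p)
        for k, n, g, p in zip(ks, ns, gds, pops)
    )


def _oracle_data():
    return _obs(
        ks=[12, 30, 25, 48, 5, 7, 19, 33, 9, 41, 16, 28],
        ns=[100, 110, 90, 120, 80, 95, 100, 105, 85, 115, 92, 101],
        gds=[0.00, 0.02, 0.05, 0.075, 0.00, 0.018, 0.05, 0.068,
             0.00, 0.061, 0.05, 0.063],
        pops=list("AAAABBBBCCCC"),
    )


class TestClosedForms:
    def test_intercept_only_is_sample_logit(self):
        obs = _obs([30, 30], [100, 100], [0.0, 0.0], ["A", "A"])
        f = fit(DesignSpec("prezygotic", ("intercept",), obs))
        assert f.coef("intercept") == pytest.approx(-0.8472978603872034, abs=1e-9)

    def test_two_point_saturated_model_exact(self):
        obs = _obs([10, 90], [100, 100], [0.0, 0.1], ["A", "A"])
        f = gd_only_fit(obs)
        np.testing.assert_allclose(f.predict_gd([0.0, 0.1]), [0.10, 0.90], atol=1e-9)
        assert f.deviance == pytest.approx(0.0, abs=1e-9)

    def test_score_equations_at_fixed_point(self):
        obs = _oracle_data()
        design = DesignSpec("prezygotic", ("intercept", "gd", "female_pop"), obs)
        f = fit(design)
        X, _, k, n = build_design(obs, design.terms)
        eta = X @ f.beta
        resid = k - n * expit(eta)
        assert np.max(np.abs(X.T @ resid)) < 1e-8


@pytest.fixture(scope="module")
def fitted():
    design = DesignSpec("prezygotic", ("intercept", "gd", "female_pop"),
                        _oracle_data())
    return fit(design), sequential_f_tests(design)


class TestAgainstFrozenROracle:
    """Estimates, SEs, t, dispersion, deviance and sequential F vs R stats::glm."""

    R_BETA = [-1.859331561006801, 21.338904573122949,
              -0.616841120680446, -0.344900897877413]
    R_SE = [0.231037538575398, 3.875811570389956,
            0.237645287519598, 0.219804150921037]
    R_T = [-8.04774658036799, 5.50566099140263, -2.59563792372519, -1.56912822816215]
    R_DISPERSION = 1.74182306191074
    R_DEVIANCE = 13.7592461388055
    R_F = {"gd": 34.5844195757762, "female_pop": 3.53456437872518}
    R_P = {"gd": 0.000369645888449705, "female_pop": 0.0794341720398543}

    def test_coefficients(self, fitted):
        f, _ = fitted
        np.testing.assert_allclose(f.beta, self.R_BETA, rtol=1e-7)

    def test_standard_errors_and_t(self, fitted):
        f, _ = fitted
        np.testing.assert_allclose(f.se, self.R_SE, rtol=1e-7)
        np.testing.assert_allclose(f.t, self.R_T, rtol=1e-7)

    def test_dispersion_and_deviance(self, fitted):
        f, _ = fitted
        assert f.dispersion == pytest.approx(self.R_DISPERSION, rel=1e-7)
        assert f.deviance == pytest.approx(self.R_DEVIANCE, rel=1e-7)
        assert f.df_residual == 8

    def test_sequential_f_table(self, fitted):
        _, tests = fitted
        by_term = {t.term: t for t in tests}
        for term in ("gd", "female_pop"):
            assert by_term[term].f == pytest.approx(self.R_F[term], rel=1e-6)
            assert by_term[term].p_value == pytest.approx(self.R_P[term], rel=1e-6)
        assert by_term["gd"].df1 == 1 and by_term["female_pop"].df1 == 2
        assert by_term["gd"].df2 == 8


class TestInvariants:
    def test_dispersion_does_not_move_estimates(self):
        """Quasi inference rescales se/t only; beta equals the binomial MLE."""
        import statsmodels.api as sm

        obs = _oracle_data()
        X, _, k, n = build_design(obs, ("intercept", "gd", "female_pop"))
        ref = sm.GLM(np.column_stack([k, n - k]), X,
                     family=sm.families.Binomial()).fit()
        f = fit(DesignSpec("prezygotic", ("intercept", "gd", "female_pop"), obs))
        np.testing.assert_allclose(f.beta, ref.params, rtol=1e-7)

    def test_deviance_nonincreasing_along_sequence(self):
        obs = _oracle_data()
        devs = []
        for terms in [("intercept",), ("intercept", "gd"),
                      ("intercept", "gd", "female_pop")]:
            devs.append(fit(DesignSpec("prezygotic", terms, obs)).deviance)
        assert devs[0] >= devs[1] >= devs[2]

    def test_beta_invariant_to_disaggregation(self):
        agg = _obs([30, 60], [100, 120], [0.0, 0.05], ["A", "A"])
        split = _obs([10, 20, 25, 35], [40, 60, 50, 70],
                     [0.0, 0.0, 0.05, 0.05], ["A", "A", "A", "A"])
        np.testing.assert_allclose(gd_only_fit(agg).beta, gd_only_fit(split).beta,
                                   atol=1e-8)

    def test_zero_deviance_term_gives_f_zero_p_one(self):
        # populations with identical response patterns: the pop term's MLE is
        # exactly zero, so its deviance reduction vanishes
        obs = _obs([10, 30, 10, 30], [50, 50, 50, 50],
                   [0.0, 0.05, 0.0, 0.05], ["A", "A", "B", "B"])
        tests = sequential_f_tests(
            DesignSpec("prezygotic", ("intercept", "gd", "female_pop"), obs))
        pop_test = next(t for t in tests if t.term == "female_pop")
        assert pop_test.f == pytest.approx(0.0, abs=1e-6)
        assert pop_test.p_value == pytest.approx(1.0, abs=1e-4)


class TestDegenerateDesigns:
    def test_all_zero_gd_names_aliased_term(self):
        obs = _obs([10, 20, 30], [50, 50, 50], [0.0, 0.0, 0.0], ["A", "A", "A"])
        with pytest.raises(RankDeficiencyError, match="gd"):
            gd_only_fit(obs)

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="interaction"):
            DesignSpec("prezygotic", ("intercept", "gd:female_pop"),
                       _obs([1], [2], [0.0], ["A"]) * 2)

    def test_single_population_routes_to_gd_only(self):
        obs = _obs([5, 15, 30, 40], [50, 50, 50, 50],
                   [0.0, 0.02, 0.05, 0.075], ["A"] * 4)
        report = simplify_and_refit(
            DesignSpec("prezygotic", ("intercept", "gd"), obs))
        assert report.route == "gd_only"
        assert set(report.main_fit.names) == {"intercept", "gd"}


class TestSimplificationRouting:
    def _records(self, seed, pre):
        cfg = SimulationConfig(seed=seed, prezygotic=pre)
        return [r for r in simulate_study(cfg) if r.cross_class != "backcross"]

    def test_heterogeneous_slopes_route_to_per_population(self, table2):
        """Some populations with steep slopes, others flat: interaction detected."""
        hits = 0
        for seed in range(8):
            cfg = SimulationConfig(seed=seed)
            recs = simulate_study(cfg)
            # overwrite prezygotic response: steep for CIM/CN/K females, flat else
            obs = []
            rng = np.random.default_rng(1000 + seed)
            for r in recs:
                if r.cross_class == "backcross":
                    continue
                gd = table2.lookup(r.female_pop, r.male_pop)
                slope = 40.0 if r.female_pop in ("CIM", "CN", "K") else 0.0
                p = expit(-1.45 + slope * gd)
                obs.append(BarrierObservation(
                    "prezygotic", int(rng.binomial(r.eggs, p)), r.eggs, gd,
                    r.female_pop))
            report = simplify_and_refit(
                DesignSpec("prezygotic",
                           ("intercept", "gd", "female_pop", "gd:female_pop"),
                           tuple(obs)))
            if report.route == "per_population":
                hits += 1
                assert set(report.per_population) == set(table2.labels)
        assert hits >= 6

    def test_common_slope_routes_to_main_effects(self):
        taken = 0
        for seed in range(10):
            recs = self._records(seed, BarrierParams(-1.453, 12.728))
            obs = observations(recs, table2_fixture(), "prezygotic")
            report = simplify_and_refit(
                DesignSpec("prezygotic",
                           ("intercept", "gd", "female_pop", "gd:female_pop"),
                           tuple(obs)))
            if report.route == "main_effects":
                taken += 1
        assert taken >= 8  # interaction should rarely be (falsely) significant


class TestCalibration:
    def test_null_gd_rejection_rate_near_alpha(self):
        """Type-I error of the sequential gd test under a flat barrier curve."""
        n_rep, alpha = 400, 0.05
        rejections = 0
        flat = BarrierParams(-1.3, 0.0)
        for seed in range(n_rep):
            cfg = SimulationConfig(seed=seed, prezygotic=flat)
            recs = [r for r in simulate_study(cfg) if r.cross_class != "backcross"]
            obs = observations(recs, cfg.distances, "prezygotic")
            tests = sequential_f_tests(
                DesignSpec("prezygotic", ("intercept", "gd"), tuple(obs)))
            if tests[0].p_value < alpha:
                rejections += 1
        rate = rejections / n_rep
        # binomial 99% bounds around alpha at n_rep replicates
        half = 2.576 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < half + 0.01

    def test_power_against_strong_slope(self):
        rejections = 0
        for seed in range(60):
            cfg = SimulationConfig(seed=10_000 + seed,
                                   prezygotic=BarrierParams(-1.3, 40.0))
            recs = [r for r in simulate_study(cfg) if r.cross_class != "backcross"]
            obs = observations(recs, cfg.distances, "prezygotic")
            tests = sequential_f_tests(
                DesignSpec("prezygotic", ("intercept", "gd"), tuple(obs)))
            if tests[0].p_value < 0.05:
                rejections += 1
        assert rejections / 60 > 0.9

    def test_parameter_recovery_study_layout(self):
        """gd-only estimates recover (-1.3, 40) within 3 simulation SEs."""
        betas = []
        for seed in range(120):
            cfg = SimulationConfig(seed=20_000 + seed,
                                   prezygotic=BarrierParams(-1.3, 40.0))
            recs = [r for r in simulate_study(cfg) if r.cross_class != "backcross"]
            obs = observations(recs, cfg.distances, "prezygotic")
            betas.append(gd_only_fit(obs).beta)
        betas = np.asarray(betas)
        mean, se = betas.mean(axis=0), betas.std(axis=0, ddof=1) / math.sqrt(len(betas))
        assert abs(mean[0] - (-1.3)) < 3 * se[0]
        assert abs(mean[1] - 40.0) < 3 * se[1]
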