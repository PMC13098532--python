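"""Skill-formation model: shapes, optimization, decomposition, calibration."""

from dataclasses import replace

import numpy as np
import pytest

from gxekit.structural import (
    SkillParams,
    calibrate_to_cohort,
    decompose_gxe,
    entry_skills,
    implied_stage_effects,
    optimal_investment,
    treatment_effect,
    value_treatment_gradient_oracle,
    welfare_gradient,
)


@pytest.fixture(scope="module")
def params():
    return SkillParams()


class TestShapes:
    def test_production_shape_assumptions_on_grid(self, params):
        """theta_tau increasing and concave in entry skills and in G."""
        h = 1e-4
        for g in np.linspace(-2.5, 2.5, 7):
            for th in np.linspace(1.2, 5.0, 7):
                f = lambda t_, g_: float(params.theta_tau(t_, g_, 5))
                d_th = (f(th + h, g) - f(th - h, g)) / (2 * h)
                d2_th = (f(th + h, g) - 2 * f(th, g) + f(th - h, g)) / h**2
                d_g = (f(th, g + h) - f(th, g - h)) / (2 * h)
                d2_g = (f(th, g + h) - 2 * f(th, g) + f(th, g - h)) / h**2
                assert d_th > 0 and d_g > 0
                assert d2_th < 0 and d2_g < 0

    def test_entry_skills_monotone_in_g_and_investment(self, params):
        gg = np.linspace(-2, 2, 9)
        th4 = entry_skills(gg, 0.0, 4, params)
        assert np.all(np.diff(th4) > 0)
        th5_low = entry_skills(0.0, 0.5, 5, params)
        th5_high = entry_skills(0.0, 1.0, 5, params)
        assert th5_high > th5_low
        # finite-difference vs analytic investment derivative
        h = 1e-6
        fd = (entry_skills(0.0, 1.0 + h, 5, params) - entry_skills(0.0, 1.0 - h, 5, params)) / (2 * h)
        analytic = (params.a0) * params.alpha * 1.0 ** (params.alpha - 1)
        assert fd == pytest.approx(analytic, rel=1e-4)

    def test_no_growth_without_inputs(self):
        p = SkillParams(m5=0.0)
        assert entry_skills(0.5, 0.0, 5, p) == pytest.approx(
            entry_skills(0.5, 0.0, 4, p), abs=1e-12
        )

    def test_inadmissible_params_rejected(self):
        with pytest.raises(ValueError):
            SkillParams(r=1.5)
        with pytest.raises(ValueError):
            SkillParams(alpha=1.2)
        with pytest.raises(ValueError):
            SkillParams(mu0=-5.0)


class TestInvestment:
    def test_matches_grid_argmax(self, params):
        for g in (-1.0, 0.0, 1.5):
            x_star = optimal_investment(g, params)
            grid = np.linspace(0, params.x_max, 4001)
            v = np.asarray(params.value(grid, g))
            x_grid = grid[np.argmax(v)]
            assert abs(x_star - x_grid) <= grid[1] - grid[0] + 1e-9

    def test_foc_residual_small_at_interior(self, params):
        x = optimal_investment(0.0, params)
        h = 1e-6
        foc = (params.value(x + h, 0.0) - params.value(x - h, 0.0)) / (2 * h)
        assert abs(foc) < 1e-4

    def test_prohibitive_cost_drives_investment_to_zero(self, params):
        """The power technology satisfies an Inada condition, so the optimum
        is interior but vanishes as the cost scale explodes."""
        xs = [optimal_investment(0.0, replace(params, c0=c)) for c in (1, 50, 500)]
        assert xs[0] > xs[1] > xs[2]
        assert xs[2] < 0.01

    def test_envelope_second_order(self, params):
        x = optimal_investment(0.0, params)
        v0 = float(params.value(x, 0.0))
        for eps in (0.05, 0.025):
            dv = abs(float(params.value(x + eps, 0.0)) - v0)
            assert dv < 2 * eps**2 * 10  # O(eps^2)
        d_big = abs(float(params.value(x + 0.05, 0.0)) - v0)
        d_small = abs(float(params.value(x + 0.025, 0.0)) - v0)
        assert d_small < d_big / 2.5  # quadratic, not linear, shrinkage

    def test_investment_gradient_sign_matches_complementarity(self, params):
        """aG > 0 makes investment productivity rise with G -> dx*/dG > 0."""
        comp = replace(params, aG=0.3, cG=0.0)
        x_lo = optimal_investment(-1.0, comp)
        x_hi = optimal_investment(1.0, comp)
        assert x_hi > x_lo


class TestTreatmentEffect:
    def test_zero_when_no_age_effect_and_no_gap(self):
        # no maturation, no investment productivity, no age multiplier:
        # entry skills identical at both ages and delta vanishes exactly
        p = SkillParams(m5=0.0, phi=0.0, a0=0.0, aG=0.0)
        te = treatment_effect(0.0, p)
        assert abs(te["delta"]) < 1e-9

    def test_positive_when_age_helps_and_skills_grow(self, params):
        te = treatment_effect(0.0, params)
        assert te["delta"] > 0
        assert te["theta5_star"] > te["theta4"]

    def test_split_residual_shrinks_quadratically(self, params):
        """First-order split error is O(gap^2): scale the gap, check decay."""
        resids = []
        for scale in (1.0, 0.5, 0.25):
            dec_gap = params.theta5(
                params.theta4(0.0), 0.0, optimal_investment(0.0, params)
            ) - params.theta4(0.0)
            th4 = float(params.theta4(0.0))
            th5 = th4 + scale * float(dec_gap)
            h = 1e-5
            mp = (
                float(params.theta_tau(th4 + h, 0.0, 5))
                - float(params.theta_tau(th4 - h, 0.0, 5))
            ) / (2 * h)
            exact = float(params.theta_tau(th5, 0.0, 5) - params.theta_tau(th4, 0.0, 4))
            approx = (th5 - th4) * mp + float(
                params.theta_tau(th4, 0.0, 5) - params.theta_tau(th4, 0.0, 4)
            )
            resids.append(abs(approx - exact))
        assert resids[1] < resids[0] / 3
        assert resids[2] < resids[1] / 3


class TestDecomposition:
    def test_terms_sum_exactly_to_total(self, params):
        dec = decompose_gxe(0.5, params)
        assert dec.total == dec.term1 + dec.term2 + dec.term3 + dec.term4

    def test_residual_quadratic_in_gap(self, params):
        r1 = abs(decompose_gxe(0.0, params, gap_scale=1.0).residual)
        r2 = abs(decompose_gxe(0.0, params, gap_scale=0.5).residual)
        r4 = abs(decompose_gxe(0.0, params, gap_scale=0.25).residual)
        assert r2 < r1 / 3
        assert r4 < r2 / 3

    def test_separable_linear_family_kills_terms_2_to_4(self):
        p = SkillParams(family="linear")
        dec = decompose_gxe(0.0, p)
        assert abs(dec.term2) < 1e-10
        assert abs(dec.term3) < 1e-10
        assert abs(dec.term4) < 1e-10
        assert abs(dec.residual) < 1e-8

    def test_cross_partial_sign_follows_rho_vs_r(self):
        """rho > r: skills and genes complements (term3 > 0); rho < r: substitutes."""
        comp = SkillParams(r=0.3, rho=0.9)
        sub = SkillParams(r=0.8, rho=0.3)
        assert decompose_gxe(0.0, comp).term3 > 0
        assert decompose_gxe(0.0, sub).term3 < 0

    def test_behavioural_response_included_by_default(self, params):
        """Freezing parental investment changes the theta5* gradient."""
        responsive = replace(params, aG=0.3)
        with_resp = decompose_gxe(0.0, responsive, behavioural_response=True)
        without = decompose_gxe(0.0, responsive, behavioural_response=False)
        assert with_resp.term1 != pytest.approx(without.term1, abs=1e-6)

    def test_coarse_step_warns(self, params):
        with pytest.warns(UserWarning, match="coarse"):
            decompose_gxe(0.0, params, step_h=0.5)


class TestWelfare:
    def test_matches_value_function_oracle(self, params):
        for g in (-1.0, 0.0, 1.0):
            grad = welfare_gradient(g, params)
            oracle = value_treatment_gradient_oracle(g, params)
            assert grad == pytest.approx(oracle, abs=5e-5)

    def test_zero_cost_equals_outcome_gradient(self):
        p = SkillParams(c0=0.0)
        dec = decompose_gxe(0.0, p)
        assert welfare_gradient(0.0, p) == pytest.approx(dec.gradient, abs=5e-6)


class TestCalibration:
    def test_reproduces_entry_positive_ks_negative_pattern(self):
        targets = {"entry": (1.151, 0.126), "ks2": (0.379, -0.093)}
        fitted = calibrate_to_cohort(targets)
        eff = implied_stage_effects(fitted)
        assert eff["entry"][0] > 0 and eff["entry"][1] > 0
        assert eff["ks"][0] > 0 and eff["ks"][1] < 0
        assert eff["entry"][0] == pytest.approx(1.151, abs=0.05)
        assert eff["ks"][1] == pytest.approx(-0.093, abs=0.02)

    def test_zero_targets_give_near_zero_interactions(self):
        targets = {"entry": (0.6, 0.0), "ks2": (0.3, 0.0)}
        fitted = calibrate_to_cohort(targets)
        eff = implied_stage_effects(fitted)
        assert abs(eff["entry"][1]) < 0.02
        assert abs(eff["ks"][1]) < 0.02

    def test_reproducible(self):
        targets = {"entry": (1.151, 0.126), "ks2": (0.379, -0.093)}
        a = calibrate_to_cohort(targets, seed=3)
        b = calibrate_to_cohort(targets, seed=3)
        assert a == b

    def test_requires_entry_and_ks_targets(self):
        with pytest.raises(ValueError):
            calibrate_to_cohort({"entry": (1.0, 0.1)})

    def test_calibrated_model_drives_cohort_sign_flip(self):
        """Simulated cohort from the calibrated technology shows the
        positive-entry / negative-KS interaction pattern."""
        from gxekit.cohort import CohortConfig, simulate_cohort
        from gxekit.estimation import fit_rdd

        fitted = calibrate_to_cohort({"entry": (1.151, 0.126), "ks2": (0.379, -0.093)})
        cfg = CohortConfig(
            n_children=60_000, generator="structural", skill_params=fitted,
            noise_sd={s: 0.5 for s in ("entry", "ks1", "ks2", "ks3", "ks4")},
            missing_rates={}, father_pgi_missing_rate=0.0,
            standardize_scores=False,
        )
        tab = simulate_cohort(cfg, seed=99)
        entry = fit_rdd(tab, "entry", cluster_by=None)
        ks2 = fit_rdd(tab, "ks2", cluster_by=None)
        assert entry.params["pgi_x_treated"] > 2 * entry.se("pgi_x_treated")
        assert ks2.params["pgi_x_treated"] < -2 * ks2.se("pgi_x_treated")
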