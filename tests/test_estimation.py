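"""GxE regression and school-entry RDD: recovery, specification, probes."""

import numpy as np
import pytest

from gxekit._rng import substream
from gxekit.cohort import CohortConfig, CohortTable, simulate_cohort
from gxekit.estimation import (
    binned_means,
    entry_skill_probe,
    fit_gxe,
    fit_rdd,
    treatment_effect_at,
)


def _gxe_data(seed, n=10_000, b_g=0.3, b_e=0.3, b_gxe=0.1, b_g2=0.0, rho_ge=0.0):
    rng = substream(seed, "test_gxe_dgp")
    g = rng.standard_normal(n)
    e = rho_ge * g + np.sqrt(1 - rho_ge**2) * rng.standard_normal(n)
    y = b_g * g + b_e * e + b_gxe * g * e + b_g2 * g * g + rng.standard_normal(n)
    return y, g, e


class TestFitGxe:
    def test_recovers_interaction(self):
        y, g, e = _gxe_data(seed=1)
        est = fit_gxe(y, g, e)
        assert abs(est.params["g_x_e"] - 0.1) < 2 * est.se("g_x_e")
        assert abs(est.params["e"] - 0.3) < 2 * est.se("e")

    def test_size_under_null(self):
        """Interaction t-test rejects ~5% when the true interaction is zero."""
        reps = 400
        rejections = 0
        for k in range(reps):
            y, g, e = _gxe_data(seed=2000 + k, n=1500, b_gxe=0.0)
            est = fit_gxe(y, g, e)
            rejections += est.pvalue("g_x_e") < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_quadratic_confound_needs_quadratic_block(self):
        """G^2 effects + corr(G, E) fake an interaction unless G^2 is included."""
        reps = 30
        naive = np.empty(reps)
        guarded = np.empty(reps)
        for k in range(reps):
            y, g, e = _gxe_data(seed=3000 + k, b_gxe=0.0, b_g2=0.15, rho_ge=0.5)
            naive[k] = fit_gxe(y, g, e).params["g_x_e"]
            guarded[k] = fit_gxe(y, g, e, include_quadratics=True).params["g_x_e"]
        assert naive.mean() > 5 * naive.std(ddof=1) / np.sqrt(reps)
        assert abs(guarded.mean()) < 3 * guarded.std(ddof=1) / np.sqrt(reps)

    def test_descriptor_records_blocks(self):
        y, g, e = _gxe_data(seed=4, n=500)
        x = np.random.default_rng(4).standard_normal((500, 2))
        est = fit_gxe(y, g, e, controls=x, include_quadratics=True)
        assert est.descriptor["blocks"]["quadratics"]
        assert "g_x_x0" in est.params.index and "e_x_x1" in est.params.index

    def test_identical_inputs_bit_reproducible(self):
        y, g, e = _gxe_data(seed=5, n=2000)
        a = fit_gxe(y, g, e)
        b = fit_gxe(y, g, e)
        assert (a.params == b.params).all()
        assert (a.cov.to_numpy() == b.cov.to_numpy()).all()


class TestFitRdd:
    def test_recovers_generating_coefficients(self):
        tab = simulate_cohort(
            CohortConfig(
                n_children=60_000, standardize_scores=False,
                missing_rates={}, father_pgi_missing_rate=0.0,
            ),
            seed=6,
        )
        est = fit_rdd(tab, "ks2", parental_controls=True, cluster_by=None)
        assert abs(est.params["treated"] - 0.379) < 3 * est.se("treated")
        assert abs(est.params["pgi_x_treated"] + 0.093) < 3 * est.se("pgi_x_treated")

    def test_parental_controls_shrink_pgi_under_nurture(self):
        """With nurture in the DGP the PGI main effect drops when parental
        PGIs are controlled (they absorb the passive-rGE part)."""
        cfg = CohortConfig(n_children=60_000, missing_rates={}, father_pgi_missing_rate=0.0)
        for s in cfg.stage_coefs.values():
            s["d_gm"], s["d_gf"] = 0.25, 0.25
        tab = simulate_cohort(cfg, seed=7)
        no_ctrl = fit_rdd(tab, "ks2", parental_controls=False, cluster_by=None)
        ctrl = fit_rdd(tab, "ks2", parental_controls=True, cluster_by=None)
        assert ctrl.params["pgi"] < no_ctrl.params["pgi"] - 2 * no_ctrl.se("pgi")

    def test_cluster_counts_enforced(self):
        tab = simulate_cohort(CohortConfig(n_children=3000), seed=8)
        df = tab.df[tab.df["mob"].isin([8, 9])].reset_index(drop=True)
        with pytest.raises(ValueError, match="cluster"):
            fit_rdd(CohortTable(df), "ks2", cluster_by="mob", min_obs=10)

    def test_quadratic_pgi_leaves_interaction_stable_under_linear_dgp(self):
        """Linearity diagnostic: adding a PGI^2 block barely moves the
        interaction when the truth is linear in the PGI."""
        coefs = {s: {} for s in ("entry", "ks1", "ks2", "ks3", "ks4")}
        coefs["ks2"] = {"d_e": 0.4, "d_g": 0.3, "d_gxe": -0.1, "d_mob": -0.09}
        tab = simulate_cohort(
            CohortConfig(n_children=60_000, standardize_scores=False,
                         stage_coefs=coefs,
                         missing_rates={}, father_pgi_missing_rate=0.0),
            seed=9,
        )
        base = fit_rdd(tab, "ks2", cluster_by=None)
        df = tab.df
        band = df[(df.r >= -3) & (df.r <= 2)]
        aug = fit_gxe(
            band["score_ks2"].to_numpy(),
            band["pgi_child"].to_numpy(),
            band["treated"].to_numpy(),
            controls=band["r"].to_numpy(),
            control_names=["mob"],
            include_quadratics=True,
        )
        assert abs(
            aug.params["g_x_e"] - base.params["pgi_x_treated"]
        ) < 2 * base.se("pgi_x_treated") + 2 * aug.se("g_x_e")

    def test_binned_means_roughly_linear(self):
        tab = simulate_cohort(CohortConfig(n_children=40_000), seed=10)
        bm = binned_means(tab, "ks2", n_bins=10)
        assert set(bm["treated"]) == {0, 1}
        for treated, grp in bm.groupby("treated"):
            r = np.corrcoef(grp["pgi_mean"], grp["score_mean"])[0, 1]
            assert r > 0.9  # monotone, near-linear profile


class TestTreatmentEffectAt:
    def test_published_ks2_percent_boost(self):
        """0.379 - 0.093 * PGI at PGI = -1 is ~25% above the mean effect."""
        import pandas as pd

        from gxekit.estimation import GxEEstimate

        params = pd.Series({"e": 0.379, "g_x_e": -0.093})
        cov = pd.DataFrame(np.eye(2) * 1e-12, index=params.index, columns=params.index)
        est = GxEEstimate(params, cov, n=0)
        effect, pct = treatment_effect_at(est, -1.0)
        assert effect == pytest.approx(0.472, abs=1e-12)
        assert round(pct) == 25

    def test_zero_interaction_zero_percent(self):
        import pandas as pd

        from gxekit.estimation import GxEEstimate

        params = pd.Series({"e": 0.5, "g_x_e": 0.0})
        cov = pd.DataFrame(np.eye(2) * 1e-12, index=params.index, columns=params.index)
        est = GxEEstimate(params, cov, n=0)
        for pgi in (-2.0, 0.0, 1.5):
            effect, pct = treatment_effect_at(est, pgi)
            assert pct == 0.0
        assert treatment_effect_at(est, 0.0)[0] == 0.5


class TestEntrySkillProbe:
    @staticmethod
    def _mechanism_cohort(seed, through_entry: bool):
        """KS2 interaction operating through entry skills vs directly.

        through_entry: entry has a GxE component and KS2 = 0.6 * entry + T;
        otherwise entry is treatment-only and KS2 carries its own GxE.
        """
        rng = substream(seed, "probe_dgp")
        n = 60_000
        cfg = CohortConfig(
            n_children=n, standardize_scores=False,
            missing_rates={}, father_pgi_missing_rate=0.0,
        )
        tab = simulate_cohort(cfg, seed=seed)
        df = tab.df
        g = df["pgi_child"].to_numpy()
        t = df["treated"].to_numpy()
        entry_gxe = 0.25 if through_entry else 0.0
        direct_gxe = 0.0 if through_entry else 0.15
        entry = 0.8 * t + entry_gxe * g * t + 0.3 * g + 0.4 * rng.standard_normal(n)
        ks2 = (
            0.6 * entry + 0.3 * t + direct_gxe * g * t + 0.2 * g
            + 0.6 * rng.standard_normal(n)
        )
        df["score_entry"] = entry
        df["score_ks2"] = ks2
        return CohortTable(df, tab.truth)

    def test_entry_mediated_interaction_shrinks_when_controlled(self):
        tab = self._mechanism_cohort(seed=11, through_entry=True)
        probe = entry_skill_probe(tab, "ks2", cluster_by=None)
        assert abs(probe["gxe_augmented"]) < 0.35 * abs(probe["gxe_baseline"])

    def test_technology_interaction_unmoved_by_entry_controls(self):
        tab = self._mechanism_cohort(seed=12, through_entry=False)
        probe = entry_skill_probe(tab, "ks2", cluster_by=None)
        se = probe["augmented"].se("pgi_x_treated")
        assert abs(probe["gxe_shift"]) < 3 * se

    def test_constant_entry_score_refused(self):
        tab = simulate_cohort(
            CohortConfig(n_children=3000, missing_rates={}, father_pgi_missing_rate=0.0),
            seed=13,
        )
        tab.df["score_entry"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            entry_skill_probe(tab, "ks2", cluster_by=None)
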