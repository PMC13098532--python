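"""Generative-model correctness: founders, mating, transmission, phenotypes."""

import numpy as np
import pytest
from scipy import stats

from gxekit.genetics_sim import (
    EffectProfile,
    EnvironmentSpec,
    assign_environment,
    assortative_pairing,
    generate_phenotype,
    simulate_families,
    simulate_founders,
    transmit,
    true_scores,
)
from gxekit.panels import GenotypePanel, PedigreeIndex


class TestFounders:
    def test_binomial_moments(self):
        """HWE draw at p=0.5: mean genotype 1.0 and variance 2p(1-p)."""
        n = 10_000
        panel = simulate_founders(n, 30, allele_freqs=np.full(30, 0.5), seed=1)
        mc_se = np.sqrt(0.5 / n)  # SD of the per-SNP mean = sqrt(2p(1-p)/n)
        assert np.all(np.abs(panel.values.mean(axis=0) - 1.0) < 3 * mc_se)
        v = panel.values.var(axis=0)
        assert np.all(np.abs(v - 0.5) < 0.05)

    def test_variance_tracks_frequency(self):
        panel = simulate_founders(20_000, 10, allele_freqs=np.full(10, 0.2), seed=2)
        assert np.allclose(panel.values.var(axis=0), 2 * 0.2 * 0.8, atol=0.02)

    def test_near_monomorphic_logged(self, caplog):
        with caplog.at_level("WARNING"):
            simulate_founders(100, 5, allele_freqs=np.full(5, 0.9995), seed=3)
        assert "near-monomorphic" in caplog.text

    @pytest.mark.parametrize("bad", [dict(n=1, n_snps=5), dict(n=10, n_snps=0)])
    def test_rejects_bad_counts(self, bad):
        with pytest.raises(ValueError):
            simulate_founders(**bad, seed=0)

    def test_rejects_bad_freq_range(self):
        with pytest.raises(ValueError):
            simulate_founders(10, 5, freq_range=(0.9, 0.1), seed=0)


class TestAssortativePairing:
    @pytest.mark.parametrize("r_am", [0.0, 0.3])
    def test_spousal_correlation_hits_target(self, r_am):
        eff = EffectProfile.uniform(100)
        fam = simulate_families(10_000, 100, eff, r_am=r_am, seed=5)
        sm = true_scores(fam.fathers, eff)
        sf = true_scores(fam.mothers, eff)
        realized = np.corrcoef(sm, sf)[0, 1]
        tol = 0.03 if r_am else 3 / np.sqrt(10_000)
        assert abs(realized - r_am) < tol

    def test_assortment_raises_parent_child_correlation(self):
        eff = EffectProfile.uniform(100)
        random_m = simulate_families(10_000, 100, eff, r_am=0.0, seed=6)
        assorted = simulate_families(10_000, 100, eff, r_am=0.4, seed=6)
        def pc_corr(fam):
            return np.corrcoef(
                true_scores(fam.children, eff), true_scores(fam.mothers, eff)
            )[0, 1]
        # random mating: 0.5; assortment pushes it to (1 + r)/2
        assert abs(pc_corr(random_m) - 0.5) < 0.03
        assert pc_corr(assorted) > pc_corr(random_m) + 0.05

    def test_unequal_pools_rejected(self):
        a = simulate_founders(10, 5, seed=1)
        b = simulate_founders(12, 5, allele_freqs=a.allele_freqs, seed=2)
        with pytest.raises(ValueError):
            assortative_pairing(a, b, np.ones(5), 0.2, seed=0)


class TestTransmission:
    def test_forced_heterozygote(self):
        mothers = GenotypePanel(np.full((50, 4), 2.0), np.full(4, 0.5))
        fathers = GenotypePanel(np.zeros((50, 4)), np.full(4, 0.5))
        ped = PedigreeIndex(np.arange(50), np.arange(50))
        children, _ = transmit(mothers, fathers, ped, seed=0)
        assert np.all(children.values == 1.0)

    def test_transmission_expectation(self, small_families):
        """E[G_child | parents] = (G_m + G_f) / 2 over many draws."""
        fam = small_families
        mid = (fam.mothers.values + fam.fathers.values) / 2
        diff = fam.children.values - mid
        # each child-SNP deviation has variance <= 1/2; average over all cells
        se = np.sqrt(0.5 / diff.size)
        assert abs(diff.mean()) < 4 * se

    def test_exact_transmission_distribution(self):
        """Chi-square of empirical child genotypes vs enumerated law."""
        rules = {  # (g_m, g_f) -> exact distribution over child genotype
            (0, 0): [1, 0, 0],
            (2, 2): [0, 0, 1],
            (1, 1): [0.25, 0.5, 0.25],
            (2, 0): [0, 1, 0],
            (1, 2): [0, 0.5, 0.5],
            (1, 0): [0.5, 0.5, 0],
        }
        n = 100_000
        for (gm, gf), probs in rules.items():
            mothers = GenotypePanel(np.full((n, 1), float(gm)), np.array([0.5]))
            fathers = GenotypePanel(np.full((n, 1), float(gf)), np.array([0.5]))
            ped = PedigreeIndex(np.arange(n), np.arange(n))
            children, _ = transmit(mothers, fathers, ped, seed=gm * 3 + gf)
            observed = np.bincount(children.values[:, 0].astype(int), minlength=3)
            keep = np.asarray(probs) > 0
            if keep.sum() == 1:  # deterministic transmission
                assert observed[keep][0] == n
            else:
                chi2 = stats.chisquare(observed[keep], n * np.asarray(probs)[keep])
                assert chi2.pvalue > 0.001

    def test_sibling_genotype_correlation_half(self, sibling_families):
        fam = sibling_families
        g1 = fam.children.values[0::2]
        g2 = fam.children.values[1::2]
        corrs = [
            np.corrcoef(g1[:, j], g2[:, j])[0, 1]
            for j in range(g1.shape[1])
        ]
        assert abs(np.mean(corrs) - 0.5) < 0.02

    def test_allele_frequency_conserved(self, small_families):
        fam = small_families
        child_freq = fam.children.values.mean(axis=0) / 2
        p = fam.children.allele_freqs
        mc_se = np.sqrt(p * (1 - p) / (2 * fam.children.n))
        assert np.all(np.abs(child_freq - p) < 4 * mc_se)

    def test_fractional_parents_rejected(self):
        mothers = GenotypePanel(np.full((5, 2), 0.7), np.full(2, 0.5))
        fathers = GenotypePanel(np.zeros((5, 2)), np.full(2, 0.5))
        ped = PedigreeIndex(np.arange(5), np.arange(5))
        with pytest.raises(ValueError, match="integer"):
            transmit(mothers, fathers, ped, seed=0)


class TestEnvironment:
    def test_exogenous_independent_of_genotype(self, small_families, effects50):
        fam = small_families
        E, _ = assign_environment(
            fam.children, fam.mothers, fam.fathers, fam.pedigree,
            EnvironmentSpec("exogenous"), effects50, seed=11,
        )
        r = np.corrcoef(E, true_scores(fam.children, effects50))[0, 1]
        assert abs(r) < 3 / np.sqrt(fam.children.n)

    def test_predetermined_loads_on_parents(self, effects50):
        fam = simulate_families(10_000, 50, effects50, seed=12)
        spec = EnvironmentSpec("predetermined", parent_loading=0.5)
        E, _ = assign_environment(
            fam.children, fam.mothers, fam.fathers, fam.pedigree, spec,
            effects50, seed=12,
        )
        par = true_scores(fam.mothers, effects50) + true_scores(fam.fathers, effects50)
        assert np.corrcoef(E, par)[0, 1] > 0.2

    def test_nonpredetermined_loads_on_child_conditionally(self, effects50):
        fam = simulate_families(10_000, 50, effects50, seed=13)
        spec = EnvironmentSpec("nonpredetermined", child_loading=0.5)
        E, _ = assign_environment(
            fam.children, fam.mothers, fam.fathers, fam.pedigree, spec,
            effects50, seed=13,
        )
        tc = true_scores(fam.children, effects50)
        tp = np.column_stack(
            [true_scores(fam.mothers, effects50), true_scores(fam.fathers, effects50)]
        )
        # partial correlation of E with the child score given both parents
        resid = lambda v: v - tp @ np.linalg.lstsq(tp, v, rcond=None)[0]
        r = np.corrcoef(resid(E), resid(tc))[0, 1]
        assert r > 0.2

    def test_scenario_loading_contradictions(self):
        with pytest.raises(ValueError):
            EnvironmentSpec("exogenous", parent_loading=0.5)
        with pytest.raises(ValueError):
            EnvironmentSpec("predetermined", child_loading=0.5)

    def test_estar_correlates_with_e(self, small_families, effects50):
        fam = small_families
        E, Estar = assign_environment(
            fam.children, fam.mothers, fam.fathers, fam.pedigree,
            EnvironmentSpec("exogenous", estar_corr=0.6), effects50, seed=14,
        )
        assert abs(np.corrcoef(E, Estar)[0, 1] - 0.6) < 0.05


class TestPhenotype:
    def test_pure_noise_variance(self, small_families):
        fam = small_families
        eff = EffectProfile(np.zeros(50), residual_sd=1.0)
        y = generate_phenotype(
            fam.children, fam.mothers, fam.fathers, fam.pedigree,
            np.zeros(fam.children.n), None, eff, seed=15,
        )
        assert abs(y.var() - 1.0) < 0.1

    def test_noiseless_direct_effect_exact(self, small_families):
        fam = small_families
        b = np.zeros(50)
        b[0] = 0.5
        eff = EffectProfile(b, residual_sd=0.0)
        y = generate_phenotype(
            fam.children, fam.mothers, fam.fathers, fam.pedigree,
            np.zeros(fam.children.n), None, eff, seed=16,
        )
        g = fam.children.values[:, 0]
        slope = np.polyfit(g, y, 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_nurture_creates_conditional_parent_correlation(self, small_families, effects50):
        fam = small_families
        y = generate_phenotype(
            fam.children, fam.mothers, fam.fathers, fam.pedigree,
            np.zeros(fam.children.n), None, effects50, seed=17,
        )
        tc = true_scores(fam.children, effects50)[:, None]
        tm = true_scores(fam.mothers, effects50)
        resid = lambda v: v - tc[:, 0] * (tc[:, 0] @ v) / (tc[:, 0] @ tc[:, 0])
        r = np.corrcoef(resid(y - y.mean()), resid(tm - tm.mean()))[0, 1]
        assert r > 0.05

    def test_mendelian_conditional_randomness(self, effects50):
        """Child genotype is random given both parental genotypes.

        Regressing the child's allele count on the environment, conditional
        on the parental counts, must give a slope near zero even when the
        environment is strongly loaded on the parents' scores.
        """
        fam = simulate_families(10_000, 50, effects50, seed=18)
        spec = EnvironmentSpec("predetermined", parent_loading=0.8)
        E, _ = assign_environment(
            fam.children, fam.mothers, fam.fathers, fam.pedigree, spec,
            effects50, seed=18,
        )
        slopes = []
        for j in range(0, 50, 10):
            X = np.column_stack(
                [np.ones(fam.children.n), fam.mothers.values[:, j],
                 fam.fathers.values[:, j], E]
            )
            coef, *_ = np.linalg.lstsq(X, fam.children.values[:, j], rcond=None)
            resid = fam.children.values[:, j] - X @ coef
            sigma = np.sqrt(resid @ resid / (len(resid) - 4))
            se = sigma / np.sqrt(((E - E.mean()) ** 2).sum())
            slopes.append(coef[3] / se)
        assert np.all(np.abs(slopes) < 4)  # t-scores consistent with zero
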