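"""Generative model for genotyped families and gene-environment correlation.

The simulator implements the canonical causal diagram of family-based genetic
studies: founder genotypes in Hardy-Weinberg equilibrium, spousal correlation
through assortative mating, Mendelian transmission to children, environments
with configurable gene-environment correlation (rGE), and phenotypes that mix
direct genetic effects, parental "genetic nurture", sibling spillovers, and
true gene-by-environment interaction.

Conventions
-----------
* SNPs are unlinked: transmission is independent across SNPs, so there is no
  linkage disequilibrium by construction.
* Direct genetic effects are per-SNP weights ``b_j``; the *true genetic score*
  of a person is the weighted allele-count sum ``T = G @ b``.  Genetic nurture
  is parameterized at the score level: the outcome loads on the parents' true
  scores with coefficients ``nurture_mother`` / ``nurture_father``.  Under
  random mating this keeps the probability-limit algebra closed form, e.g. a
  naive (between-family) per-SNP regression has slope
  ``b_j * (1 + (nurture_mother + nurture_father) / 2)``.
* Gene-by-environment blocks operate on the *standardized* true child score,
  so their coefficients are in per-standard-deviation units, matching how
  polygenic indices are used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .panels import GenotypePanel, PedigreeIndex

__all__ = [
    "EffectProfile",
    "EnvironmentSpec",
    "GxETrueModel",
    "FamilyData",
    "simulate_founders",
    "assortative_pairing",
    "transmit",
    "assign_environment",
    "generate_phenotype",
    "simulate_families",
    "true_scores",
]

logger = logging.getLogger(__name__)

_NEAR_MONOMORPHIC = 1e-3  # flag frequencies this close to 0 or 1


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class EffectProfile:
    """Genetic architecture of the outcome.

    ``snp_effects`` are the per-SNP direct effects ``b_j`` on the raw
    allele-count scale.  ``nurture_mother`` / ``nurture_father`` are
    coefficients on the parents' *true scores* (indirect genetic effects /
    genetic nurture).  ``sibling_effect`` loads the outcome on the mean true
    score of one's siblings.  ``residual_sd`` is the SD of the i.i.d. noise.
    """

    snp_effects: np.ndarray
    intercept: float = 0.0
    nurture_mother: float = 0.0
    nurture_father: float = 0.0
    sibling_effect: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        self.snp_effects = np.asarray(self.snp_effects, dtype=float)
        if not np.all(np.isfinite(self.snp_effects)):
            raise ValueError("snp_effects must be finite")
        for name in ("intercept", "nurture_mother", "nurture_father", "sibling_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    @classmethod
    def uniform(
        cls,
        n_snps: int,
        score_sd: float = 1.0,
        freq: float = 0.5,
        **kwargs,
    ) -> "EffectProfile":
        """Equal per-SNP effects scaled so the true score has SD ~ score_sd.

        Uses the binomial variance ``2 p (1 - p)`` at the typical frequency
        ``freq`` of the simulated panel.
        """
        b = score_sd / np.sqrt(n_snps * 2 * freq * (1 - freq))
        return cls(snp_effects=np.full(n_snps, b), **kwargs)


@dataclass
class EnvironmentSpec:
    """How the environment relates to the family's genotypes.

    ``scenario`` follows the taxonomy of G-by-E estimation settings:

    * ``"exogenous"`` - E is pure noise, independent of all genotypes.
    * ``"predetermined"`` - E loads on the parents' genetic scores (passive
      rGE / genetic nurture channel) but is not caused by the child's own
      genotype.
    * ``"nonpredetermined"`` - E additionally loads on the child's own score
      (active/evocative rGE: the environment is a mediator of G) and may be
      reverse-caused by the outcome.

    ``estar_corr`` and ``estar_effect`` describe a correlated environment E*
    that affects the outcome directly; omitting it from an analysis makes the
    estimated E coefficient pick up E*.
    """

    scenario: str = "exogenous"
    parent_loading: float = 0.0
    child_loading: float = 0.0
    estar_corr: float = 0.5
    estar_effect: float = 0.0
    reverse_loading: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in ("exogenous", "predetermined", "nonpredetermined"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "exogenous":
            if self.parent_loading or self.child_loading or self.reverse_loading:
                raise ValueError("exogenous E cannot load on any genotype or outcome")
        if self.scenario == "predetermined":
            if self.child_loading or self.reverse_loading:
                raise ValueError(
                    "predetermined E is set before conception: child-score "
                    "loading and reverse causality must be zero"
                )
        if not -1 < self.estar_corr < 1:
            raise ValueError("estar_corr must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class GxETrueModel:
    """True coefficients of the interaction blocks of the outcome equation.

    All genetic terms operate on the standardized true child score S, so
    ``beta_GxE`` is the per-SD interaction effect.  ``beta_controls``,
    ``beta_g_controls`` and ``beta_e_controls`` are optional loadings for
    extra control variables and their interactions with S and E.
    """

    beta_E: float = 0.0
    beta_GxE: float = 0.0
    beta_G2: float = 0.0
    beta_E2: float = 0.0
    beta_controls: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_g_controls: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_e_controls: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for name in ("beta_E", "beta_GxE", "beta_G2", "beta_E2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class FamilyData:
    """Bundle of aligned panels produced by :func:`simulate_families`."""

    children: GenotypePanel
    mothers: GenotypePanel
    fathers: GenotypePanel
    pedigree: PedigreeIndex


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def simulate_founders(
    n: int,
    n_snps: int,
    freq_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
    allele_freqs: np.ndarray | None = None,
    stream: str = "founders",
) -> GenotypePanel:
    """Draw founder genotypes in Hardy-Weinberg equilibrium.

    Each SNP ``j`` gets a frequency ``p_j`` uniform on ``freq_range`` (or the
    supplied ``allele_freqs``) and genotypes i.i.d. Binomial(2, p_j).
    """
    if n < 2:
        raise ValueError("need at least 2 founders")
    if n_snps < 1:
        raise ValueError("need at least 1 SNP")
    rng = substream(seed, stream)
    if allele_freqs is None:
        lo, hi = freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")
        allele_freqs = rng.uniform(lo, hi, size=n_snps) if lo < hi else np.full(n_snps, lo)
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    near_mono = (allele_freqs < _NEAR_MONOMORPHIC) | (allele_freqs > 1 - _NEAR_MONOMORPHIC)
    if near_mono.any():
        logger.warning(
            "%d SNP(s) are near-monomorphic (frequency within %.0e of 0/1)",
            int(near_mono.sum()),
            _NEAR_MONOMORPHIC,
        )
    # HWE draw as two independent allele Bernoullis (faster than binomial)
    values = (
        (rng.random((n, n_snps)) < allele_freqs).astype(float)
        + (rng.random((n, n_snps)) < allele_freqs)
    )
    return GenotypePanel(values, allele_freqs)


def _mating_scores(panel: GenotypePanel, weights: np.ndarray) -> np.ndarray:
    s = panel.values @ np.asarray(weights, dtype=float)
    sd = s.std()
    if sd == 0:
        raise ValueError("mating scores are constant; cannot order spouses")
    return (s - s.mean()) / sd


def assortative_pairing(
    males: GenotypePanel,
    females: GenotypePanel,
    mating_weights: np.ndarray,
    r_am: float = 0.0,
    seed: int = 0,
) -> PedigreeIndex:
    """Match spouses so their mating-score correlation is ``r_am``.

    Gaussian-copula rank matching: each pool is ranked on a noisy latent
    ``a * score + sqrt(1 - a^2) * noise`` with ``a = sqrt(|r_am|)``; pairing
    the two rankings makes the latents comonotone, which induces a spousal
    score correlation of ``a^2 = |r_am|`` (anti-ranked for negative values).
    ``r_am = 0`` degenerates to random pairing.
    """
    if males.n != females.n:
        raise ValueError("male and female pools must be the same size")
    if not -1 < r_am < 1:
        raise ValueError("|r_am| must be < 1")
    rng = substream(seed, "pairing")
    sm = _mating_scores(males, mating_weights)
    sf = _mating_scores(females, mating_weights)
    a = np.sqrt(abs(r_am))
    zm = a * sm + np.sqrt(1 - a * a) * rng.standard_normal(males.n)
    zf = a * sf + np.sqrt(1 - a * a) * rng.standard_normal(females.n)
    order_f = np.argsort(zf)
    order_m = np.argsort(zm) if r_am >= 0 else np.argsort(-zm)
    # couple k: father order_m[k], mother order_f[k]
    return PedigreeIndex(mother_row=order_f, father_row=order_m)


def transmit(
    mothers: GenotypePanel,
    fathers: GenotypePanel,
    pedigree: PedigreeIndex,
    children_per_family: int = 1,
    seed: int = 0,
) -> tuple[GenotypePanel, PedigreeIndex]:
    """Mendelian transmission: one allele from each parent, per SNP.

    Child count = Bernoulli(G_m / 2) + Bernoulli(G_f / 2), independently
    across SNPs (unlinked) and across children (no shared segregation).
    Returns the child panel plus a pedigree with ``children_per_family``
    children per couple (family-major order).
    """
    if not mothers.is_integer() or not fathers.is_integer():
        raise ValueError("transmission requires integer parental genotypes")
    if children_per_family < 1:
        raise ValueError("children_per_family must be >= 1")
    rng = substream(seed, "transmit")
    gm = mothers.values[pedigree.mother_row]  # (F, J)
    gf = fathers.values[pedigree.father_row]
    n_fam, n_snps = gm.shape
    k = children_per_family
    pm = np.repeat(gm / 2.0, k, axis=0)
    pf = np.repeat(gf / 2.0, k, axis=0)
    child = (
        (rng.random(pm.shape) < pm).astype(float)
        + (rng.random(pf.shape) < pf).astype(float)
    )
    child_ped = PedigreeIndex(
        mother_row=np.repeat(pedigree.mother_row, k),
        father_row=np.repeat(pedigree.father_row, k),
        family_id=np.repeat(np.arange(n_fam), k),
    )
    return GenotypePanel(child, mothers.allele_freqs), child_ped


def true_scores(panel: GenotypePanel, effects: EffectProfile) -> np.ndarray:
    """Raw true genetic score T = G @ b."""
    return panel.values @ effects.snp_effects


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def assign_environment(
    children: GenotypePanel,
    mothers: GenotypePanel,
    fathers: GenotypePanel,
    pedigree: PedigreeIndex,
    env: EnvironmentSpec,
    effects: EffectProfile,
    seed: int = 0,
    provisional_outcome: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the environment E and its correlated shadow E* for each child.

    * exogenous: E = noise.
    * predetermined: E = parent_loading * (standardized mid-parent score) + noise.
    * nonpredetermined: additionally child_loading * (standardized child
      score), and, when ``reverse_loading`` is set, a loading on a supplied
      provisional outcome (reverse causality).

    E* is built as ``estar_corr * standardized(E) + sqrt(1-estar_corr^2) * noise``;
    its effect on the outcome is ``env.estar_effect`` (applied by
    :func:`generate_phenotype`).
    """
    rng = substream(seed, "environment")
    n = pedigree.n_children
    e = env.noise_sd * rng.standard_normal(n)
    if env.scenario in ("predetermined", "nonpredetermined") and env.parent_loading:
        tm = true_scores(mothers, effects)[pedigree.mother_row]
        tf = true_scores(fathers, effects)[pedigree.father_row]
        e = e + env.parent_loading * _standardize(tm + tf)
    if env.scenario == "nonpredetermined":
        if env.child_loading:
            e = e + env.child_loading * _standardize(true_scores(children, effects))
        if env.reverse_loading:
            if provisional_outcome is None:
                raise ValueError(
                    "reverse_loading requires a provisional outcome vector"
                )
            e = e + env.reverse_loading * _standardize(provisional_outcome)
    rho = env.estar_corr
    estar = rho * _standardize(e) + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
    return e, estar


def generate_phenotype(
    children: GenotypePanel,
    mothers: GenotypePanel,
    fathers: GenotypePanel,
    pedigree: PedigreeIndex,
    E: np.ndarray,
    E_star: np.ndarray | None,
    effects: EffectProfile,
    gxe: GxETrueModel | None = None,
    estar_effect: float = 0.0,
    controls: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Compose the outcome from all generative channels.

    Y = b0 + T_child + nurture_m * T_mother + nurture_f * T_father
        + sibling_effect * mean(T_sibs) + beta_E * E + beta_GxE * S * E
        + beta_G2 * S^2 + beta_E2 * E^2 + estar_effect * E* + control blocks
        + residual,

    where T are raw true scores and S is the standardized child score.
    """
    gxe = gxe or GxETrueModel()
    n = pedigree.n_children
    E = np.asarray(E, dtype=float)
    if E.shape[0] != n:
        raise ValueError("E length must match number of children")
    tc = true_scores(children, effects)
    tm = true_scores(mothers, effects)[pedigree.mother_row]
    tf = true_scores(fathers, effects)[pedigree.father_row]
    y = (
        effects.intercept
        + tc
        + effects.nurture_mother * tm
        + effects.nurture_father * tf
    )
    if effects.sibling_effect:
        fam = pedigree.family_id
        sums = np.zeros(fam.max() + 1)
        counts = np.zeros(fam.max() + 1)
        np.add.at(sums, fam, tc)
        np.add.at(counts, fam, 1.0)
        others = np.where(
            counts[fam] > 1, (sums[fam] - tc) / np.maximum(counts[fam] - 1, 1), 0.0
        )
        y = y + effects.sibling_effect * others
    needs_score = bool(
        gxe.beta_GxE or gxe.beta_G2 or gxe.beta_g_controls.size
    )
    s = _standardize(tc) if needs_score else np.zeros(n)
    y = y + gxe.beta_E * E + gxe.beta_GxE * s * E + gxe.beta_G2 * s * s + gxe.beta_E2 * E * E
    if estar_effect:
        if E_star is None:
            raise ValueError("estar_effect set but no E* vector supplied")
        y = y + estar_effect * np.asarray(E_star, dtype=float)
    if controls is not None:
        controls = np.atleast_2d(np.asarray(controls, dtype=float))
        if controls.shape[0] != n:
            controls = controls.T
        if gxe.beta_controls.size:
            y = y + controls @ gxe.beta_controls
        if gxe.beta_g_controls.size:
            y = y + (controls * s[:, None]) @ gxe.beta_g_controls
        if gxe.beta_e_controls.size:
            y = y + (controls * E[:, None]) @ gxe.beta_e_controls
    if effects.residual_sd:
        rng = substream(seed, "phenotype")
        y = y + effects.residual_sd * rng.standard_normal(n)
    return y


def simulate_families(
    n_families: int,
    n_snps: int,
    effects: EffectProfile,
    children_per_family: int = 1,
    r_am: float = 0.0,
    freq_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
    allele_freqs: np.ndarray | None = None,
) -> FamilyData:
    """Founders -> assortative pairing -> transmission, in one call.

    Mating scores use the true-effect weights (assortment on the trait's
    genetic propensity).  Parent panels in the result are aligned so row i is
    the parent of family i (pedigree rows are the identity after alignment).
    """
    fathers = simulate_founders(
        n_families, n_snps, freq_range, seed, allele_freqs, stream="founders_m"
    )
    mothers = simulate_founders(
        n_families, n_snps, freq_range, seed,
        allele_freqs if allele_freqs is not None else fathers.allele_freqs,
        stream="founders_f",
    )
    couples = assortative_pairing(fathers, mothers, effects.snp_effects, r_am, seed)
    # align parent panels couple-major so downstream indexing is the identity
    mothers = mothers.take(couples.mother_row)
    fathers = fathers.take(couples.father_row)
    aligned = PedigreeIndex(
        mother_row=np.arange(n_families), father_row=np.arange(n_families)
    )
    children, child_ped = transmit(
        mothers, fathers, aligned, children_per_family, seed
    )
    return FamilyData(children, mothers, fathers, child_ped)
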