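"""Mendelian imputation of a missing father from mother-child duos.

A child carries one maternal and one paternal allele at each biallelic SNP.
Observing the mother's and child's genotypes pins down (or constrains) which
allele the father transmitted; the untransmitted paternal allele is never
observed and is imputed by its population expectation, the reference allele
frequency ``p``.  The expected paternal allele count is therefore

    E[G_f | G_m, G_c, p] = P(paternal transmitted allele = 1 | G_m, G_c, p) + p

with the posterior computed by enumerating maternal transmission under
Mendelian segregation and paternal transmission under Hardy-Weinberg.
Mother-child pairs that are jointly impossible under Mendelian inheritance
(e.g. G_m = 0 with G_c = 2) are flagged as conflicts and masked, never
silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panels import GenotypePanel

__all__ = [
    "ImputedPanel",
    "ConflictReport",
    "impute_father",
    "mendelian_conflicts",
    "paternal_posterior",
]


@dataclass
class ImputedPanel:
    """Fractional expected paternal genotypes plus the conflict mask."""

    panel: GenotypePanel
    conflict_mask: np.ndarray  # (n, J) bool; True where duo is impossible

    @property
    def values(self) -> np.ndarray:
        return self.panel.values

    @property
    def conflict_rate(self) -> float:
        return float(self.conflict_mask.mean())


@dataclass
class ConflictReport:
    """(individual, SNP) pairs violating Mendelian transmission."""

    pairs: np.ndarray  # (k, 2) int array of (row, snp) indices
    rate: float
    n_checked: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.pairs.shape[0]} Mendelian conflicts in {self.n_checked} "
            f"duo genotypes (rate {self.rate:.4g})"
        )


def paternal_posterior(g_m: np.ndarray, g_c: np.ndarray, p: np.ndarray) -> np.ndarray:
    """P(paternal transmitted allele = 1 | G_m, G_c, p); nan for conflicts.

    Enumerates the maternal transmitted allele a_m ~ Bernoulli(G_m / 2) and
    the paternal transmitted allele t_p ~ Bernoulli(p) (Hardy-Weinberg
    father), conditioning on G_c = a_m + t_p.
    """
    g_m = np.asarray(g_m, dtype=float)
    g_c = np.asarray(g_c, dtype=float)
    p = np.asarray(p, dtype=float)
    pm = g_m / 2.0  # P(maternal transmitted allele = 1)
    # joint likelihoods of (a_m, t_p) consistent with the observed child count
    like_tp0 = np.where(g_c == 0, (1 - pm), np.where(g_c == 1, pm, 0.0)) * (1 - p)
    like_tp1 = np.where(g_c == 1, (1 - pm), np.where(g_c == 2, pm, 0.0)) * p
    total = like_tp0 + like_tp1
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(total > 0, like_tp1 / total, np.nan)
    return post


def impute_father(
    child: GenotypePanel,
    mother: GenotypePanel,
    allele_freqs: np.ndarray | None = None,
) -> ImputedPanel:
    """Expected paternal allele counts from mother-child duos.

    ``allele_freqs`` defaults to the frequencies stored on the child panel
    (a perfectly matched reference); pass different values to study the
    effect of a misspecified reference panel.
    """
    if child.values.shape != mother.values.shape:
        raise ValueError("child and mother panels must be aligned (same shape)")
    if not child.is_integer() or not mother.is_integer():
        raise ValueError("imputation requires integer (hard-call) genotypes")
    p = np.asarray(
        child.allele_freqs if allele_freqs is None else allele_freqs, dtype=float
    )
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("reference allele frequencies must lie in (0, 1)")
    post = paternal_posterior(mother.values, child.values, p[None, :])
    conflict = ~np.isfinite(post)
    dosage = post + p[None, :]
    return ImputedPanel(
        GenotypePanel(dosage, p, ids=child.ids, snp_ids=child.snp_ids),
        conflict_mask=conflict,
    )


def mendelian_conflicts(child: GenotypePanel, mother: GenotypePanel) -> ConflictReport:
    """QC scan for duo genotypes impossible under Mendelian transmission.

    With only the mother observed, the detectable conflicts are
    (G_m = 0, G_c = 2) and (G_m = 2, G_c = 0): the child must carry, or must
    lack, an allele the mother cannot have supplied or withheld.  A fully
    heterozygous mother can produce any child genotype, so no conflict is
    detectable there.
    """
    if child.values.shape != mother.values.shape:
        raise ValueError("panels must be aligned")
    gm, gc = mother.values, child.values
    bad = ((gm == 0) & (gc == 2)) | ((gm == 2) & (gc == 0))
    rows, cols = np.nonzero(bad)
    return ConflictReport(
        pairs=np.column_stack([rows, cols]),
        rate=float(bad.mean()),
        n_checked=int(bad.size),
    )
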