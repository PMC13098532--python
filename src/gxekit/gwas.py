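"""Per-SNP association designs: naive, trio-conditioned, and sibling FE.

Each design runs one small regression per SNP (no joint or mixed model) and
returns allele-count-scale coefficients with heteroskedasticity-robust (HC1)
standard errors:

* ``regular_gwas`` - univariate OLS of the outcome on each SNP. Its slope
  absorbs direct effects *and* everything correlated with the genotype
  between families (genetic nurture, assortative mating, population
  structure).
* ``trio_gwas`` - OLS of the outcome on the child's SNP conditional on both
  parents' genotypes at that SNP.  Because the child's genotype is random
  given the parents (Mendelian segregation), the child coefficient is the
  direct genetic effect.
* ``sibling_fe_gwas`` - within-family (demeaned) OLS, absorbing the parental
  genotypes through a family fixed effect.

The regressions are vectorized across SNPs with closed-form normal equations
so that Monte-Carlo studies can rerun the GWAS stage thousands of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import GenotypePanel, PedigreeIndex

__all__ = [
    "GwasResult",
    "regular_gwas",
    "trio_gwas",
    "sibling_fe_gwas",
    "write_sumstats",
    "read_sumstats",
]

_MIN_VAR = 1e-12


@dataclass
class GwasResult:
    """Per-SNP estimates from one design.

    ``beta``/``se`` are ``nan`` for dropped SNPs; ``dropped`` maps SNP index
    to the reason.
    """

    beta: np.ndarray
    se: np.ndarray
    n: int
    design: str
    snp_ids: np.ndarray
    effect_allele_freq: np.ndarray
    dropped: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in ("regular", "trio", "sibling_fe"):
            raise ValueError(f"unknown design {self.design!r}")
        est = np.isfinite(self.beta)
        if np.any(self.se[est] <= 0):
            raise ValueError("standard errors must be positive where estimated")

    @property
    def n_estimated(self) -> int:
        return int(np.isfinite(self.beta).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "effect_allele": "G",
                "freq": self.effect_allele_freq,
                "beta": self.beta,
                "se": self.se,
                "n": self.n,
                "design": self.design,
            }
        )


def _univariate_robust(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column simple OLS with HC1 SEs.

    ``g`` is (n, J); returns (beta, se, var_g) with nan where var_g ~ 0.
    """
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    ok = sxx > _MIN_VAR * n
    beta = np.full(g.shape[1], np.nan)
    se = np.full(g.shape[1], np.nan)
    beta[ok] = sxy[ok] / sxx[ok]
    # HC1 sandwich: sum(gc^2 e^2) / sxx^2 * n/(n-2)
    # e = yc - beta*gc  =>  gc^2 e^2 = gc^2 yc^2 - 2 beta gc^3 yc + beta^2 gc^4
    g2 = gc * gc
    s_g2y2 = np.einsum("ij,i->j", g2, yc * yc)
    s_g3y = np.einsum("ij,ij,i->j", g2, gc, yc)
    s_g4 = np.einsum("ij,ij->j", g2, g2)
    meat = s_g2y2 - 2 * beta * s_g3y + beta * beta * s_g4
    with np.errstate(invalid="ignore"):
        se[ok] = np.sqrt(np.maximum(meat[ok], 0) / sxx[ok] ** 2 * n / max(n - 2, 1))
    se[ok] = np.maximum(se[ok], _MIN_VAR**0.5)  # exact fits: keep SEs positive
    return beta, se, sxx / n


def regular_gwas(panel: GenotypePanel, y: np.ndarray) -> GwasResult:
    """Naive (between-family) GWAS: per-SNP univariate OLS."""
    y = np.asarray(y, dtype=float)
    if panel.n != y.shape[0]:
        raise ValueError("panel and outcome length mismatch")
    if panel.n <= 2:
        raise ValueError("need n > 2")
    beta, se, var_g = _univariate_robust(panel.values, y)
    dropped = {int(j): "monomorphic" for j in np.nonzero(~np.isfinite(beta))[0]}
    if np.allclose(y, y[0]):
        beta = np.where(np.isfinite(beta), 0.0, beta)
        se = np.where(np.isfinite(se), _MIN_VAR ** 0.5, se)
    return GwasResult(
        beta, se, panel.n, "regular", panel.snp_ids, panel.allele_freqs, dropped
    )


def trio_gwas(
    children: GenotypePanel,
    mothers: GenotypePanel,
    fathers: GenotypePanel,
    y: np.ndarray,
    pedigree: PedigreeIndex | None = None,
) -> GwasResult:
    """Trio GWAS: per-SNP OLS of Y on (G_child, G_mother, G_father).

    The father panel may hold fractional imputed dosages.  The reported
    coefficient is the child (direct-effect) term.  SNPs whose 4x4 design is
    singular (e.g. a constant imputed father column) are dropped.
    """
    y = np.asarray(y, dtype=float)
    gm = mothers.values if pedigree is None else mothers.values[pedigree.mother_row]
    gf = fathers.values if pedigree is None else fathers.values[pedigree.father_row]
    gc = children.values
    n, J = gc.shape
    if not (gm.shape == gf.shape == gc.shape) or y.shape[0] != n:
        raise ValueError("trio panels and outcome must be aligned")
    # per-SNP normal equations for X = [1, gc, gm, gf]
    cols = [np.ones((n, J)), gc, gm, gf]
    A = np.empty((J, 4, 4))
    b = np.empty((J, 4))
    for a_i in range(4):
        b[:, a_i] = np.einsum("ij,i->j", cols[a_i], y)
        for a_j in range(a_i, 4):
            s = np.einsum("ij,ij->j", cols[a_i], cols[a_j])
            A[:, a_i, a_j] = s
            A[:, a_j, a_i] = s
    # screen singular systems via the determinant (tiny = collinear)
    det = np.linalg.det(A)
    scale = np.abs(A).max(axis=(1, 2)) ** 4 + _MIN_VAR
    ok = np.abs(det) > 1e-9 * scale
    beta = np.full(J, np.nan)
    se = np.full(J, np.nan)
    if ok.any():
        coef = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]  # (k, 4)
        # residuals for robust covariance
        idx = np.nonzero(ok)[0]
        fitted = (
            coef[:, 0][None, :]
            + gc[:, idx] * coef[:, 1][None, :]
            + gm[:, idx] * coef[:, 2][None, :]
            + gf[:, idx] * coef[:, 3][None, :]
        )
        e = y[:, None] - fitted
        Ainv = np.linalg.inv(A[ok])
        # meat = X' diag(e^2) X, assembled element-wise
        e2 = e * e
        meat = np.empty((ok.sum(), 4, 4))
        sub = [c[:, idx] for c in cols]
        for a_i in range(4):
            for a_j in range(a_i, 4):
                s = np.einsum("ij,ij,ij->j", sub[a_i], sub[a_j], e2)
                meat[:, a_i, a_j] = s
                meat[:, a_j, a_i] = s
        cov = Ainv @ meat @ Ainv * (n / max(n - 4, 1))
        beta[ok] = coef[:, 1]
        se[ok] = np.sqrt(np.maximum(cov[:, 1, 1], _MIN_VAR))
    dropped = {int(j): "collinear trio design" for j in np.nonzero(~ok)[0]}
    return GwasResult(
        beta, se, n, "trio", children.snp_ids, children.allele_freqs, dropped
    )


def sibling_fe_gwas(
    panel: GenotypePanel, family_id: np.ndarray, y: np.ndarray
) -> GwasResult:
    """Sibling fixed-effects GWAS: within-family demeaned per-SNP OLS.

    Families with a single included member are excluded (no within
    variation); SNPs with zero within-family variance are reported NA.
    """
    y = np.asarray(y, dtype=float)
    family_id = np.asarray(family_id, dtype=int)
    if panel.n != y.shape[0] or panel.n != family_id.shape[0]:
        raise ValueError("panel, family ids and outcome must be aligned")
    fams, inverse, counts = np.unique(family_id, return_inverse=True, return_counts=True)
    keep = counts[inverse] >= 2
    if not keep.any():
        raise ValueError("no families with >= 2 siblings")
    g = panel.values[keep]
    yk = y[keep]
    inv = inverse[keep]
    fams_k, inv = np.unique(inv, return_inverse=True)
    n_fam = fams_k.size
    # within-family demeaning
    fam_means_g = np.zeros((n_fam, g.shape[1]))
    np.add.at(fam_means_g, inv, g)
    fam_counts = np.bincount(inv).astype(float)
    fam_means_g /= fam_counts[:, None]
    fam_means_y = np.bincount(inv, weights=yk) / fam_counts
    gd = g - fam_means_g[inv]
    yd = yk - fam_means_y[inv]
    beta, se, var_within = _univariate_robust(gd, yd)
    # correct dof: demeaning absorbs one parameter per family
    n_eff = keep.sum()
    adj = np.sqrt((n_eff - 2) / max(n_eff - n_fam - 1, 1))
    se = se * adj
    dropped = {
        int(j): "no within-family variation" for j in np.nonzero(~np.isfinite(beta))[0]
    }
    return GwasResult(
        beta, se, int(n_eff), "sibling_fe", panel.snp_ids, panel.allele_freqs, dropped
    )


def write_sumstats(path: str, result: GwasResult) -> None:
    """Tab-delimited summary statistics (snp_id, effect_allele, freq, beta, se, n, design)."""
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_sumstats(path: str) -> GwasResult:
    df = pd.read_csv(path, sep="\t")
    design = df["design"].iloc[0]
    return GwasResult(
        beta=df["beta"].to_numpy(dtype=float),
        se=df["se"].to_numpy(dtype=float),
        n=int(df["n"].iloc[0]),
        design=str(design),
        snp_ids=df["snp_id"].to_numpy(),
        effect_allele_freq=df["freq"].to_numpy(dtype=float),
    )
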