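"""Polygenic index construction, measurement error, and the ORIV correction.

A polygenic index (PGI) is a weighted sum of allele counts with weights taken
from GWAS summary statistics.  Because discovery samples are finite, the
estimated weights carry sampling noise and the constructed PGI is a noisy
proxy of the true genetic score; regressing an outcome on it suffers
classical attenuation bias.  The obviously-related-instrumental-variables
(ORIV) estimator purges that bias: the discovery sample is split in half,
two independently noisy PGIs are built, and each is used as an instrument
for the other in a stacked two-equation 2SLS with standard errors clustered
on the individual (who appears once per equation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .gwas import GwasResult, regular_gwas, trio_gwas
from .panels import GenotypePanel, PedigreeIndex
from .genetics_sim import EffectProfile

__all__ = [
    "PGIWeights",
    "PGIScores",
    "OrivFit",
    "make_weights",
    "score",
    "split_sample_pgis",
    "oriv_fit",
]


@dataclass
class PGIWeights:
    """Per-SNP scoring weights tagged by their source design."""

    weights: np.ndarray
    snp_ids: np.ndarray
    effect_allele: np.ndarray
    source: str  # "oracle" | "regular" | "trio" | "sibling_fe"
    discovery_n: int | None = None
    split_id: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != np.asarray(self.snp_ids).shape[0]:
            raise ValueError("one weight per SNP required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "effect_allele": self.effect_allele,
                "weight": self.weights,
            }
        )


@dataclass
class PGIScores:
    """Standardized per-person scores; the standardization is retained."""

    values: np.ndarray
    mean: float
    sd: float
    source: str

    @property
    def raw(self) -> np.ndarray:
        return self.values * self.sd + self.mean


def make_weights(
    source: GwasResult | EffectProfile,
    snp_ids: np.ndarray | None = None,
    p_threshold: float | None = None,
    split_id: int | None = None,
) -> PGIWeights:
    """Scoring weights from GWAS summary statistics or the true effects.

    Passing the true :class:`EffectProfile` yields oracle weights (the
    infinite-discovery-sample benchmark).  ``p_threshold`` optionally keeps
    only SNPs whose association p-value is below the threshold, zeroing the
    rest (dropped SNPs from the GWAS are always zeroed).
    """
    if isinstance(source, EffectProfile):
        if snp_ids is None:
            snp_ids = np.array([f"snp{j}" for j in range(source.snp_effects.size)])
        return PGIWeights(
            weights=source.snp_effects.copy(),
            snp_ids=np.asarray(snp_ids),
            effect_allele=np.full(source.snp_effects.size, "G"),
            source="oracle",
        )
    w = np.where(np.isfinite(source.beta), source.beta, 0.0)
    if p_threshold is not None:
        z = np.abs(source.beta) / source.se
        pvals = 2 * stats.norm.sf(z)
        keep = np.isfinite(pvals) & (pvals < p_threshold)
        if not keep.any():
            raise ValueError("p_threshold filtered out every SNP")
        w = np.where(keep, w, 0.0)
    if not np.any(w != 0):
        raise ValueError("all SNPs have zero weight")
    return PGIWeights(
        weights=w,
        snp_ids=source.snp_ids,
        effect_allele=np.full(w.size, "G"),
        source=source.design,
        discovery_n=source.n,
        split_id=split_id,
    )


def score(
    panel: GenotypePanel,
    weights: PGIWeights,
    standardization_sample: np.ndarray | None = None,
) -> PGIScores:
    """Weighted allele-count sum, standardized in the declared sample.

    SNPs are aligned by id and effect allele; any mismatch is a hard error
    (no silent strand flipping).  ``standardization_sample`` is a boolean or
    index mask selecting the rows whose mean/SD define the standardization
    (default: all rows).
    """
    if not np.array_equal(np.asarray(panel.snp_ids), np.asarray(weights.snp_ids)):
        raise ValueError("SNP ids of panel and weights do not align")
    if not np.all(np.asarray(weights.effect_allele) == "G"):
        raise ValueError("effect-allele mismatch: refusing to score")
    raw = panel.values @ weights.weights
    sel = raw if standardization_sample is None else raw[standardization_sample]
    mu, sd = float(np.mean(sel)), float(np.std(sel))
    if sd == 0:
        raise ValueError("score has zero variance in the standardization sample")
    return PGIScores((raw - mu) / sd, mu, sd, weights.source)


def split_sample_pgis(
    panel: GenotypePanel,
    y: np.ndarray,
    seed: int = 0,
    design: str = "regular",
    trio_panels: tuple[GenotypePanel, GenotypePanel, PedigreeIndex] | None = None,
) -> tuple[PGIWeights, PGIWeights]:
    """Two GWAS runs on disjoint random halves of the discovery sample.

    The halves share no individuals, so the estimation noise in the two
    weight vectors is independent - the requirement for ORIV.  For odd n the
    halves differ by one individual.
    """
    n = panel.n
    if n < 4:
        raise ValueError("discovery sample too small to split (need n >= 4)")
    rng = substream(seed, "pgi_split")
    perm = rng.permutation(n)
    half_a, half_b = perm[: n // 2], perm[n // 2 :]
    if np.intersect1d(half_a, half_b).size:
        raise AssertionError("split halves overlap")  # unreachable guard
    out = []
    for k, half in enumerate((half_a, half_b)):
        if design == "regular":
            res = regular_gwas(panel.take(half), np.asarray(y)[half])
        elif design == "trio":
            if trio_panels is None:
                raise ValueError("trio design requires mother/father panels")
            mothers, fathers, ped = trio_panels
            res = trio_gwas(
                panel.take(half),
                mothers.take(ped.mother_row[half]),
                fathers.take(ped.father_row[half]),
                np.asarray(y)[half],
            )
        else:
            raise ValueError(f"unsupported split design {design!r}")
        out.append(make_weights(res, split_id=k))
    return out[0], out[1]


@dataclass
class OrivFit:
    """Stacked-2SLS measurement-error-corrected PGI coefficient."""

    beta: float
    se: float
    ols_beta: float
    ols_se: float
    first_stage_F: float
    reliability: float  # corr(score_A, score_B): the PGI reliability ratio
    n: int


def _cluster_cov(Z: np.ndarray, X: np.ndarray, e: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Cluster-robust sandwich for the just-identified IV estimator."""
    zx_inv = np.linalg.inv(Z.T @ X)
    ze = Z * e[:, None]
    n_groups = np.unique(groups).size
    sums = np.zeros((n_groups, Z.shape[1]))
    _, inv = np.unique(groups, return_inverse=True)
    np.add.at(sums, inv, ze)
    meat = sums.T @ sums
    g = n_groups
    adj = g / (g - 1) if g > 1 else 1.0
    return adj * zx_inv @ meat @ zx_inv.T


def oriv_fit(
    y: np.ndarray,
    score_a: np.ndarray,
    score_b: np.ndarray,
    controls: np.ndarray | None = None,
    f_floor: float = 10.0,
) -> OrivFit:
    """ORIV: each split-sample PGI instruments the other, stacked.

    The data are duplicated into two equations - (regressor A, instrument B)
    and (regressor B, instrument A) - sharing all control coefficients, and
    estimated by 2SLS with standard errors clustered on the individual.
    Scores are used on the scale supplied by the caller; with equal-noise
    splits, plain OLS on either score converges to ``reliability * beta``
    while ORIV converges to ``beta``.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    n = y.shape[0]
    if a.shape[0] != n or b.shape[0] != n:
        raise ValueError("scores and outcome must be aligned")
    W = np.ones((n, 1)) if controls is None else np.column_stack(
        [np.ones(n), np.asarray(controls, dtype=float)]
    )
    # first-stage strength: partial F of B in a regression of A on [W, B]
    f_stats = []
    for reg, inst in ((a, b), (b, a)):
        Zfs = np.column_stack([W, inst])
        coef, *_ = np.linalg.lstsq(Zfs, reg, rcond=None)
        resid = reg - Zfs @ coef
        sigma2 = resid @ resid / (n - Zfs.shape[1])
        cov = sigma2 * np.linalg.inv(Zfs.T @ Zfs)
        f_stats.append(float(coef[-1] ** 2 / cov[-1, -1]))
    first_f = min(f_stats)
    if first_f < f_floor:
        raise ValueError(
            f"first-stage F = {first_f:.2f} below floor {f_floor}: "
            "instruments too weak for ORIV"
        )
    # stacked system
    X = np.vstack([np.column_stack([a, W]), np.column_stack([b, W])])
    Z = np.vstack([np.column_stack([b, W]), np.column_stack([a, W])])
    ys = np.concatenate([y, y])
    groups = np.concatenate([np.arange(n), np.arange(n)])
    beta_vec = np.linalg.solve(Z.T @ X, Z.T @ ys)
    e = ys - X @ beta_vec
    cov = _cluster_cov(Z, X, e, groups)
    # reference OLS (mean of the two single-score fits)
    ols_b, ols_se = [], []
    for s in (a, b):
        Xo = np.column_stack([s, W])
        coef, *_ = np.linalg.lstsq(Xo, y, rcond=None)
        r = y - Xo @ coef
        sigma2 = r @ r / (n - Xo.shape[1])
        c = sigma2 * np.linalg.inv(Xo.T @ Xo)
        ols_b.append(coef[0])
        ols_se.append(np.sqrt(c[0, 0]))
    # reliability of a single score = corr(A, B) under equal independent noise
    ra = a - W @ np.linalg.lstsq(W, a, rcond=None)[0]
    rb = b - W @ np.linalg.lstsq(W, b, rcond=None)[0]
    rel = float(np.corrcoef(ra, rb)[0, 1])
    return OrivFit(
        beta=float(beta_vec[0]),
        se=float(np.sqrt(cov[0, 0])),
        ols_beta=float(np.mean(ols_b)),
        ols_se=float(np.mean(ols_se)),
        first_stage_F=first_f,
        reliability=rel,
        n=n,
    )
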