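"""Fully-interacted G-by-E regression, school-entry RDD, and design checks.

Two estimators form the core:

* :func:`fit_gxe` - the interacted linear model
  ``Y = b0 + bG G + bE E + bGxE (G x E) [+ bG2 G^2 + bE2 E^2] + controls
  + (G x controls) + (E x controls)``, with heteroskedasticity-robust
  standard errors.  Interacting the controls with both G and E prevents the
  interaction coefficient from absorbing spurious correlations between a
  control and either main variable.
* :func:`fit_rdd` - the school-entry regression discontinuity on the
  month-of-birth running variable, with a symmetric bandwidth around the
  September-1 cutoff, full trend/treatment/PGI interaction blocks,
  demeaned-control interactions, optional parental-PGI controls, and
  standard errors clustered by calendar month of birth (few clusters:
  inference uses t critical values with G-1 degrees of freedom; an
  HC1 fallback is available and flagged in the estimate descriptor).

Plus Table-2-style covariate balance diagnostics, the treatment-effect-at-
a-PGI-value helper, a binned-means linearity diagnostic, and the
entry-skills mediation probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import STAGES, CohortTable

__all__ = [
    "GxEEstimate",
    "RDDEstimate",
    "fit_gxe",
    "fit_rdd",
    "treatment_effect_at",
    "balance_table",
    "entry_skill_probe",
    "binned_means",
    "plot_binned_means",
]


@dataclass
class GxEEstimate:
    """Coefficients + robust covariance of the interacted model."""

    params: pd.Series
    cov: pd.DataFrame
    n: int
    descriptor: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.cov.to_numpy()
        if c.size == 0:
            return
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh((c + c.T) / 2)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("covariance must be positive semidefinite")

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def tvalue(self, name: str) -> float:
        return float(self.params[name] / self.se(name))

    def pvalue(self, name: str) -> float:
        df = self.descriptor.get("df_inference")
        t = self.tvalue(name)
        if df:
            return float(2 * stats.t.sf(abs(t), df))
        return float(2 * stats.norm.sf(abs(t)))

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        df = self.descriptor.get("df_inference")
        crit = stats.t.ppf(1 - alpha / 2, df) if df else stats.norm.ppf(1 - alpha / 2)
        b, s = float(self.params[name]), self.se(name)
        return b - crit * s, b + crit * s


@dataclass
class RDDEstimate(GxEEstimate):
    """RDD coefficient blocks; inherits the covariance accessors."""

    stage: str = ""
    bandwidth: int = 3
    cluster_by: str | None = "mob"


def _named_ols(
    y: np.ndarray,
    columns: dict[str, np.ndarray],
    cov_type: str = "HC1",
    cluster_groups: np.ndarray | None = None,
) -> tuple[pd.Series, pd.DataFrame, dict[str, Any]]:
    """OLS with a deterministic column order and robust/cluster covariance."""
    names = list(columns)
    X = np.column_stack([columns[c] for c in names])
    bad = [c for c, v in columns.items() if c != "const" and np.std(v) == 0]
    if bad:
        raise ValueError(f"zero-variance regressor(s): {bad}")
    model = sm.OLS(y, X)
    if cov_type == "cluster":
        if cluster_groups is None:
            raise ValueError("cluster covariance requires groups")
        res = model.fit(cov_type="cluster", cov_kwds={"groups": cluster_groups})
        df_inf = int(np.unique(cluster_groups).size - 1)
    else:
        res = model.fit(cov_type=cov_type)
        df_inf = int(res.df_resid)
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    meta = {"df_inference": df_inf, "cov_type": cov_type}
    return params, cov, meta


def fit_gxe(
    y: np.ndarray,
    g: np.ndarray,
    e: np.ndarray,
    controls: np.ndarray | None = None,
    control_names: Sequence[str] | None = None,
    include_quadratics: bool = False,
    include_control_interactions: bool = True,
    extra: dict[str, np.ndarray] | None = None,
    cov_type: str = "HC1",
) -> GxEEstimate:
    """Estimate the fully-interacted G-by-E model.

    ``controls`` must not be caused by G or E ("bad controls"); this is the
    caller's responsibility and cannot be checked from the data.  ``extra``
    adds named columns (e.g. parental PGIs) after the interaction blocks.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    n = y.shape[0]
    cols: dict[str, np.ndarray] = {
        "const": np.ones(n),
        "g": g,
        "e": e,
        "g_x_e": g * e,
    }
    if include_quadratics:
        cols["g_sq"] = g * g
        cols["e_sq"] = e * e
    if controls is not None:
        controls = np.atleast_2d(np.asarray(controls, dtype=float))
        if controls.shape[0] != n:
            controls = controls.T
        cnames = list(control_names or [f"x{k}" for k in range(controls.shape[1])])
        for k, name in enumerate(cnames):
            cols[name] = controls[:, k]
        if include_control_interactions:
            for k, name in enumerate(cnames):
                cols[f"g_x_{name}"] = g * controls[:, k]
            for k, name in enumerate(cnames):
                cols[f"e_x_{name}"] = e * controls[:, k]
    for name, v in (extra or {}).items():
        cols[name] = np.asarray(v, dtype=float)
    params, cov, meta = _named_ols(y, cols, cov_type=cov_type)
    meta.update(
        {
            "blocks": {
                "quadratics": include_quadratics,
                "control_interactions": include_control_interactions and controls is not None,
                "extra": sorted(extra) if extra else [],
            },
        }
    )
    return GxEEstimate(params, cov, n, meta)


_RDD_CONTROLS = ("female", "birth_1992", *[f"pc{j}" for j in range(1, 11)], "father_pgi_missing")


def fit_rdd(
    table: CohortTable,
    stage: str = "ks2",
    bandwidth_months: int = 3,
    parental_controls: bool = False,
    include_control_interactions: bool = True,
    cluster_by: str | None = "mob",
    entry_controls: bool = False,
    min_obs: int = 60,
) -> RDDEstimate:
    """School-entry RDD for one test stage.

    The sample is restricted to births within ``bandwidth_months`` either
    side of September 1 (3 -> June..November).  Controls are demeaned in the
    estimation sample before interacting, so the treatment and PGI main
    effects are the effects for a pupil with average characteristics.
    ``entry_controls`` augments the model with the Entry Assessment score
    and its PGI interaction (the mediation probe; only valid for Key Stage
    outcomes on the entry-observed subsample).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    b = int(bandwidth_months)
    if not 1 <= b <= 4:
        raise ValueError("bandwidth must be 1..4 months")
    df = table.df
    score = df[f"score_{stage}"].to_numpy(dtype=float)
    keep = np.isfinite(score) & (df["r"].to_numpy() >= -b) & (df["r"].to_numpy() <= b - 1)
    if entry_controls:
        entry = df["score_entry"].to_numpy(dtype=float)
        keep &= np.isfinite(entry)
    n = int(keep.sum())
    if n < min_obs:
        raise ValueError(
            f"only {n} usable observations for stage {stage!r} "
            f"(floor {min_obs}); is the stage fully missing?"
        )
    d = df.loc[keep]
    y = score[keep]
    pgi = d["pgi_child"].to_numpy(dtype=float)
    t = d["treated"].to_numpy(dtype=float)
    r = d["r"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {
        "const": np.ones(n),
        "pgi": pgi,
        "treated": t,
        "pgi_x_treated": pgi * t,
        "mob": r,
        "mob_x_pgi": r * pgi,
        "mob_x_treated": r * t,
        "mob_x_pgi_x_treated": r * pgi * t,
    }
    controls = {
        "female": d["female"].to_numpy(dtype=float),
        "birth_1992": (d["birth_year"].to_numpy() == 1992).astype(float),
        **{f"pc{j}": d[f"pc{j}"].to_numpy(dtype=float) for j in range(1, 11)},
        "father_pgi_missing": d["father_pgi_missing"].to_numpy(dtype=float),
    }
    for name, v in controls.items():
        vd = v - v.mean()  # demeaned in the estimation sample
        if vd.std() == 0:
            continue  # e.g. no missing fathers simulated
        cols[name] = vd
        if include_control_interactions:
            cols[f"pgi_x_{name}"] = pgi * vd
            cols[f"treated_x_{name}"] = t * vd
    if parental_controls:
        pm = d["pgi_mother"].to_numpy(dtype=float)
        pf = d["pgi_father"].to_numpy(dtype=float)
        cols["pgi_mother"] = pm
        cols["pgi_father"] = pf
        cols["pgi_mother_x_pgi"] = pm * pgi
        cols["pgi_father_x_pgi"] = pf * pgi
        cols["pgi_mother_x_treated"] = pm * t
        cols["pgi_father_x_treated"] = pf * t
    if entry_controls:
        ent = df["score_entry"].to_numpy(dtype=float)[keep]
        if np.std(ent) == 0:
            raise ValueError("entry score is constant; cannot control for it")
        cols["entry_score"] = ent
        cols["entry_x_pgi"] = ent * pgi
    if cluster_by == "mob":
        groups = d["mob"].to_numpy()
        left = np.unique(groups[t == 0]).size
        right = np.unique(groups[t == 1]).size
        if left < 2 or right < 2:
            raise ValueError("need at least 2 month-of-birth clusters per side")
        params, cov, meta = _named_ols(y, cols, cov_type="cluster", cluster_groups=groups)
    elif cluster_by is None:
        params, cov, meta = _named_ols(y, cols, cov_type="HC1")
    else:
        raise ValueError(f"unsupported cluster variable {cluster_by!r}")
    meta.update(
        {
            "blocks": {
                "control_interactions": include_control_interactions,
                "parental_controls": parental_controls,
                "entry_controls": entry_controls,
            },
            "controls": [c for c in controls if c in cols],
        }
    )
    return RDDEstimate(
        params, cov, n, meta, stage=stage, bandwidth=b, cluster_by=cluster_by
    )


def treatment_effect_at(
    est: GxEEstimate, pgi_value: float
) -> tuple[float, float]:
    """Treatment effect at a PGI value and its percent change vs PGI = 0.

    effect = d_E + d_GxE * pgi;  percent = 100 * (effect / d_E - 1).
    """
    names = est.params.index
    e_name = "treated" if "treated" in names else "e"
    i_name = "pgi_x_treated" if "pgi_x_treated" in names else "g_x_e"
    d_e = float(est.params[e_name])
    d_gxe = float(est.params[i_name])
    if d_e == 0:
        raise ValueError("treatment main effect is zero; percent change undefined")
    effect = d_e + d_gxe * pgi_value
    return effect, 100.0 * (effect / d_e - 1.0)


def _polyserial(binary: np.ndarray, cont: np.ndarray) -> float:
    """Two-step polyserial correlation for a binary-by-continuous pair.

    Rescales the Pearson (point-biserial) correlation by the ratio implied
    by a latent bivariate-normal model: r_ps = r_pb * sqrt(p q) / phi(z_p).
    """
    p = binary.mean()
    if p in (0.0, 1.0):
        return np.nan
    r_pb = np.corrcoef(binary, cont)[0, 1]
    z = stats.norm.ppf(1 - p)
    return float(r_pb * np.sqrt(p * (1 - p)) / stats.norm.pdf(z))


def balance_table(
    table: CohortTable,
    covariates: Sequence[str] | None = None,
    correction: str = "none",
    bandwidth_months: int = 3,
) -> pd.DataFrame:
    """Covariate means by treatment status with t-tests, plus treated-PGI
    correlations (Pearson and two-step polyserial, labelled).

    Covariates should be determined before (or at) birth; later-measured
    variables could themselves be affected by the treatment.  ``correction``
    in {none, holm, bonferroni} adjusts the t-test p-values.
    """
    if correction not in ("none", "holm", "bonferroni"):
        raise ValueError("correction must be none|holm|bonferroni")
    df = table.df
    b = bandwidth_months
    keep = (df["r"] >= -b) & (df["r"] <= b - 1)
    d = df.loc[keep]
    t = d["treated"].to_numpy(dtype=float)
    covariates = list(
        covariates
        or ["female", "pc1", "pc2", "pc3", "pgi_child", "pgi_mother", "pgi_father"]
    )
    rows = []
    pvals = []
    for cov_name in covariates:
        if cov_name == "birth_1992":
            x = (d["birth_year"].to_numpy() == 1992).astype(float)
        else:
            x = d[cov_name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        x1, x0 = x[ok & (t == 1)], x[ok & (t == 0)]
        tt = stats.ttest_ind(x1, x0, equal_var=False)
        rows.append(
            {
                "covariate": cov_name,
                "n_treated": x1.size,
                "mean_treated": x1.mean(),
                "n_control": x0.size,
                "mean_control": x0.mean(),
                "p_value": tt.pvalue,
                "corr_pearson": np.corrcoef(t[ok], x[ok])[0, 1],
                "corr_polyserial": _polyserial(t[ok], x[ok]),
            }
        )
        pvals.append(tt.pvalue)
    out = pd.DataFrame(rows)
    if correction != "none":
        from statsmodels.stats.multitest import multipletests

        method = {"holm": "holm", "bonferroni": "bonferroni"}[correction]
        out["p_adjusted"] = multipletests(pvals, method=method)[1]
    return out


def entry_skill_probe(
    table: CohortTable, stage: str, **rdd_kwargs
) -> dict[str, Any]:
    """Mediation probe: does the Key-Stage interaction run through entry skills?

    Fits the RDD twice on the entry-observed subsample - baseline and
    augmented with the entry score and its PGI interaction - and reports the
    shift in the treatment-by-PGI coefficient.  If the interaction operates
    through skills already present at entry, controlling for them moves it
    toward zero; interactions arising inside the schooling technology are
    unaffected.
    """
    if stage == "entry":
        raise ValueError("the probe applies to post-entry (Key Stage) outcomes")
    # restrict both fits to the entry-observed subsample for comparability
    df = table.df
    sub = CohortTable(df.loc[np.isfinite(df["score_entry"].to_numpy(dtype=float))].copy(),
                      table.truth)
    base = fit_rdd(sub, stage, entry_controls=False, **rdd_kwargs)
    aug = fit_rdd(sub, stage, entry_controls=True, **rdd_kwargs)
    return {
        "baseline": base,
        "augmented": aug,
        "gxe_baseline": float(base.params["pgi_x_treated"]),
        "gxe_augmented": float(aug.params["pgi_x_treated"]),
        "gxe_shift": float(
            aug.params["pgi_x_treated"] - base.params["pgi_x_treated"]
        ),
    }


def binned_means(
    table: CohortTable,
    stage: str,
    n_bins: int = 20,
    bandwidth_months: int = 3,
    trim: float = 3.0,
) -> pd.DataFrame:
    """PGI-binned mean scores by treatment group (linearity diagnostic).

    Returns a tidy frame suitable for plotting the score-vs-PGI relation for
    the treated and control groups separately; approximately parallel,
    linear profiles support a linear-in-PGI specification.
    """
    df = table.df
    b = bandwidth_months
    keep = (
        np.isfinite(df[f"score_{stage}"].to_numpy(dtype=float))
        & (df["r"] >= -b)
        & (df["r"] <= b - 1)
        & (df["pgi_child"].abs() <= trim)
    )
    d = df.loc[keep]
    edges = np.quantile(d["pgi_child"], np.linspace(0, 1, n_bins + 1))
    rows = []
    for treated, grp in d.groupby("treated"):
        idx = np.clip(np.searchsorted(edges, grp["pgi_child"], side="right") - 1, 0, n_bins - 1)
        for k in range(n_bins):
            sel = grp.loc[idx == k]
            if len(sel) == 0:
                continue
            rows.append(
                {
                    "treated": int(treated),
                    "bin": k,
                    "pgi_mean": sel["pgi_child"].mean(),
                    "score_mean": sel[f"score_{stage}"].mean(),
                    "n": len(sel),
                }
            )
    return pd.DataFrame(rows)


def plot_binned_means(table: CohortTable, stage: str, path: str, **kwargs):
    """Render the binned score-vs-PGI profiles by treatment group to a file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    bm = binned_means(table, stage, **kwargs)
    fig, ax = plt.subplots(figsize=(6, 4))
    for treated, grp in bm.groupby("treated"):
        ax.scatter(
            grp["pgi_mean"], grp["score_mean"],
            label="old-for-grade" if treated else "young-for-grade",
            color="black" if treated else "grey", s=18,
        )
    ax.set_xlabel("PGI (standardized)")
    ax.set_ylabel(f"mean {stage} score")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return bm
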