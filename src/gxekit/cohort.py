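"""Synthetic school-entry cohort: month of birth, test scores, missingness.

Emulates the structure of a UK birth-cohort study built around the
September-1 school-entry cutoff: children born June-August of a school year
enter school young (age ~4), children born September-November enter old
(age ~5).  Each child carries a month of birth, a birth-year indicator
(1991/92), sex, ten genetic principal components, child/mother/father
polygenic indices (father partly missing), and five test scores - an Entry
Assessment taken at school entry plus four Key Stage tests - with
stage-specific missingness.

Scores are produced either by a *reduced-form* generator (per-stage linear
coefficients on treatment, PGI, their interaction and month-of-birth trends,
with published-table-style defaults) or by the *structural* skill-formation
model of :mod:`gxekit.structural`.

Month-of-birth recode: the running variable is months since September,
``r = ((mob - 9 + 6) mod 12) - 6``, so June..November map to -3..2 with
September = 0 and the discontinuity sits between August (-1) and
September (0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "STAGES",
    "DEFAULT_STAGE_COEFS",
    "DEFAULT_MISSING_RATES",
    "CohortConfig",
    "CohortTable",
    "mob_running",
    "family_scores",
    "simulate_cohort",
    "apply_missingness",
]

STAGES = ("entry", "ks1", "ks2", "ks3", "ks4")

#: Default generating coefficients per stage.  Conventions: ``d_e`` is the
#: treatment (old-for-grade) effect, ``d_g`` the PGI main effect, ``d_gxe``
#: their interaction, ``d_mob*`` the running-variable trend blocks, ``d_gm``/
#: ``d_gf`` parental-PGI effects.  Values follow the preferred (parental-PGI
#: controlled) columns of the empirical school-entry application this module
#: emulates: entry-stage interaction positive, Key-Stage interactions
#: negative or near zero.
DEFAULT_STAGE_COEFS: dict[str, dict[str, float]] = {
    "entry": {
        "d_e": 1.151, "d_g": -0.049, "d_gxe": 0.126,
        "d_mob": -0.156, "d_mob_t": 0.064, "d_mob_g": -0.088, "d_mob_g_t": 0.138,
        "d_gm": 0.016, "d_gf": 0.114,
    },
    "ks1": {
        "d_e": 0.687, "d_g": 0.303, "d_gxe": -0.107,
        "d_mob": -0.082, "d_mob_t": 0.048, "d_mob_g": 0.040, "d_mob_g_t": -0.014,
        "d_gm": 0.093, "d_gf": -0.051,
    },
    "ks2": {
        "d_e": 0.379, "d_g": 0.319, "d_gxe": -0.093,
        "d_mob": -0.094, "d_mob_t": 0.079, "d_mob_g": 0.014, "d_mob_g_t": 0.014,
        "d_gm": 0.086, "d_gf": 0.028,
    },
    "ks3": {
        "d_e": 0.210, "d_g": 0.211, "d_gxe": 0.008,
        "d_mob": -0.022, "d_mob_t": 0.020, "d_mob_g": -0.012, "d_mob_g_t": 0.047,
        "d_gm": 0.154, "d_gf": 0.084,
    },
    "ks4": {
        "d_e": 0.274, "d_g": 0.297, "d_gxe": -0.042,
        "d_mob": -0.035, "d_mob_t": 0.020, "d_mob_g": 0.022, "d_mob_g_t": -0.002,
        "d_gm": 0.076, "d_gf": 0.035,
    },
}

#: Share of each stage's scores that is missing, plus the share of fathers
#: without a (genotyped or imputable) PGI.  Scaled to the cohort the module
#: emulates, where the Entry Assessment is observed only for a subsample.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "entry": 0.75, "ks1": 0.20, "ks2": 0.17, "ks3": 0.29, "ks4": 0.17,
}
DEFAULT_FATHER_MISSING = 0.32

#: Residual SDs chosen so generated scores have variance near one under the
#: default coefficients (before optional re-standardization).
DEFAULT_NOISE_SD: dict[str, float] = {
    "entry": 0.65, "ks1": 0.85, "ks2": 0.90, "ks3": 0.95, "ks4": 0.92,
}


def mob_running(mob: np.ndarray) -> np.ndarray:
    """Months since September: Jun..Nov -> -3..2, Sep = 0."""
    mob = np.asarray(mob, dtype=int)
    if np.any((mob < 1) | (mob > 12)):
        raise ValueError("months must lie in 1..12")
    return ((mob - 9 + 6) % 12) - 6


@dataclass
class CohortConfig:
    """Generation settings for one synthetic cohort."""

    n_children: int = 8600
    generator: str = "reduced_form"  # or "structural"
    stage_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(DEFAULT_STAGE_COEFS[s]) for s in STAGES}
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    father_pgi_missing_rate: float = DEFAULT_FATHER_MISSING
    treated_months: tuple[int, ...] = (9, 10, 11, 12)
    r_am: float = 0.0  # spousal score correlation feeding the family scores
    standardize_scores: bool = True
    standardize_pgi_post_bandwidth: bool = False  # alternative PGI convention
    confounded_pc_loading: float = 0.0  # optional population-structure mode
    skill_params: Any = None  # SkillParams when generator == "structural"

    def __post_init__(self) -> None:
        if self.generator not in ("reduced_form", "structural"):
            raise ValueError("generator must be 'reduced_form' or 'structural'")
        if self.generator == "structural" and self.skill_params is None:
            raise ValueError("structural generator requires skill_params")
        for rate in list(self.missing_rates.values()) + [self.father_pgi_missing_rate]:
            if not 0 <= rate <= 1:
                raise ValueError("missingness rates must lie in [0, 1]")


@dataclass
class CohortTable:
    """Person-level cohort records (thin wrapper over a DataFrame)."""

    df: pd.DataFrame
    truth: dict[str, Any] = field(default_factory=dict)

    SCORE_COLS = tuple(f"score_{s}" for s in STAGES)

    def __post_init__(self) -> None:
        required = {
            "mob", "r", "treated", "birth_year", "female",
            "pgi_child", "pgi_mother", "pgi_father", "father_pgi_missing",
        }
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# " + json.dumps({c: str(self.df[c].dtype) for c in self.df.columns}) + "\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str) -> "CohortTable":
        with open(path) as fh:
            header = fh.readline()
            dtypes = json.loads(header.lstrip("# "))
            df = pd.read_csv(fh, sep="\t")
        for col, dt in dtypes.items():
            df[col] = df[col].astype(dt)
        return cls(df)

    def write_truth(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


def family_scores(
    n: int, r_am: float, seed: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized (child, mother, father) genetic scores.

    Midparent quantitative-genetics model: parental scores are standard
    normal with spousal correlation ``r_am``; the child score is the
    midparent average plus independent segregation noise with variance
    ``(1 - r_am) / 2``, giving the child unit variance and the classic
    parent-child correlation ``(1 + r_am) / 2``.
    """
    rng = rng or substream(seed, "family_scores")
    s_m = rng.standard_normal(n)
    s_f = r_am * s_m + np.sqrt(1 - r_am**2) * rng.standard_normal(n)
    seg_sd = np.sqrt((1 - r_am) / 2)
    s_c = (s_m + s_f) / 2 + seg_sd * rng.standard_normal(n)
    return s_c, s_m, s_f


def _structural_scores(
    config: CohortConfig, pgi: np.ndarray, treated: np.ndarray, r: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    from .structural import cohort_scores  # local import to avoid cycle

    return cohort_scores(config.skill_params, pgi, treated, r, config.noise_sd, rng)


def simulate_cohort(
    config: CohortConfig,
    seed: int = 0,
    scores: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> CohortTable:
    """Draw a full-year cohort; the estimator applies the bandwidth later.

    ``scores`` optionally supplies (child, mother, father) PGIs from an
    SNP-level family simulation; by default the Gaussian midparent model of
    :func:`family_scores` is used (the two agree in distribution for a
    polygenic score, and the Gaussian path scales to large cohorts).
    """
    rng = substream(seed, "cohort")
    n = config.n_children
    mob = rng.integers(1, 13, size=n)
    r = mob_running(mob)
    treated = np.isin(mob, config.treated_months).astype(float)
    birth_year = rng.integers(0, 2, size=n)  # 0 = 1991, 1 = 1992
    female = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 10))

    if scores is None:
        s_c, s_m, s_f = family_scores(n, config.r_am, seed, rng)
    else:
        s_c, s_m, s_f = (np.asarray(s, dtype=float) for s in scores)
    if config.confounded_pc_loading:
        pcs[:, 0] = pcs[:, 0] + config.confounded_pc_loading * s_c

    def _std(x: np.ndarray, sel: np.ndarray | None = None) -> np.ndarray:
        ref = x if sel is None else x[sel]
        return (x - ref.mean()) / ref.std()

    band = np.abs(r + 0.5) <= 2.5  # June..November
    sel = band if config.standardize_pgi_post_bandwidth else None
    pgi_c, pgi_m, pgi_f = (_std(s, sel) for s in (s_c, s_m, s_f))

    df = pd.DataFrame(
        {
            "mob": mob,
            "r": r,
            "treated": treated,
            "birth_year": 1991 + birth_year,
            "female": female,
            "pgi_child": pgi_c,
            "pgi_mother": pgi_m,
            "pgi_father": pgi_f,
            "father_pgi_missing": np.zeros(n, dtype=bool),
        }
    )
    for j in range(10):
        df[f"pc{j + 1}"] = pcs[:, j]

    if config.generator == "structural":
        stage_scores = _structural_scores(config, pgi_c, treated, r, rng)
    else:
        stage_scores = {}
        for stage in STAGES:
            c = config.stage_coefs.get(stage, {})
            sd = config.noise_sd.get(stage, 1.0)
            score = (
                c.get("d_0", 0.0)
                + c.get("d_g", 0.0) * pgi_c
                + c.get("d_e", 0.0) * treated
                + c.get("d_gxe", 0.0) * pgi_c * treated
                + c.get("d_mob", 0.0) * r
                + c.get("d_mob_t", 0.0) * r * treated
                + c.get("d_mob_g", 0.0) * r * pgi_c
                + c.get("d_mob_g_t", 0.0) * r * pgi_c * treated
                + c.get("d_gm", 0.0) * pgi_m
                + c.get("d_gf", 0.0) * pgi_f
                + sd * rng.standard_normal(n)
            )
            stage_scores[stage] = score

    for stage in STAGES:
        score = stage_scores[stage]
        if config.standardize_scores:
            score = (score - score.mean()) / score.std()
        df[f"score_{stage}"] = score

    truth = {
        "generator": config.generator,
        "stage_coefs": config.stage_coefs if config.generator == "reduced_form" else None,
        "noise_sd": config.noise_sd,
        "standardize_scores": config.standardize_scores,
        "treated_months": list(config.treated_months),
        "r_am": config.r_am,
        "seed": seed,
    }
    return CohortTable(df, truth)


def apply_missingness(
    table: CohortTable,
    rates: dict[str, float] | None = None,
    father_rate: float | None = None,
    seed: int = 0,
) -> CohortTable:
    """Missing-completely-at-random masks for scores and the paternal PGI.

    Masked scores become NaN; masked fathers get ``father_pgi_missing=True``
    and a zeroed PGI (estimators add the standard missing-parent dummy).
    Returns a new table; counts are recorded in ``truth['missingness']``.
    """
    rates = DEFAULT_MISSING_RATES if rates is None else rates
    father_rate = DEFAULT_FATHER_MISSING if father_rate is None else father_rate
    rng = substream(seed, "missingness")
    df = table.df.copy()
    log: dict[str, int] = {}
    for stage, rate in rates.items():
        col = f"score_{stage}"
        if col not in df.columns or rate == 0:
            continue
        mask = rng.random(len(df)) < rate
        df.loc[mask, col] = np.nan
        log[col] = int(mask.sum())
    if father_rate:
        mask = rng.random(len(df)) < father_rate
        df["father_pgi_missing"] = mask
        df.loc[mask, "pgi_father"] = 0.0
        log["pgi_father"] = int(mask.sum())
    truth = dict(table.truth)
    truth["missingness"] = log
    return CohortTable(df, truth)
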