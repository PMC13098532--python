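"""Structural model of skill formation around school entry.

A child enters school at age 4 (young) or 5 (old).  Entry skill at age 4 is
a function of the genetic endowment G alone; entering at 5 adds a year at
home in which parents choose an investment x to produce extra skill.  Once
in school, skills at test time tau are produced from entry skill, G, and the
entry age.  Parents assigned the old entry age pick x by maximizing the test
outcome net of a convex investment cost.

Default functional family (``family="ces"``):

    theta4(G)            = mu0 + muG * G
    theta5(theta4, G, x) = theta4 + m5 + (a0 + aG * G) * x**alpha
    theta_tau(th, G, a)  = m(a, G) * [w_e * th**r + w_G * (g0 + gG * G)**r]**(rho/r)
    m(a, G)              = 1 + (phi + ageG * G) * 1{a = 5}
    C(x, G)              = c0 * x**(1 + eta) / (1 + eta) * (1 + cG * G)

with r < 1 (r != 0) and rho in (0, 1) so the technology is increasing and
concave in both continuous inputs on the admissible domain.  The sign of
the skill-gene cross partial is sign(rho - r): rho > r makes entry skills
and genes complements, rho < r substitutes.  One parameter per interaction
mechanism: (muG, aG) drive differential pre-entry accumulation, phi the
productivity-of-entry-skills channel, rho vs r the skill-gene interaction,
and ageG the age-gene channel.

``family="linear"`` is the separable benchmark
``theta_tau = kappa * a + w_e * th + w_G * (g0 + gG * G)`` in which every
interaction mechanism other than differential pre-entry accumulation
vanishes identically.

The treatment effect of old-for-grade entry is
``delta(G) = theta_tau(theta5*, G, 5) - theta_tau(theta4, G, 4)`` and its
genetic gradient decomposes into four mechanisms (evaluated with central
finite differences; the behavioural response dx*/dG is part of the total
derivative of theta5* unless switched off):

1. differential pre-entry accumulation,
2. change in the marginal productivity of entry skills with entry age,
3. entry-skill-gene cross partial times the entry-skill gap,
4. age-gene interaction holding entry skills fixed.

Terms (1)+(2) equal the exact first-plus-third terms of the underlying
product-rule expansion; (3)+(4) carry a first-order Taylor remainder, so the
sum differs from the exact numerical gradient by a residual that shrinks
quadratically in the entry-skill gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy import optimize

__all__ = [
    "SkillParams",
    "DecompositionResult",
    "entry_skills",
    "optimal_investment",
    "treatment_effect",
    "decompose_gxe",
    "welfare_gradient",
    "calibrate_to_cohort",
    "cohort_scores",
]

_G_DOMAIN = (-3.0, 3.0)


@dataclass
class SkillParams:
    """Parameters of the production technology, cost, and age effects."""

    family: str = "ces"
    # pre-entry skill
    mu0: float = 2.0
    muG: float = 0.35
    m5: float = 0.3          # autonomous maturation age 4 -> 5
    a0: float = 0.6          # investment productivity level
    aG: float = 0.15         # investment productivity gene gradient
    alpha: float = 0.5       # diminishing returns to investment
    # in-school technology
    w_e: float = 0.6
    w_G: float = 0.4
    r: float = 0.5           # CES curvature (< 1, != 0)
    rho: float = 0.9         # returns to scale (< 1); rho - r signs the cross partial
    g0: float = 4.0
    gG: float = 1.0
    phi: float = 0.15        # age productivity multiplier at entry age 5
    ageG: float = 0.0        # age-gene coupling (mechanism 4 dial)
    kappa: float = 0.5       # additive age effect (linear family)
    # cost
    c0: float = 0.4
    eta: float = 1.0
    cG: float = 0.0
    x_max: float = 10.0

    def __post_init__(self) -> None:
        if self.family not in ("ces", "linear"):
            raise ValueError("family must be 'ces' or 'linear'")
        if self.family == "ces":
            if not (self.r < 1 and self.r != 0):
                raise ValueError("need r < 1 and r != 0")
            if not 0 < self.rho <= 1:
                raise ValueError("need rho in (0, 1]")
            if self.w_e <= 0 or self.w_G <= 0:
                raise ValueError("CES shares must be positive")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.c0 < 0 or self.eta <= 0:
            raise ValueError("cost must be convex with nonnegative scale")
        lo, hi = _G_DOMAIN
        for g in (lo, hi):
            if self.g0 + self.gG * g <= 0:
                raise ValueError("gene input g0 + gG*G must stay positive on the domain")
            if self.family == "ces" and 1 + (self.phi + self.ageG * g) <= 0:
                raise ValueError("age multiplier must stay positive on the domain")
            if self.theta4(g) <= 0:
                raise ValueError("entry skills must stay positive on the domain")

    # -- primitives ---------------------------------------------------------

    def theta4(self, G) -> np.ndarray | float:
        return self.mu0 + self.muG * np.asarray(G, dtype=float)

    def theta5(self, theta4, G, x) -> np.ndarray | float:
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        return theta4 + self.m5 + (self.a0 + self.aG * np.asarray(G)) * x**self.alpha

    def theta_tau(self, theta_e, G, age) -> np.ndarray | float:
        theta_e = np.asarray(theta_e, dtype=float)
        G = np.asarray(G, dtype=float)
        s_G = self.g0 + self.gG * G
        if self.family == "linear":
            return self.kappa * age + self.w_e * theta_e + self.w_G * s_G
        m_age = 1.0 + (self.phi + self.ageG * G) * (age == 5)
        agg = self.w_e * theta_e**self.r + self.w_G * s_G**self.r
        return m_age * agg ** (self.rho / self.r)

    def cost(self, x, G) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return self.c0 * x ** (1 + self.eta) / (1 + self.eta) * (1 + self.cG * np.asarray(G))

    def value(self, x, G) -> np.ndarray | float:
        th5 = self.theta5(self.theta4(G), G, x)
        return self.theta_tau(th5, G, 5) - self.cost(x, G)


@dataclass
class DecompositionResult:
    """Four-mechanism split of d(treatment effect)/dG."""

    term1: float  # differential pre-entry accumulation
    term2: float  # effect on productivity of entry skills
    term3: float  # entry skill-gene interaction
    term4: float  # age-gene interaction
    gradient: float  # exact numerical d(delta)/dG
    step_h: float
    gap: float  # theta5* - theta4

    @property
    def total(self) -> float:
        return self.term1 + self.term2 + self.term3 + self.term4

    @property
    def residual(self) -> float:
        return self.total - self.gradient


def entry_skills(G, x5, entry_age: int, params: SkillParams):
    """Skill stock at school entry for the given entry age."""
    if entry_age not in (4, 5):
        raise ValueError("entry_age must be 4 or 5")
    if np.any(np.asarray(x5) < 0):
        raise ValueError("investment must be nonnegative")
    th4 = params.theta4(G)
    if entry_age == 4:
        return th4
    return params.theta5(th4, G, x5)


def optimal_investment(
    G: float, params: SkillParams, tol: float = 1e-10
) -> float:
    """Parental investment maximizing the test outcome net of cost.

    Solves the first-order condition by bounded scalar maximization of the
    value function; the result satisfies |FOC| < 1e-6 at interior optima or
    sits at a boundary with the correctly signed derivative.
    """
    neg_v = lambda x: -float(params.value(x, G))
    res = optimize.minimize_scalar(
        neg_v, bounds=(0.0, params.x_max), method="bounded",
        options={"xatol": tol, "maxiter": 500},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"investment optimization failed: {res.message}")
    x = float(res.x)
    # snap to the boundary when the unconstrained optimum is outside
    h = 1e-7
    foc = (params.value(x + h, G) - params.value(x - h, G)) / (2 * h)
    if x < 1e-6 and foc < 0:
        return 0.0
    return x


def _theta5_star(G: float, params: SkillParams, behavioural: bool = True,
                 x_fixed: float | None = None) -> tuple[float, float]:
    x = optimal_investment(G, params) if (behavioural or x_fixed is None) else x_fixed
    return float(params.theta5(params.theta4(G), G, x)), x


def treatment_effect(G: float, params: SkillParams) -> dict[str, float]:
    """Effect of old-for-grade entry on test-time skills, with its split.

    Returns the exact effect ``delta``, the first-order split into a
    pre-entry skill accumulation part and a technological age part, and the
    approximation residual.
    """
    th4 = float(params.theta4(G))
    th5, x5 = _theta5_star(G, params)
    delta = float(params.theta_tau(th5, G, 5) - params.theta_tau(th4, G, 4))
    h = 1e-5 * max(abs(th4), 1.0)
    mp4_at5 = float(
        (params.theta_tau(th4 + h, G, 5) - params.theta_tau(th4 - h, G, 5)) / (2 * h)
    )
    pre_entry = (th5 - th4) * mp4_at5
    age_effect = float(params.theta_tau(th4, G, 5) - params.theta_tau(th4, G, 4))
    return {
        "delta": delta,
        "pre_entry_part": pre_entry,
        "age_part": age_effect,
        "split_residual": pre_entry + age_effect - delta,
        "x5_star": x5,
        "theta5_star": th5,
        "theta4": th4,
    }


def decompose_gxe(
    G: float,
    params: SkillParams,
    step_h: float = 1e-4,
    behavioural_response: bool = True,
    gap_scale: float = 1.0,
) -> DecompositionResult:
    """Four-mechanism decomposition of d(delta)/dG at one genotype value.

    All derivatives are central finite differences with step ``step_h`` on
    the standardized-G scale; the investment policy is re-solved at the
    perturbed genotypes so the behavioural response is part of the total
    derivative of theta5* (set ``behavioural_response=False`` to freeze x at
    its G-level optimum).  ``gap_scale`` shrinks the entry-skill gap
    theta5* - theta4 toward zero for Taylor-remainder studies.
    """
    h = float(step_h)
    if h <= 0:
        raise ValueError("step_h must be positive")
    if h > 0.1:
        import warnings

        warnings.warn("step_h > 0.1 is too coarse for stable second differences")

    x_base = optimal_investment(G, params)

    def th4(g: float) -> float:
        return float(params.theta4(g))

    def th5s(g: float) -> float:
        th, _ = _theta5_star(g, params, behavioural_response, x_fixed=x_base)
        return th4(g) + gap_scale * (th - th4(g))

    def delta(g: float) -> float:
        return float(
            params.theta_tau(th5s(g), g, 5) - params.theta_tau(th4(g), g, 4)
        )

    gradient = (delta(G + h) - delta(G - h)) / (2 * h)
    d_th5 = (th5s(G + h) - th5s(G - h)) / (2 * h)
    d_th4 = (th4(G + h) - th4(G - h)) / (2 * h)
    t4, t5 = th4(G), th5s(G)
    gap = t5 - t4
    he = max(abs(gap), 1e-3) * 1e-2  # skill-direction step

    def mp(th: float, g: float, age: int) -> float:
        return float(
            (params.theta_tau(th + he, g, age) - params.theta_tau(th - he, g, age))
            / (2 * he)
        )

    term1 = mp(t4, G, 4) * (d_th5 - d_th4)
    term2 = (mp(t5, G, 5) - mp(t4, G, 4)) * d_th5
    cross = (mp(t4, G + h, 5) - mp(t4, G - h, 5)) / (2 * h)
    term3 = cross * gap
    dG_at5 = (
        float(params.theta_tau(t4, G + h, 5)) - float(params.theta_tau(t4, G - h, 5))
    ) / (2 * h)
    dG_at4 = (
        float(params.theta_tau(t4, G + h, 4)) - float(params.theta_tau(t4, G - h, 4))
    ) / (2 * h)
    term4 = dG_at5 - dG_at4
    return DecompositionResult(
        term1=float(term1),
        term2=float(term2),
        term3=float(term3),
        term4=float(term4),
        gradient=float(gradient),
        step_h=h,
        gap=float(gap),
    )


def welfare_gradient(G: float, params: SkillParams, step_h: float = 1e-4) -> float:
    """Genetic gradient of the *welfare* treatment effect.

    The value of old-for-grade entry nets out the investment cost:
    dDeltaV/dG = dDelta(theta)/dG - C_x * dx*/dG - C_G, evaluated
    numerically.  With a zero cost function this equals the outcome
    gradient.
    """
    h = float(step_h)
    dec = decompose_gxe(G, params, step_h=h)
    x_p = optimal_investment(G + h, params)
    x_m = optimal_investment(G - h, params)
    x_0 = optimal_investment(G, params)
    dx_dG = (x_p - x_m) / (2 * h)
    hx = max(abs(x_0), 1e-3) * 1e-3
    c_x = float((params.cost(x_0 + hx, G) - params.cost(max(x_0 - hx, 0.0), G)) /
                (hx + min(hx, x_0)))
    c_G = float((params.cost(x_0, G + h) - params.cost(x_0, G - h)) / (2 * h))
    return float(dec.gradient - c_x * dx_dG - c_G)


def value_treatment_gradient_oracle(G: float, params: SkillParams, step_h: float = 1e-4) -> float:
    """Direct central difference of DeltaV(G) = V(G) - theta_tau(theta4, G, 4)."""
    h = float(step_h)

    def dv(g: float) -> float:
        x = optimal_investment(g, params)
        return float(params.value(x, g) - params.theta_tau(params.theta4(g), g, 4))

    return (dv(G + h) - dv(G - h)) / (2 * h)


# ---------------------------------------------------------------------------
# Cohort linkage and calibration
# ---------------------------------------------------------------------------


def _policy_grid(params: SkillParams, n_grid: int = 41) -> tuple[np.ndarray, np.ndarray]:
    gg = np.linspace(*_G_DOMAIN, n_grid)
    xs = np.array([optimal_investment(g, params) for g in gg])
    return gg, xs


def implied_stage_effects(
    params: SkillParams, n_grid: int = 41
) -> dict[str, tuple[float, float]]:
    """Model-implied (treatment effect, treatment-by-G slope) per stage.

    Evaluated on a standard-normal-weighted G grid, in SDs of the pooled
    (half treated / half control) score distribution so the numbers are
    comparable with standardized-test regression coefficients.
    """
    gg, xs = _policy_grid(params, n_grid)
    w = np.exp(-gg**2 / 2)
    w /= w.sum()
    th4 = np.asarray(params.theta4(gg), dtype=float)
    th5 = np.asarray(params.theta5(th4, gg, xs), dtype=float)
    out: dict[str, tuple[float, float]] = {}

    def delta_stats(y1: np.ndarray, y0: np.ndarray) -> tuple[float, float]:
        pooled_mean = 0.5 * (y1 @ w + y0 @ w)
        pooled_var = 0.5 * ((y1 - pooled_mean) ** 2 @ w + (y0 - pooled_mean) ** 2 @ w)
        sd = np.sqrt(pooled_var) if pooled_var > 0 else 1.0
        d = (y1 - y0) / sd
        mean_d = d @ w
        mean_g = gg @ w
        var_g = (gg - mean_g) ** 2 @ w
        slope = ((gg - mean_g) * (d - mean_d)) @ w / var_g
        return float(mean_d), float(slope)

    out["entry"] = delta_stats(th5, th4)
    y1 = np.asarray(params.theta_tau(th5, gg, 5), dtype=float)
    y0 = np.asarray(params.theta_tau(th4, gg, 4), dtype=float)
    out["ks"] = delta_stats(y1, y0)
    return out


def calibrate_to_cohort(
    targets: dict[str, tuple[float, float]],
    params0: SkillParams | None = None,
    seed: int = 0,
) -> SkillParams:
    """Least-squares calibration of the technology to stage-wise RDD targets.

    ``targets`` maps ``"entry"`` and ``"ks"`` (any Key Stage) to
    (treatment effect, treatment-by-PGI interaction) pairs in test-score SD
    units.  Free parameters: (muG, a0, aG, phi, rho, ageG).  Reports
    infeasibility if the calibrated model cannot reproduce the sign pattern
    of the targets.
    """
    if "entry" not in targets or not any(k.startswith("ks") for k in targets):
        raise ValueError("targets must include the entry stage and one Key Stage")
    ks_key = next(k for k in targets if k.startswith("ks"))
    base = params0 or SkillParams()
    x0 = np.array([base.muG, base.a0, base.aG, base.phi, base.rho, base.ageG])
    lb = np.array([0.0, 0.05, -0.5, -0.5, 0.05, -0.25])
    ub = np.array([1.0, 3.0, 0.8, 1.5, 0.999, 0.25])

    def unpack(v: np.ndarray) -> SkillParams:
        return replace(
            base, muG=v[0], a0=v[1], aG=v[2], phi=v[3], rho=v[4], ageG=v[5]
        )

    tgt = np.array([*targets["entry"], *targets[ks_key]])
    # interactions are an order of magnitude smaller than main effects;
    # upweight them so the fit resolves both scales
    wts = np.array([1.0, 4.0, 1.0, 4.0])

    def resid(v: np.ndarray) -> np.ndarray:
        try:
            p = unpack(v)
        except ValueError:
            return np.full(4, 1e3)
        eff = implied_stage_effects(p, n_grid=25)
        model = np.array([*eff["entry"], *eff["ks"]])
        return (model - tgt) * wts

    sol = optimize.least_squares(
        resid, x0, bounds=(lb, ub), xtol=1e-10, ftol=1e-12, max_nfev=400
    )
    fitted = unpack(sol.x)
    eff = implied_stage_effects(fitted)
    signs_ok = all(
        np.sign(m) == np.sign(t) or t == 0
        for m, t in zip(
            [*eff["entry"], *eff["ks"]], tgt, strict=True
        )
    )
    if not signs_ok:
        raise RuntimeError(
            "calibration could not reproduce the sign pattern of the targets "
            "under the chosen functional family"
        )
    return fitted


def cohort_scores(
    params: SkillParams,
    pgi: np.ndarray,
    treated: np.ndarray,
    r: np.ndarray,
    noise_sd: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Stage scores for a simulated cohort driven by the structural model.

    Entry scores are the (age-appropriate) entry skills; Key-Stage scores
    are in-school production.  A small month-of-birth trend proxies the
    within-year age gradient, and stage noise is added on top.
    """
    g = np.clip(np.asarray(pgi, dtype=float), *_G_DOMAIN)
    treated = np.asarray(treated, dtype=float)
    gg, xs = _policy_grid(params)
    x_star = np.interp(g, gg, xs)
    th4 = np.asarray(params.theta4(g), dtype=float)
    th5 = np.asarray(params.theta5(th4, g, x_star), dtype=float)
    th_entry = np.where(treated == 1, th5, th4)
    y1 = np.asarray(params.theta_tau(th5, g, 5), dtype=float)
    y0 = np.asarray(params.theta_tau(th4, g, 4), dtype=float)
    th_ks = np.where(treated == 1, y1, y0)
    trend = -0.05 * np.asarray(r, dtype=float)
    out: dict[str, np.ndarray] = {}
    for stage in ("entry", "ks1", "ks2", "ks3", "ks4"):
        base = th_entry if stage == "entry" else th_ks
        sd = noise_sd.get(stage, 1.0)
        out[stage] = base + trend + sd * rng.standard_normal(g.shape[0])
    return out
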