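"""Synthetic relative-survival cohorts with known truth.

Each simulated subject carries two independent latent death times
(conditional on covariates, the net-survival independence assumption):

- an *expected* (other-cause) time obtained by walking the subject month by
  month through a population rate table: in each month an exponential time
  with the current monthly rate is drawn and compared with one month; the
  subject dies within the month if it is smaller, otherwise ages one month;
- a *cancer* time drawn by inverting the scenario's log-cumulative excess
  hazard, ``H_E(t | x) = -ln u`` with ``u ~ U(0, 1)``, by bracketed
  root-finding on the ln-time axis (with a floored-hazard numerical
  integration fallback when the scenario is non-monotone in time for some
  covariate patterns).

The observed time is the minimum of the two latent times and the
administrative horizon; the true cause label and the true excess and
expected hazards at exit are retained so downstream weighting and ranking
can be validated against the generating process.

Randomness uses one spawned stream per subject index, so enlarging ``n``
never reshuffles earlier subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import jitter_ties
from .dataset import CAUSE_CANCER, CAUSE_NONE, CAUSE_OTHER, SurvivalDataset
from .ratetable import RateTable
from .splines import SplineSpec, rcs_basis

logger = logging.getLogger(__name__)

__all__ = [
    "TrueEffect",
    "ScenarioSpec",
    "toy_rate_table",
    "generate_covariates",
    "simulate_expected_time",
    "simulate_cancer_time",
    "assemble_dataset",
    "gamma_from_survival_targets",
    "scenario_s1",
    "scenario_s2",
    "scenario_s3",
]

N_DRAWS_PER_SUBJECT_HEAD = 4  # u_age, u_sex, u_stage, u_dep, then monthly exps, then u_cancer


# -- scenario definition --------------------------------------------------------

@dataclass(frozen=True)
class TrueEffect:
    """True effect of one generated column on the log cumulative excess hazard.

    Numeric column: contribution ``x * (beta + alpha * ln t)``.
    Categorical column (``levels`` given): contribution ``beta[level] +
    alpha[level] * ln t`` with per-level coefficients (reference level first,
    conventionally zero).
    """

    column: str
    beta: float | tuple
    alpha: float | tuple = 0.0
    levels: tuple | None = None

    def const_slope(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (constant, ln-t slope) contribution."""
        if self.levels is None:
            x = np.asarray(x, dtype=float)
            return x * float(self.beta), x * float(self.alpha)

        def per_level(v):
            return [float(v)] * len(self.levels) if np.isscalar(v) else list(v)

        beta = dict(zip(self.levels, per_level(self.beta)))
        alpha = dict(zip(self.levels, per_level(self.alpha)))
        c = np.array([beta[v] for v in x], dtype=float)
        s = np.array([alpha[v] for v in x], dtype=float)
        return c, s


@dataclass(frozen=True)
class ScenarioSpec:
    """Generating process for one synthetic cohort."""

    n: int
    seed: int
    baseline: SplineSpec
    gamma: tuple            # (intercept, *spline coefficients) of ln H_0(t)
    effects: tuple[TrueEffect, ...] = ()
    rate_table: RateTable | None = None
    horizon: float = 8.0    # administrative follow-up limit, years
    diagnosis_year: float = 2000.5
    age_mean: float = 71.0
    age_sd: float = 11.0
    age_bounds: tuple[float, float] = (40.0, 99.0)
    sex_levels: tuple = ("f", "m")
    sex_probs: tuple = (0.5, 0.5)
    stage_levels: tuple = (1, 2, 3, 4)
    stage_probs: tuple = (0.25, 0.30, 0.25, 0.20)
    dep_levels: tuple = (1, 2, 3, 4, 5)
    dep_probs: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    name: str = "scenario"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        for label, probs in (("sex", self.sex_probs), ("stage", self.stage_probs),
                             ("dep", self.dep_probs)):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{label} probabilities must sum to 1, got {probs}")
        if len(self.gamma) != self.baseline.df + 1:
            raise ValueError("gamma must have baseline df + 1 entries (intercept first)")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise ValueError("degenerate age bounds")

    # -- truth evaluation --------------------------------------------------

    def _const_slope(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        const = np.zeros(len(X))
        slope = np.zeros(len(X))
        for eff in self.effects:
            c, s = eff.const_slope(X[eff.column].to_numpy())
            const += c
            slope += s
        return const, slope

    def true_eta(self, X: pd.DataFrame, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """ln H_E and its d/d ln t at per-subject log times ``z``; shapes (n,)."""
        g = np.asarray(self.gamma, dtype=float)
        B, dB = rcs_basis(np.asarray(z, dtype=float), self.baseline)
        const, slope = self._const_slope(X)
        eta = g[0] + B @ g[1:] + const + slope * z
        deta = dB @ g[1:] + slope
        return eta, deta

    def true_cumulative_excess_hazard(self, X: pd.DataFrame, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        eta, _ = self.true_eta(X, np.log(t))
        return np.exp(eta)

    def true_excess_hazard(self, X: pd.DataFrame, t) -> np.ndarray:
        """Analytic lambda_E at per-subject times, floored at 0."""
        t = np.asarray(t, dtype=float)
        eta, deta = self.true_eta(X, np.log(t))
        return np.maximum(np.exp(eta) * deta / t, 0.0)


def gamma_from_survival_targets(baseline: SplineSpec, targets) -> tuple:
    """Baseline coefficients that interpolate stated net-survival values.

    ``targets`` is a sequence of ``(t_years, net_survival)`` pairs, one per
    baseline parameter (df + 1): the coefficients solve
    ``gamma_0 + s(ln t_k; gamma) = ln(-ln S_k)`` exactly.  This keeps the
    scenario definitions readable (survival fractions instead of raw spline
    coefficients on an unscaled cubic basis).
    """
    targets = list(targets)
    if len(targets) != baseline.df + 1:
        raise ValueError(f"need exactly {baseline.df + 1} targets for this baseline")
    t = np.asarray([tk for tk, _ in targets], dtype=float)
    s = np.asarray([sk for _, sk in targets], dtype=float)
    if ((s <= 0) | (s >= 1)).any() or (t <= 0).any():
        raise ValueError("targets need t > 0 and survival in (0, 1)")
    B, _ = rcs_basis(np.log(t), baseline)
    A = np.column_stack([np.ones(t.size), B])
    return tuple(np.linalg.solve(A, np.log(-np.log(s))))


# -- random draws ---------------------------------------------------------------

def _subject_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _categorical(u: np.ndarray, levels, probs):
    edges = np.cumsum(probs)
    idx = np.searchsorted(edges, u, side="right")
    idx = np.minimum(idx, len(levels) - 1)
    return np.asarray(levels, dtype=object)[idx]


def generate_covariates(spec: ScenarioSpec, streams=None) -> pd.DataFrame:
    """Covariate table: age (truncated normal), sex, stage, deprivation.

    ``agez = (age - 70) / 10`` and its square are included for linear /
    quadratic age effects.  Reproducible given the scenario seed.
    """
    streams = streams or _subject_streams(spec.seed, spec.n)
    U = np.array([[g.random() for _ in range(N_DRAWS_PER_SUBJECT_HEAD)] for g in streams])
    lo, hi = spec.age_bounds
    fa = norm.cdf((lo - spec.age_mean) / spec.age_sd)
    fb = norm.cdf((hi - spec.age_mean) / spec.age_sd)
    age = spec.age_mean + spec.age_sd * norm.ppf(fa + U[:, 0] * (fb - fa))
    agez = (age - 70.0) / 10.0
    return pd.DataFrame({
        "age": age,
        "agez": agez,
        "agez2": agez**2,
        "sex": _categorical(U[:, 1], spec.sex_levels, spec.sex_probs),
        "stage": _categorical(U[:, 2], spec.stage_levels, spec.stage_probs),
        "dep": _categorical(U[:, 3], spec.dep_levels, spec.dep_probs),
        "diag_year": np.full(spec.n, spec.diagnosis_year),
    })


def simulate_expected_time(rate_table: RateTable, X: pd.DataFrame, horizon: float,
                           exp_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Month-by-month other-cause death times from a rate table.

    ``exp_draws`` holds one standard-exponential draw per subject per month.
    In month ``m`` the subject's monthly expected hazard is looked up at the
    attained age and calendar period; the subject dies at ``m + E/r`` months
    if ``E/r < 1``, else survives the month.  Survivors of every month reach
    the horizon.  Returns times in years and a died-of-other-causes flag.
    """
    n = len(X)
    n_months = exp_draws.shape[1]
    m = np.arange(n_months) / 12.0
    sidx = rate_table.strata_indices_frame(X, {"sex": "sex", "dep": "dep"})
    ages = X["age"].to_numpy(dtype=float)[:, None] + m[None, :]
    periods = X["diag_year"].to_numpy(dtype=float)[:, None] + m[None, :]
    yearly = rate_table.rate_at(ages, periods, tuple(s[:, None] for s in sidx))
    monthly = yearly / 12.0
    with np.errstate(divide="ignore"):
        u = np.where(monthly > 0, exp_draws / np.where(monthly > 0, monthly, 1.0), np.inf)
    dies = u < 1.0
    first = np.where(dies.any(axis=1), dies.argmax(axis=1), -1)
    died = first >= 0
    t = np.full(n, horizon)
    rows = np.nonzero(died)[0]
    t[rows] = (first[rows] + u[rows, first[rows]]) / 12.0
    late = t >= horizon
    t[late] = horizon
    died &= ~late
    return t, died


_Z_BRACKET = (np.log(1e-6), np.log(1e3))


def simulate_cancer_time(spec: ScenarioSpec, X: pd.DataFrame, u: np.ndarray,
                         tol: float = 1e-10) -> np.ndarray:
    """Invert ``H_E(t | x) = -ln u`` for each subject.

    Subjects whose log cumulative hazard is monotone in log time (checked
    analytically from the scenario's ln-t slopes) are solved by vectorised
    bisection on the bracket ``[1e-6, 1e3]`` years; non-monotone patterns
    fall back to numerical integration of the floored hazard.  Targets
    unreachable within the bracket yield ``+inf`` (the subject never dies of
    the disease), with a logged count.
    """
    n = len(X)
    target = np.log(-np.log(np.asarray(u, dtype=float)))
    zlo, zhi = _Z_BRACKET
    g = np.asarray(spec.gamma, dtype=float)

    zg = np.linspace(zlo, zhi, 512)
    _, dBg = rcs_basis(zg, spec.baseline)
    base_slope_min = float((dBg @ g[1:]).min())
    _, slope = spec._const_slope(X)
    monotone = base_slope_min + slope > 1e-12

    t = np.full(n, np.inf)

    idx = np.nonzero(monotone)[0]
    if idx.size:
        Xi = X.iloc[idx]
        lo = np.full(idx.size, zlo)
        hi = np.full(idx.size, zhi)
        eta_lo, _ = spec.true_eta(Xi, lo)
        eta_hi, _ = spec.true_eta(Xi, hi)
        tg = target[idx]
        never = eta_hi < tg
        immediate = eta_lo > tg
        solve = ~(never | immediate)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            eta_mid, _ = spec.true_eta(Xi, mid)
            too_low = eta_mid < tg
            lo = np.where(solve & too_low, mid, lo)
            hi = np.where(solve & ~too_low, mid, hi)
        t[idx[solve]] = np.exp(0.5 * (lo + hi))[solve]
        t[idx[immediate]] = np.exp(zlo)
        if never.any():
            logger.info("simulate_cancer_time: %d subject(s) never reach their target "
                        "cumulative hazard (time set to +inf)", int(never.sum()))

    nm = np.nonzero(~monotone)[0]
    if nm.size:
        zg = np.linspace(zlo, zhi, 4001)
        dz = zg[1] - zg[0]
        for i in nm:
            eta, deta = spec.true_eta(X.iloc[[i]], zg)
            # cumulative hazard of the floored hazard: integrand e^eta * max(eta', 0)
            f = np.exp(eta) * np.maximum(deta, 0.0)
            Ht = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dz)])
            goal = -np.log(u[i])
            k = np.searchsorted(Ht, goal)
            if k >= Ht.size:
                continue  # never reaches the target: +inf
            if k == 0:
                t[i] = np.exp(zg[0])
            else:
                frac = (goal - Ht[k - 1]) / max(Ht[k] - Ht[k - 1], tol)
                t[i] = np.exp(zg[k - 1] + frac * dz)
    return t


def assemble_dataset(spec: ScenarioSpec, jitter_deaths: bool = True,
                     round_to_months: bool = False) -> SurvivalDataset:
    """Full synthetic cohort with truth columns.

    Observed time is the minimum of the latent cancer time, the latent
    other-cause time and the administrative horizon; status is 1 unless the
    horizon wins, and the cause label records which latent time won.  The
    true excess and expected hazards at the observed time are attached as
    ``lambda_e_true`` / ``lambda_p_true``.

    ``round_to_months`` records times rounded up to whole months (as an
    administrative registry would), which creates heavy ties; by default
    tied death times are broken with :func:`ranksexplained.core.jitter_ties`
    (the administrative censoring atom at the horizon is left tied).  Pass
    ``jitter_deaths=False`` to keep ties, e.g. to study the tied-censoring
    pathology.
    """
    if spec.rate_table is None:
        raise ValueError("scenario needs a rate table (use toy_rate_table())")
    streams = _subject_streams(spec.seed, spec.n)
    X = generate_covariates(spec, streams)
    n_months = int(np.ceil(spec.horizon * 12 - 1e-9))
    exp_draws = np.array([g.standard_exponential(n_months) for g in streams])
    u_cancer = np.array([g.random() for g in streams])

    t_other, died_other = simulate_expected_time(spec.rate_table, X, spec.horizon, exp_draws)
    t_cancer = simulate_cancer_time(spec, X, u_cancer)

    t_obs = np.minimum(np.minimum(t_cancer, t_other), spec.horizon)
    cause = np.where(t_obs >= spec.horizon, CAUSE_NONE,
                     np.where(t_cancer <= t_other, CAUSE_CANCER, CAUSE_OTHER))
    t_obs = np.where(t_obs >= spec.horizon, spec.horizon, t_obs)
    status = (cause != CAUSE_NONE).astype(int)

    if round_to_months:
        t_obs = np.ceil(t_obs * 12.0 - 1e-9) / 12.0

    if jitter_deaths:
        dmask = status == 1
        dt = t_obs[dmask]
        uniq = np.unique(dt)
        if uniq.size < dt.size:
            gap = np.diff(uniq).min() if uniq.size > 1 else np.inf
            eps = min(1e-6 * float(np.median(dt)), 0.45 * gap, 0.45 * float(dt.min()))
            t_obs = t_obs.copy()
            t_obs[dmask] = jitter_ties(dt, seed=spec.seed, eps_abs=eps)

    df = X.copy()
    df["time"] = t_obs
    df["status"] = status
    df["cause"] = cause
    df["t_cancer"] = t_cancer
    df["t_other"] = t_other
    safe_t = np.maximum(t_obs, 1e-12)
    df["lambda_e_true"] = spec.true_excess_hazard(X, safe_t)
    sidx = spec.rate_table.strata_indices_frame(X, {"sex": "sex", "dep": "dep"})
    df["lambda_p_true"] = spec.rate_table.rate_at(
        X["age"].to_numpy() + t_obs, X["diag_year"].to_numpy() + t_obs, sidx)

    return SurvivalDataset(
        df=df,
        time_col="time",
        status_col="status",
        cause_col="cause",
        covariate_cols=("agez", "agez2", "sex", "stage", "dep"),
        age_col="age",
        diagnosis_date_col="diag_year",
        strata_cols={"sex": "sex", "dep": "dep"},
    )


# -- packaged scenarios and rate table ------------------------------------------

def toy_rate_table() -> RateTable:
    """Small Gompertz-like population life table (not any country's real rates).

    Ages 40-99 by single year, calendar years 1998-2012, stratified by sex
    and deprivation quintile; hazards per person-year of plausible magnitude
    for a high-income country (about 0.028/yr for a 71-year-old man in 2000).
    """
    ages = np.arange(40.0, 100.0)
    periods = np.arange(1998.0, 2013.0)
    sexes = ["f", "m"]
    deps = [1, 2, 3, 4, 5]
    a = ages[:, None, None, None] + 0.5
    p = periods[None, :, None, None]
    sexmult = np.array([0.85, 1.25])[None, None, :, None]
    depmult = (0.82 + 0.09 * (np.array(deps, dtype=float) - 1))[None, None, None, :]
    rates = np.exp(-9.8 + 0.087 * a) * sexmult * depmult * np.exp(-0.01 * (p - 2000.0))
    return RateTable(ages, periods, {"sex": sexes, "dep": deps}, rates)


_BASELINE_KNOTS = SplineSpec((np.log(0.01), np.log(8.0)), (np.log(0.5),))


def scenario_s1(n: int = 2000, seed: int = 0, **overrides) -> ScenarioSpec:
    """Simple scenario: linear proportional effect of age on the excess hazard.

    The baseline interpolates colon-cancer-like net survival (88% at 3
    months, 74% at 1 year, 55% at 5 years for a 70-year-old); the age effect
    is 0.35 per decade on the log cumulative excess hazard.
    """
    gamma = gamma_from_survival_targets(_BASELINE_KNOTS, [(0.25, 0.88), (1.0, 0.74), (5.0, 0.55)])
    return ScenarioSpec(
        n=n, seed=seed, baseline=_BASELINE_KNOTS, gamma=gamma,
        effects=(TrueEffect("agez", beta=0.35),),
        rate_table=toy_rate_table(), name="s1_like", **overrides,
    )


def scenario_s2(n: int = 2000, seed: int = 0, **overrides) -> ScenarioSpec:
    """Complex scenario: non-linear non-proportional age, non-proportional stage
    and deprivation.

    The age effect is a quadratic in standardised age multiplied by
    ``(1 + ln t)`` (a stand-in for an unpublished registry-derived shape,
    stated here explicitly); stage carries large, time-waning effects
    (lung-cancer-like lethality gradients) and deprivation small ones.
    """
    gamma = gamma_from_survival_targets(_BASELINE_KNOTS, [(0.25, 0.96), (1.0, 0.88), (5.0, 0.70)])
    return ScenarioSpec(
        n=n, seed=seed, baseline=_BASELINE_KNOTS, gamma=gamma,
        effects=(
            TrueEffect("agez", beta=0.25, alpha=0.25),
            TrueEffect("agez2", beta=0.06, alpha=0.06),
            TrueEffect("stage", beta=(0.0, 1.0, 2.0, 3.0), alpha=(0.0, -0.25, -0.40, -0.55),
                       levels=(1, 2, 3, 4)),
            TrueEffect("dep", beta=(0.0, 0.06, 0.12, 0.18, 0.25),
                       alpha=(0.0, 0.0, -0.02, -0.02, -0.04), levels=(1, 2, 3, 4, 5)),
        ),
        rate_table=toy_rate_table(),
        stage_probs=(0.16, 0.09, 0.25, 0.50),
        name="s2_like", **overrides,
    )


def scenario_s3(n: int = 2000, seed: int = 0, **overrides) -> ScenarioSpec:
    """Fully proportional counterpart of :func:`scenario_s2` (flat local RE)."""
    gamma = gamma_from_survival_targets(_BASELINE_KNOTS, [(0.25, 0.96), (1.0, 0.88), (5.0, 0.70)])
    return ScenarioSpec(
        n=n, seed=seed, baseline=_BASELINE_KNOTS, gamma=gamma,
        effects=(
            TrueEffect("agez", beta=0.30),
            TrueEffect("stage", beta=(0.0, 1.0, 2.0, 3.0), levels=(1, 2, 3, 4)),
            TrueEffect("dep", beta=(0.0, 0.06, 0.12, 0.18, 0.25), levels=(1, 2, 3, 4, 5)),
        ),
        rate_table=toy_rate_table(),
        stage_probs=(0.16, 0.09, 0.25, 0.50),
        name="s3_like", **overrides,
    )
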