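"""Ranks-explained (RE) explained-variation measures for survival models.

At every failure time ``t_i`` the subject that fails is assigned three ranks
within the risk set ``R_i`` (the ``n_i`` subjects still under observation,
failing subject included):

- ``r_null = (n_i + 1) / 2`` — the mean rank, a model with no information;
- ``r_model = 1 + #{k in R_i : lam_k(t_i) > lam_i(t_i)} + 1/2 #{ties}`` —
  the predicted failure position under the model's hazard ordering;
- ``r_perfect = 1`` — the failing record always ranked first.

RE is the ratio of summed model-explained rank variation to the total rank
variation, with inverse-probability-of-censoring weights ``1 / G(t-)`` from
the reverse Kaplan–Meier estimator, accumulated over failures up to a
horizon ``tau``.  In the relative-survival setting each death additionally
carries a cancer-death weight

    w_i = lam_E(t_i | x_i) / (lam_E(t_i | x_i) + lam_P(t_i)),

its estimated probability of being a death from the disease, yielding the
weighted measure REw; the sum of these weights estimates the number of
disease deaths.  All emitted values lie in [-1, 1] by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CAUSE_CANCER, SurvivalDataset
from .ratetable import RateTable

logger = logging.getLogger(__name__)

__all__ = [
    "RankDecomposition",
    "REResult",
    "CensoringDistribution",
    "rank_components",
    "reverse_km",
    "cancer_weight",
    "compute_re",
    "local_re",
    "smooth_series",
    "bootstrap_ci",
    "jitter_ties",
]

MODES = ("overall", "cause_specific", "weighted")
SUM_WEIGHTS_BAND = (0.30, 0.90)  # advisable share of disease deaths among all deaths


# -- rank decomposition ---------------------------------------------------------

@dataclass(frozen=True)
class RankDecomposition:
    """Ranks and weights attached to one observed failure."""

    time: float
    subject: int
    n_risk: int
    r_null: float
    r_model: float
    r_perfect: float = 1.0
    inv_g: float = 1.0       # censoring weight 1 / G(t-)
    w: float = 1.0           # cancer-death weight in [0, 1]


def rank_components(hazards_at_risk, failing: int, time: float = np.nan,
                    subject: int = -1) -> RankDecomposition:
    """Rank decomposition of one failure (weights left at their defaults).

    ``hazards_at_risk`` holds the model hazards of every subject in the risk
    set (failing subject included) evaluated at the failure time; ``failing``
    indexes the failing subject within that array.  Ties in hazards receive
    mid-rank credit, so an all-equal-hazards model scores ``r_model = r_null``.
    """
    lam = np.asarray(hazards_at_risk, dtype=float)
    if lam.size == 0:
        raise ValueError("empty risk set")
    if not np.isfinite(lam).all() or (lam < 0).any():
        raise ValueError("hazards must be finite and >= 0")
    if not 0 <= failing < lam.size:
        raise ValueError("failing subject not in the risk set")
    li = lam[failing]
    n = lam.size
    r_model = 1.0 + np.sum(lam > li) + 0.5 * (np.sum(lam == li) - 1)
    return RankDecomposition(time=float(time), subject=subject, n_risk=n,
                             r_null=(n + 1) / 2.0, r_model=float(r_model))


# -- reverse Kaplan-Meier -------------------------------------------------------

@dataclass(frozen=True)
class CensoringDistribution:
    """Kaplan–Meier estimate of the censoring survival G(t).

    Censorings are the events, deaths act as censored records.  ``at_minus``
    gives the left-continuous version used for the IPC weights: deaths at a
    time tied with censorings are weighted before the censoring mass drops G.
    """

    ctimes: np.ndarray  # unique censoring times, ascending
    surv: np.ndarray    # G just after each censoring time

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.ctimes.size == 0:
            out = np.ones_like(t)
        else:
            k = np.searchsorted(self.ctimes, t, side=side)
            out = np.where(k > 0, self.surv[np.maximum(k - 1, 0)], 1.0)
        return float(out) if out.ndim == 0 else out

    def at_minus(self, t):
        return self._eval(t, "left")

    def at(self, t):
        return self._eval(t, "right")


def reverse_km(times, d) -> CensoringDistribution:
    """Reverse Kaplan–Meier estimator of the censoring distribution.

    ``d`` is the all-cause event indicator: records with ``d = 0`` are the
    censoring events; deaths are treated as censored observations of the
    censoring process.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(d).astype(int)
    if times.size == 0:
        raise ValueError("need at least one record")
    ctimes = np.unique(times[d == 0])
    if ctimes.size == 0:
        return CensoringDistribution(np.empty(0), np.empty(0))
    n_cens = np.array([(times[d == 0] == c).sum() for c in ctimes], dtype=float)
    n_risk = np.array([(times >= c).sum() for c in ctimes], dtype=float)
    surv = np.cumprod(1.0 - n_cens / n_risk)
    return CensoringDistribution(ctimes, surv)


# -- cancer-death weight --------------------------------------------------------

def cancer_weight(lambda_e, lambda_p):
    """w = lam_E / (lam_E + lam_P), the probability a death is a disease death.

    Elementwise; ``(0, 0)`` yields 0 with a logged warning (no information on
    the cause at that time).
    """
    le = np.asarray(lambda_e, dtype=float)
    lp = np.asarray(lambda_p, dtype=float)
    if (le < 0).any() or (lp < 0).any():
        raise ValueError("hazards must be >= 0")
    total = le + lp
    both_zero = total == 0
    if np.any(both_zero):
        logger.warning("cancer_weight: %d death(s) with lambda_E = lambda_P = 0; weight set to 0",
                       int(np.sum(both_zero)))
    w = np.divide(le, total, out=np.zeros_like(le + 0.0), where=~both_zero)
    return float(w) if w.ndim == 0 else w


# -- tie breaking ---------------------------------------------------------------

def jitter_ties(times, eps_rel: float = 1e-6, seed: int = 0, eps_abs: float | None = None):
    """Break tied follow-up times by small seeded symmetric perturbations.

    Within each tied group the times are spread evenly over ``+- eps`` around
    the tied value (order randomised by ``seed``); the ordering relative to
    all distinct original times is preserved, and an error is raised if the
    perturbation would be large enough to reorder distinct times.  ``eps``
    defaults to ``eps_rel`` times the median follow-up time.
    """
    t = np.asarray(times, dtype=float)
    uniq, counts = np.unique(t, return_counts=True)
    if not (counts > 1).any():
        return t.copy()
    eps = float(eps_abs) if eps_abs is not None else eps_rel * float(np.median(t))
    if eps <= 0:
        raise ValueError("jitter epsilon must be > 0")
    # distance from each tied value to its nearest distinct neighbour
    gaps = np.diff(uniq)
    for i in np.nonzero(counts > 1)[0]:
        near = min(gaps[i - 1] if i > 0 else np.inf, gaps[i] if i < gaps.size else np.inf)
        if eps >= 0.5 * near:
            raise ValueError(
                f"jitter epsilon {eps:g} would reorder distinct times around t={uniq[i]:g} "
                f"(nearest distinct time at distance {near:g})"
            )
        if uniq[i] - eps <= 0:
            raise ValueError(f"jitter epsilon {eps:g} would produce non-positive times at t={uniq[i]:g}")
    rng = np.random.default_rng(seed)
    out = t.copy()
    for i in np.nonzero(counts > 1)[0]:
        idx = np.nonzero(t == uniq[i])[0]
        offsets = np.linspace(-0.9, 0.9, idx.size) * eps
        out[idx] = uniq[i] + rng.permutation(offsets)
    return out


def _tied_fraction(times) -> float:
    t = np.asarray(times)
    return 1.0 - np.unique(t).size / t.size


def _auto_jitter(times, jitter, jitter_seed, warn_list):
    """Resolve the jitter policy; returns possibly-jittered times."""
    t = np.asarray(times, dtype=float)
    frac = _tied_fraction(t)
    apply = jitter is True or (jitter == "auto" and frac > 0.05)
    if not apply:
        return t
    uniq = np.unique(t)
    min_gap = np.diff(uniq).min() if uniq.size > 1 else np.inf
    eps = min(1e-6 * float(np.median(t)), 0.45 * min_gap, 0.45 * float(t.min()))
    msg = (f"{frac:.1%} of follow-up times tied; jitter of +-{eps:g} applied "
           f"(administrative-censoring tie correction)")
    logger.warning(msg)
    warn_list.append(msg)
    return jitter_ties(t, seed=jitter_seed, eps_abs=eps)


# -- per-event accumulation -----------------------------------------------------

@dataclass
class _EventTerms:
    times: np.ndarray      # death times ascending, <= tau not yet applied
    subjects: np.ndarray   # row index of the failing subject
    n_risk: np.ndarray
    r_null: np.ndarray
    r_model: np.ndarray
    inv_g: np.ndarray
    m: np.ndarray          # mode weight: 1 / cause indicator / cancer weight
    num: np.ndarray        # inv_g * m * (r_null - r_model)
    den: np.ndarray        # inv_g * m * (r_null - 1)
    warnings: list[str]


def _hazard_matrix(hazards, data: SurvivalDataset, death_times: np.ndarray) -> np.ndarray:
    """Normalise a hazard provider to an (n_subjects, n_deaths) matrix."""
    from .excess import FittedExcessModel  # local import to avoid a cycle

    n, D = data.n, death_times.size
    if isinstance(hazards, FittedExcessModel):
        return hazards.hazard_matrix(data, death_times)
    if callable(hazards):
        cols = [np.asarray(hazards(t), dtype=float) for t in death_times]
        return np.column_stack(cols) if D else np.empty((n, 0))
    arr = np.asarray(hazards, dtype=float)
    if arr.shape == (n,):
        return np.repeat(arr[:, None], D, axis=1)
    if arr.shape == (n, D):
        return arr
    raise ValueError(f"hazard provider shape {arr.shape} incompatible with n={n}, deaths={D}")


def _resolve_lambda_p(expected, data: SurvivalDataset) -> np.ndarray:
    if expected is None:
        raise ValueError("mode='weighted' requires a rate table or a lambda_P vector")
    if isinstance(expected, RateTable):
        return data.expected_hazard_at_exit(expected)
    arr = np.asarray(expected, dtype=float)
    if arr.shape != (data.n,):
        raise ValueError("expected-hazard vector must have one entry per subject")
    return arr


def _event_terms(data: SurvivalDataset, hazards, mode: str, expected=None,
                 jitter="auto", jitter_seed: int = 0) -> _EventTerms:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    warn_list: list[str] = []

    raw = np.asarray(hazards) if not callable(hazards) and not hasattr(hazards, "hazard_matrix") else None
    if raw is not None and raw.ndim == 2 and jitter != False:  # noqa: E712 - tri-state flag
        jitter = False  # a positional matrix cannot follow reordered death columns
    times = _auto_jitter(data.time, jitter, jitter_seed, warn_list)
    if not np.array_equal(times, data.time):
        data = data.with_times(times)
    d = data.status

    death_rows = np.nonzero(d == 1)[0]
    death_order = death_rows[np.argsort(times[death_rows], kind="stable")]
    death_times = times[death_order]
    D = death_order.size

    M = _hazard_matrix(hazards, data, death_times)
    if (M < 0).any():
        raise ValueError("ranking hazards must be >= 0 (floor model hazards first)")

    order = np.argsort(times, kind="stable")
    ts = times[order]

    n_risk = np.empty(D, dtype=float)
    r_model = np.empty(D, dtype=float)
    for j, (i, tj) in enumerate(zip(death_order, death_times)):
        start = np.searchsorted(ts, tj, side="left")
        risk = order[start:]
        lam = M[risk, j]
        li = M[i, j]
        n_risk[j] = risk.size
        r_model[j] = 1.0 + np.sum(lam > li) + 0.5 * (np.sum(lam == li) - 1)
    r_null = (n_risk + 1) / 2.0

    G = reverse_km(times, d)
    g_minus = np.asarray(G.at_minus(death_times), dtype=float).reshape(D)
    if (g_minus == 0).any():
        t_bad = death_times[g_minus == 0][0]
        raise ValueError(
            f"G(t-) = 0 at event time {t_bad:g}: censoring support exhausted; "
            f"truncate tau strictly below {t_bad:g}"
        )
    inv_g = 1.0 / g_minus

    if mode == "overall":
        m = np.ones(D)
    elif mode == "cause_specific":
        m = (data.cause[death_order] == CAUSE_CANCER).astype(float)
    else:
        lam_p = _resolve_lambda_p(expected, data)[death_order]
        lam_e = M[death_order, np.arange(D)]
        m = np.asarray(cancer_weight(lam_e, lam_p), dtype=float).reshape(D)

    num = inv_g * m * (r_null - r_model)
    den = inv_g * m * (r_null - 1.0)
    return _EventTerms(death_times, death_order, n_risk, r_null, r_model,
                       inv_g, m, num, den, warn_list)


# -- results --------------------------------------------------------------------

@dataclass
class REResult:
    """Overall, time-varying and (optionally) local explained variation."""

    mode: str
    tau: float
    overall: float
    ci: tuple[float, float, float] | None            # (level, lower, upper)
    grid_times: np.ndarray
    grid_values: np.ndarray
    local_times: np.ndarray | None
    local_values: np.ndarray | None
    local_smoothed: np.ndarray | None
    sum_weights: float
    n_deaths: int
    prop_cancer: float
    warnings: list[str] = field(default_factory=list)

    def grid_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.grid_times, "re": self.grid_values})

    def local_frame(self) -> pd.DataFrame:
        if self.local_times is None:
            raise ValueError("no local series computed")
        return pd.DataFrame({"time": self.local_times, "local_re": self.local_values,
                             "local_re_smoothed": self.local_smoothed})

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [None if not np.isfinite(v) else float(v) for v in a]

        return {
            "mode": self.mode,
            "tau": self.tau,
            "overall": None if not np.isfinite(self.overall) else self.overall,
            "ci": None if self.ci is None else {"level": self.ci[0], "lower": self.ci[1],
                                                "upper": self.ci[2]},
            "grid_times": arr(self.grid_times),
            "grid_values": arr(self.grid_values),
            "local_times": arr(self.local_times),
            "local_values": arr(self.local_values),
            "local_smoothed": arr(self.local_smoothed),
            "sum_weights": self.sum_weights,
            "n_deaths": self.n_deaths,
            "prop_cancer": self.prop_cancer,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def default_tau(times, d) -> float:
    """Default horizon: last death strictly before an administrative censoring atom.

    If the largest observed time is shared by at least two censored records
    (the signature of administrative censoring), the horizon is the last
    death time strictly below it; otherwise it is simply the last death time.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(d).astype(int)
    death_t = times[d == 1]
    if death_t.size == 0:
        raise ValueError("no deaths in the data")
    t_max = times.max()
    n_cens_at_max = int(np.sum((times == t_max) & (d == 0)))
    if n_cens_at_max >= 2:
        before = death_t[death_t < t_max]
        if before.size:
            return float(before.max())
    return float(death_t.max())


def _default_grid(tau: float) -> np.ndarray:
    """Month 1, then every 3 months up to tau (in years)."""
    pts = [1.0 / 12.0] + list(np.arange(0.25, tau + 1e-9, 0.25))
    return np.asarray([p for p in pts if p <= tau + 1e-12])


def compute_re(
    data: SurvivalDataset,
    hazards,
    mode: str = "weighted",
    tau: float | None = None,
    grid=None,
    expected=None,
    jitter="auto",
    jitter_seed: int = 0,
    local_window: int | None = None,
    smooth_span: float = 0.3,
) -> REResult:
    """Cumulative explained variation RE / REw up to ``tau`` and on a time grid.

    Parameters
    ----------
    data
        Subject-level follow-up records.
    hazards
        Hazard provider for the ranking: a fitted excess model, a per-subject
        risk-score vector (time-constant), an (n_subjects, n_deaths) matrix
        aligned to deaths in ascending time order, or a callable ``t ->
        hazards of all subjects at t``.
    mode
        ``"overall"`` (all deaths count fully), ``"cause_specific"`` (only
        deaths labelled as disease deaths count), or ``"weighted"`` (each
        death weighted by its model-estimated probability of being a disease
        death, the REw of the relative-survival setting).
    tau
        Horizon; defaults to the last death strictly before an administrative
        censoring atom (see :func:`default_tau`).
    grid
        Reporting times for the cumulative curve; default month 1 then
        quarterly.
    expected
        Rate table or per-subject lambda_P vector (required for weighted mode).
    jitter
        ``"auto"`` (break ties when more than 5% of times are tied), True, or
        False.
    local_window
        If given, also compute the local RE series with this window size.
    """
    terms = _event_terms(data, hazards, mode, expected, jitter, jitter_seed)
    warn_list = list(terms.warnings)
    if tau is None:
        tau = default_tau(data.time, data.status)
    use = terms.times <= tau + 1e-12
    if not use.any():
        raise ValueError(f"no deaths at or before tau={tau}")
    cum_num = np.cumsum(terms.num[use])
    cum_den = np.cumsum(terms.den[use])
    if cum_den[-1] == 0:
        msg = f"explained variation undefined at tau={tau:g}: no effective events (zero denominator)"
        warnings.warn(msg, stacklevel=2)
        warn_list.append(msg)
        overall = np.nan
    else:
        overall = float(cum_num[-1] / cum_den[-1])

    grid_times = _default_grid(tau) if grid is None else np.asarray(grid, dtype=float)
    k = np.searchsorted(terms.times[use], grid_times, side="right")
    grid_values = np.full(grid_times.size, np.nan)
    ok = k > 0
    kk = np.maximum(k - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = cum_num[kk] / cum_den[kk]
    grid_values[ok & (cum_den[kk] != 0)] = vals[ok & (cum_den[kk] != 0)]

    n_deaths = int(use.sum())
    sum_w = float(terms.m[use].sum())
    prop = sum_w / n_deaths if n_deaths else np.nan
    if mode in ("weighted", "cause_specific") and not (SUM_WEIGHTS_BAND[0] <= prop <= SUM_WEIGHTS_BAND[1]):
        msg = (f"estimated share of disease deaths {prop:.1%} lies outside the advisable "
               f"{SUM_WEIGHTS_BAND[0]:.0%}-{SUM_WEIGHTS_BAND[1]:.0%} band; "
               f"excess hazard estimates may be unstable")
        logger.warning(msg)
        warn_list.append(msg)

    local_t = local_v = local_s = None
    if local_window is not None:
        local_t, local_v = _local_from_terms(terms, local_window)
        local_s = smooth_series(local_v, smooth_span)

    return REResult(mode=mode, tau=float(tau), overall=overall, ci=None,
                    grid_times=grid_times, grid_values=grid_values,
                    local_times=local_t, local_values=local_v, local_smoothed=local_s,
                    sum_weights=sum_w, n_deaths=n_deaths, prop_cancer=prop,
                    warnings=warn_list)


def _local_from_terms(terms: _EventTerms, x: int):
    if x < 2 or x % 2:
        raise ValueError("window size x must be an even integer >= 2")
    D = terms.times.size
    if D < 2:
        raise ValueError("need at least 2 deaths for the local series")
    h = x // 2
    cnum = np.concatenate([[0.0], np.cumsum(terms.num)])
    cden = np.concatenate([[0.0], np.cumsum(terms.den)])
    j = np.arange(D)
    lo = np.maximum(0, j - h)
    hi = np.minimum(D - 1, j + h)
    num = cnum[hi + 1] - cnum[lo]
    den = cden[hi + 1] - cden[lo]
    keep = den != 0
    if not keep.all():
        logger.info("local RE undefined (zero window denominator) at %d of %d events",
                    int((~keep).sum()), D)
    return terms.times[keep], num[keep] / den[keep]


def local_re(
    data: SurvivalDataset,
    hazards,
    mode: str = "weighted",
    window: int = 20,
    expected=None,
    jitter="auto",
    jitter_seed: int = 0,
):
    """Local (instantaneous) RE: per-event windows of ``window`` failures.

    For each death (index ``j`` in time order) the RE numerator and
    denominator are restricted to deaths with index in ``[j - window/2,
    j + window/2]``, truncated at the ends of the series.  Returns
    ``(event_times, local_values)`` with undefined windows dropped.
    """
    terms = _event_terms(data, hazards, mode, expected, jitter, jitter_seed)
    return _local_from_terms(terms, window)


def smooth_series(values, span: float = 0.3):
    """Running-mean (degree-0 locally weighted) smoother over the event index.

    ``span`` is the fraction of the series length in each window; output is
    clipped to [-1, 1].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    k = max(1, int(round(span * v.size)))
    h = k // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    j = np.arange(v.size)
    lo = np.maximum(0, j - h)
    hi = np.minimum(v.size - 1, j + h)
    out = (c[hi + 1] - c[lo]) / (hi + 1 - lo)
    return np.clip(out, -1.0, 1.0)


def bootstrap_ci(
    data: SurvivalDataset,
    hazards,
    mode: str = "weighted",
    tau: float | None = None,
    B: int = 1999,
    level: float = 0.95,
    seed: int | None = None,
    refit: bool = False,
    fit_spec=None,
    rate_table: RateTable | None = None,
    expected=None,
    jitter="auto",
) -> tuple[float, float]:
    """Percentile bootstrap interval for RE / REw at ``tau``.

    Subjects are resampled with replacement.  With ``refit=True`` the excess
    model is re-estimated on every resample (requires ``fit_spec`` and, for
    the relative setting, ``rate_table``); with ``refit=False`` the fixed
    hazard provider is re-evaluated on the resampled subjects (a fast
    diagnostic that ignores estimation uncertainty).  Deterministic given
    ``seed``.  A resample with no effective events is redrawn (at most 10
    attempts).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if refit and fit_spec is None:
        raise ValueError("refit=True requires fit_spec")
    from .excess import FittedExcessModel, fit as fit_excess

    if isinstance(hazards, np.ndarray) and hazards.ndim == 2:
        raise TypeError("matrix hazard providers cannot be bootstrapped; pass a model, "
                        "score vector or callable")
    rng = np.random.default_rng(seed)
    n = data.n
    if tau is None:
        tau = default_tau(data.time, data.status)
    exp_arr = expected if not isinstance(expected, RateTable) else None
    values = np.empty(B)
    for b in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, n)
            sub = data.subset(idx)
            try:
                if refit:
                    model_b = fit_excess(sub, rate_table, fit_spec)
                    hz = model_b
                elif isinstance(hazards, FittedExcessModel):
                    hz = hazards
                elif callable(hazards):
                    hz = (lambda f, ix: (lambda t: np.asarray(f(t))[ix]))(hazards, idx)
                else:
                    hz = np.asarray(hazards, dtype=float)[idx]
                exp_b = expected if exp_arr is None else np.asarray(exp_arr, dtype=float)[idx]
                res = compute_re(sub, hz, mode, tau=tau, grid=np.asarray([tau]),
                                 expected=exp_b if mode == "weighted" else None,
                                 jitter=jitter)
                if np.isfinite(res.overall):
                    values[b] = res.overall
                    break
            except ValueError:
                pass
        else:
            raise RuntimeError("bootstrap: 10 consecutive resamples without effective events")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lower), float(upper)
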