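"""Flexible parametric excess hazard models on the log cumulative hazard scale.

The model is Royston–Parmar style: with ``z = ln t``,

    ln H_E(t | x) = gamma_0 + s(z; gamma) + sum_k beta_k' Z_k(x)
                    + sum_k (vec alpha_k)' [Z_k(x) (x) T_k(z)]

where ``s`` is a restricted cubic spline in log time (the baseline),
``Z_k`` the design columns of covariate term ``k`` (identity, categorical
indicators, or a restricted cubic spline in the covariate), and the optional
Kronecker blocks ``Z_k (x) T_k(z)`` carry time-dependent (non-proportional)
effects through a spline basis ``T_k`` in log time (one basis column, i.e.
``ln t`` itself, by default).

The excess hazard follows analytically:

    lambda_E(t | x) = H_E(t | x) * (1 / t) * d ln H_E / d ln t .

In the relative-survival setting the model is estimated by maximising

    l(theta) = sum_i [ d_i ln(lambda_P_i(t_i) + lambda_E(t_i | x_i)) - H_E(t_i | x_i) ]

where ``lambda_P_i`` is the expected (life-table) hazard of subject ``i`` at
their own follow-up time; the expected cumulative hazard enters only as an
additive constant and is dropped.  With ``lambda_P = 0`` this is exactly the
ordinary (cause-specific) Royston–Parmar likelihood.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dataset import SurvivalDataset
from .ratetable import RateTable
from .splines import SplineSpec, knots_for, rcs_basis

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateTerm",
    "ExcessModelSpec",
    "FittedExcessModel",
    "fit",
    "neg_log_likelihood",
    "log_cumulative_excess_hazard",
    "excess_hazard",
    "hazard_matrix",
]


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate term of an excess hazard model.

    transform: "identity" (single linear column), "categorical" (indicator
    per non-reference level; the first level is the reference), or "rcs"
    (restricted cubic spline in the covariate with ``df`` columns).
    ``tvc_df > 0`` adds a time-dependent effect: the term's columns interact
    with a ``tvc_df``-column spline basis in log time (``tvc_df = 1`` is the
    classical ``ln t`` interaction).
    """

    name: str
    transform: str = "identity"
    levels: tuple | None = None
    df: int = 2
    tvc_df: int = 0

    def __post_init__(self):
        if self.transform not in ("identity", "categorical", "rcs"):
            raise ValueError(f"unknown transform {self.transform!r} for term {self.name!r}")
        if self.tvc_df < 0:
            raise ValueError("tvc_df must be >= 0")


@dataclass(frozen=True)
class ExcessModelSpec:
    """Baseline spline plus covariate terms.

    ``baseline`` is either an integer df (knots resolved from the event
    times at fit time: boundary at min/max of ln event times, interior at
    quantiles — tertiles for df = 3) or an explicit :class:`SplineSpec`.
    """

    baseline: SplineSpec | int = 3
    terms: tuple[CovariateTerm, ...] = ()

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"term names must be unique, got {names}")


@dataclass
class _ResolvedTerm:
    term: CovariateTerm
    levels: list | None            # categorical levels (ref first)
    cov_spline: SplineSpec | None  # rcs-in-covariate knots
    tvc_spline: SplineSpec | None  # time-interaction basis in ln t
    col_names: list[str] = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return len(self.col_names)

    def Z(self, df: pd.DataFrame) -> np.ndarray:
        t = self.term
        col = df[t.name]
        if t.transform == "identity":
            return col.to_numpy(dtype=float)[:, None]
        if t.transform == "categorical":
            vals = col.to_numpy()
            unknown = ~np.isin(vals, self.levels)
            if unknown.any():
                raise ValueError(
                    f"term {t.name!r}: level {vals[unknown][0]!r} absent from fitted levels {self.levels}"
                )
            return np.column_stack([(vals == lvl).astype(float) for lvl in self.levels[1:]])
        basis, _ = rcs_basis(col.to_numpy(dtype=float), self.cov_spline)
        return basis


class ExcessDesign:
    """Resolved design: knot placements, categorical levels, parameter layout."""

    def __init__(self, spec: ExcessModelSpec, baseline: SplineSpec, terms: list[_ResolvedTerm]):
        self.spec = spec
        self.baseline = baseline
        self.terms = terms
        names = ["intercept"]
        names += [f"ln_t_b{j}" for j in range(baseline.df)]
        self._beta_slices: list[slice] = []
        self._alpha_slices: list[slice | None] = []
        for rt in terms:
            start = len(names)
            names += [f"{c}" for c in rt.col_names]
            self._beta_slices.append(slice(start, len(names)))
            if rt.tvc_spline is not None:
                start = len(names)
                for c in rt.col_names:
                    names += [f"{c}:lnt_b{j}" for j in range(rt.tvc_spline.df)]
                self._alpha_slices.append(slice(start, len(names)))
            else:
                self._alpha_slices.append(None)
        self.param_names = names
        self.n_params = len(names)

    @classmethod
    def resolve(cls, spec: ExcessModelSpec, data: SurvivalDataset) -> "ExcessDesign":
        log_event_times = np.log(data.time[data.status == 1])
        if isinstance(spec.baseline, SplineSpec):
            baseline = spec.baseline
        else:
            baseline = knots_for(log_event_times, int(spec.baseline))
        terms = []
        for term in spec.terms:
            levels = cov_spline = tvc_spline = None
            if term.transform == "categorical":
                levels = list(term.levels) if term.levels is not None else (
                    sorted(pd.unique(data.df[term.name]).tolist())
                )
                col_names = [f"{term.name}[{lvl}]" for lvl in levels[1:]]
            elif term.transform == "rcs":
                cov_spline = knots_for(data.df[term.name].to_numpy(dtype=float), term.df)
                col_names = [f"{term.name}_s{j}" for j in range(cov_spline.df)]
            else:
                col_names = [term.name]
            if term.tvc_df == 1:
                tvc_spline = SplineSpec(baseline.boundary_knots)
            elif term.tvc_df > 1:
                tvc_spline = knots_for(log_event_times, term.tvc_df)
            terms.append(_ResolvedTerm(term, levels, cov_spline, tvc_spline, col_names))
        return cls(spec, baseline, terms)

    # -- evaluation --------------------------------------------------------

    def Z_list(self, df: pd.DataFrame) -> list[np.ndarray]:
        return [rt.Z(df) for rt in self.terms]

    def rows(self, df: pd.DataFrame, z: np.ndarray):
        """Full design rows X and d/dz rows D at per-row log times ``z``."""
        n = len(df)
        B, dB = rcs_basis(z, self.baseline)
        X = [np.ones((n, 1)), B]
        D = [np.zeros((n, 1)), dB]
        for rt, Z in zip(self.terms, self.Z_list(df)):
            X.append(Z)
            D.append(np.zeros_like(Z))
            if rt.tvc_spline is not None:
                T, dT = rcs_basis(z, rt.tvc_spline)
                X.append((Z[:, :, None] * T[:, None, :]).reshape(n, -1))
                D.append((Z[:, :, None] * dT[:, None, :]).reshape(n, -1))
        return np.hstack(X), np.hstack(D)

    def eta_matrix(self, theta: np.ndarray, df: pd.DataFrame, z: np.ndarray):
        """eta and d eta/dz on the (subject x time) grid; shapes (n, m)."""
        theta = np.asarray(theta, dtype=float)
        z = np.atleast_1d(np.asarray(z, dtype=float))
        n = len(df)
        B, dB = rcs_basis(z, self.baseline)
        p = 1 + self.baseline.df
        eta = np.full((n, z.size), theta[0]) + (B @ theta[1:p])[None, :]
        deta = np.zeros((n, z.size)) + (dB @ theta[1:p])[None, :]
        for rt, bsl, asl, Z in zip(self.terms, self._beta_slices, self._alpha_slices, self.Z_list(df)):
            eta += (Z @ theta[bsl])[:, None]
            if asl is not None:
                A = theta[asl].reshape(rt.n_cols, rt.tvc_spline.df)
                T, dT = rcs_basis(z, rt.tvc_spline)
                eta += (Z @ A) @ T.T
                deta += (Z @ A) @ dT.T
        return eta, deta

    def to_dict(self) -> dict:
        return {
            "baseline": {"boundary": list(self.baseline.boundary_knots),
                         "interior": list(self.baseline.interior_knots)},
            "terms": [
                {
                    "name": rt.term.name,
                    "transform": rt.term.transform,
                    "tvc_df": rt.term.tvc_df,
                    "levels": rt.levels,
                    "cov_spline": None if rt.cov_spline is None else {
                        "boundary": list(rt.cov_spline.boundary_knots),
                        "interior": list(rt.cov_spline.interior_knots)},
                    "tvc_spline": None if rt.tvc_spline is None else {
                        "boundary": list(rt.tvc_spline.boundary_knots),
                        "interior": list(rt.tvc_spline.interior_knots)},
                    "col_names": rt.col_names,
                }
                for rt in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExcessDesign":
        def sp(blk):
            return None if blk is None else SplineSpec(tuple(blk["boundary"]), tuple(blk["interior"]))

        baseline = sp(d["baseline"])
        terms = []
        spec_terms = []
        for td in d["terms"]:
            term = CovariateTerm(td["name"], td["transform"], tvc_df=td["tvc_df"],
                                 levels=None if td["levels"] is None else tuple(td["levels"]))
            spec_terms.append(term)
            terms.append(_ResolvedTerm(term, td["levels"], sp(td["cov_spline"]),
                                       sp(td["tvc_spline"]), list(td["col_names"])))
        return cls(ExcessModelSpec(baseline, tuple(spec_terms)), baseline, terms)


class ExcessLikelihood:
    """Negative log-likelihood (and gradient) for fixed data and lambda_P."""

    def __init__(self, design: ExcessDesign, data: SurvivalDataset, lambda_p: np.ndarray | None):
        t = data.time
        if (t <= 0).any():
            raise ValueError("all follow-up times must be > 0")
        self.t = t
        self.d = data.status.astype(bool)
        self.lambda_p = np.zeros_like(t) if lambda_p is None else np.asarray(lambda_p, dtype=float)
        if self.lambda_p.shape != t.shape or (self.lambda_p < 0).any():
            raise ValueError("lambda_p must be a non-negative vector matching the data")
        self.X, self.D = design.rows(data.df, np.log(t))
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite covariate values in the design matrix")
        self.n_params = design.n_params

    def value_and_grad(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if not np.isfinite(theta).all():
            raise ValueError("non-finite parameter vector")
        eta = self.X @ theta
        H = np.exp(eta)
        lam_e = H * (self.D @ theta) / self.t
        mu = self.lambda_p + lam_e
        d = self.d
        if np.any(mu[d] <= 0.0):
            return np.inf, np.full(self.n_params, np.nan)
        nll = -(np.sum(np.log(mu[d])) - np.sum(H))
        # d lam_e / d theta = lam_e * X + (H / t) * D
        dlam = lam_e[d, None] * self.X[d] + (H[d] / self.t[d])[:, None] * self.D[d]
        grad = -(dlam / mu[d, None]).sum(axis=0) + (H[:, None] * self.X).sum(axis=0)
        return nll, grad

    def value(self, theta: np.ndarray) -> float:
        return self.value_and_grad(theta)[0]

    def penalized_value_and_grad(self, theta: np.ndarray):
        """Optimizer-facing objective: finite repelling penalty when infeasible.

        The likelihood proper is +inf wherever an event has total hazard
        lambda_P + lambda_E <= 0; line searches need a finite value with a
        direction back towards feasibility, so infeasible points score
        ``1e8 * (1 + sum of squared violations)`` instead.
        """
        theta = np.asarray(theta, dtype=float)
        eta = self.X @ theta
        H = np.exp(eta)
        lam_e = H * (self.D @ theta) / self.t
        mu = self.lambda_p + lam_e
        d = self.d
        bad = mu[d] <= 0.0
        if bad.any():
            Xd, Dd = self.X[d], self.D[d]
            viol = -mu[d][bad]
            dlam = lam_e[d][bad, None] * Xd[bad] + (H[d][bad] / self.t[d][bad])[:, None] * Dd[bad]
            f = 1e8 * (1.0 + float(np.sum(viol**2)))
            g = 1e8 * (-2.0 * (viol[:, None] * dlam).sum(axis=0))
            return f, g
        nll = -(np.sum(np.log(mu[d])) - np.sum(H))
        dlam = lam_e[d, None] * self.X[d] + (H[d] / self.t[d])[:, None] * self.D[d]
        grad = -(dlam / mu[d, None]).sum(axis=0) + (H[:, None] * self.X).sum(axis=0)
        return nll, grad


def neg_log_likelihood(params, design: "ExcessDesign | FittedExcessModel",
                       data: SurvivalDataset, lambda_p_at_event=None) -> float:
    """Relative-survival negative log-likelihood at ``params``.

    ``lambda_p_at_event`` holds each subject's expected hazard at their own
    follow-up time (zeros for the cause-specific special case).
    """
    if isinstance(design, FittedExcessModel):
        design = design.design
    return ExcessLikelihood(design, data, lambda_p_at_event).value(np.asarray(params, float))


@dataclass
class FittedExcessModel:
    """A fitted log-cumulative excess hazard model."""

    design: ExcessDesign
    theta: np.ndarray
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    min_dlnH_dlnt: float | None = None  # monotonicity diagnostic over event times

    @property
    def param_names(self) -> list[str]:
        return self.design.param_names

    def params_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov)) if self.cov is not None else np.full(self.theta.size, np.nan)
        return pd.DataFrame({"coef": self.theta, "se": se}, index=self.param_names)

    # -- evaluation --------------------------------------------------------

    def _frame(self, x) -> pd.DataFrame:
        if isinstance(x, SurvivalDataset):
            return x.df
        if isinstance(x, pd.DataFrame):
            return x
        if isinstance(x, (dict, pd.Series)):
            return pd.DataFrame([dict(x)])
        raise TypeError(f"cannot interpret covariate values of type {type(x)}")

    def log_cumulative_excess_hazard(self, x, t):
        """ln H_E(t | x); ``t`` scalar or vector of times > 0 (years)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if (t <= 0).any():
            raise ValueError("t must be > 0")
        eta, _ = self.design.eta_matrix(self.theta, self._frame(x), np.log(t))
        return float(eta[0, 0]) if eta.size == 1 else np.squeeze(eta)

    def excess_hazard(self, x, t):
        """Analytic lambda_E(t | x) per person-year (may be negative; not floored)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if (t <= 0).any():
            raise ValueError("t must be > 0")
        eta, deta = self.design.eta_matrix(self.theta, self._frame(x), np.log(t))
        lam = np.exp(eta) * deta / t[None, :]
        return float(lam[0, 0]) if lam.size == 1 else np.squeeze(lam)

    def hazard_matrix(self, data: SurvivalDataset, times, floor: bool = True) -> np.ndarray:
        """Per-subject-per-time lambda_E; entry (i, j) = lambda_E(t_j | x_i).

        Negative analytic values are floored at 0 (with a logged count) so the
        result can feed ranking and weighting.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if (times <= 0).any():
            raise ValueError("times must be > 0")
        eta, deta = self.design.eta_matrix(self.theta, self._frame(data), np.log(times))
        lam = np.exp(eta) * deta / times[None, :]
        if floor:
            neg = lam < 0
            if neg.any():
                logger.info("hazard_matrix: floored %d negative excess-hazard entries at 0",
                            int(neg.sum()))
                lam = np.where(neg, 0.0, lam)
        return lam

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "design": self.design.to_dict(),
            "theta": self.theta.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "min_dlnH_dlnt": self.min_dlnH_dlnt,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedExcessModel":
        d = json.loads(text)
        return cls(
            design=ExcessDesign.from_dict(d["design"]),
            theta=np.asarray(d["theta"], dtype=float),
            cov=None if d["cov"] is None else np.asarray(d["cov"], dtype=float),
            loglik=d["loglik"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            min_dlnH_dlnt=d.get("min_dlnH_dlnt"),
        )


# module-level operation aliases ------------------------------------------------

def log_cumulative_excess_hazard(model: FittedExcessModel, x, t):
    return model.log_cumulative_excess_hazard(x, t)


def excess_hazard(model: FittedExcessModel, x, t):
    return model.excess_hazard(x, t)


def hazard_matrix(model: FittedExcessModel, data: SurvivalDataset, times) -> np.ndarray:
    return model.hazard_matrix(data, times)


# fitting -----------------------------------------------------------------------

def _numerical_hessian(fun_grad, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    p = theta.size
    hess = np.empty((p, p))
    for j in range(p):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        gp = fun_grad(tp)[1]
        gm = fun_grad(tm)[1]
        hess[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (hess + hess.T)


def fit(
    data: SurvivalDataset,
    rate_table: RateTable | None,
    spec: ExcessModelSpec,
    *,
    lambda_p: np.ndarray | None = None,
    gtol: float = 1e-7,
    maxiter: int = 500,
) -> FittedExcessModel:
    """Maximum-likelihood fit of an excess hazard model.

    ``rate_table`` supplies each subject's expected hazard at exit; pass
    ``None`` (and no ``lambda_p``) for an ordinary cause-specific fit.  An
    explicit ``lambda_p`` vector overrides the rate-table lookup.

    The optimiser is quasi-Newton (L-BFGS-B) with the analytic gradient, run
    on internally rescaled design columns; start values come from a fit that
    ignores the expected hazard (overall-survival model), itself started at
    the exponential-hazard solution.
    """
    n_events = data.n_deaths
    if n_events < 1:
        raise ValueError("need at least one event to fit an excess hazard model")
    design = ExcessDesign.resolve(spec, data)
    if n_events < design.n_params:
        raise ValueError(
            f"fewer events ({n_events}) than parameters ({design.n_params})"
        )
    if lambda_p is None:
        lambda_p = (
            data.expected_hazard_at_exit(rate_table) if rate_table is not None
            else np.zeros(data.n)
        )

    lik0 = ExcessLikelihood(design, data, None)        # lambda_P-ignoring (init stage)
    lik = ExcessLikelihood(design, data, lambda_p)

    # column scaling for optimizer conditioning (theta reported unscaled)
    scale = lik.X.std(axis=0)
    scale[scale < 1e-8] = 1.0

    def scaled(lk):
        def f(th_s):
            v, g = lk.penalized_value_and_grad(th_s / scale)
            return v, g / scale
        return f

    # exponential start: ln H = ln(rate) + 1 * ln t
    rate0 = n_events / data.time.sum()
    theta0 = np.zeros(design.n_params)
    theta0[0] = np.log(rate0)
    theta0[1] = 1.0

    res0 = minimize(scaled(lik0), theta0 * scale, jac=True, method="L-BFGS-B",
                    options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12})
    res = minimize(scaled(lik), res0.x, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12})
    theta = res.x / scale
    converged = bool(res.success)
    if not converged:
        logger.warning("excess model fit did not converge: %s", res.message)

    cov = None
    if converged:
        hess = _numerical_hessian(lik.value_and_grad, theta)
        try:
            cov = np.linalg.inv(hess)
            eig = np.linalg.eigvalsh(0.5 * (cov + cov.T))
            if eig.min() < -1e-10 * max(1.0, eig.max()):
                raise np.linalg.LinAlgError("covariance not PSD")
            cov = 0.5 * (cov + cov.T)
        except np.linalg.LinAlgError:
            warnings.warn("singular or indefinite information matrix; covariance unusable",
                          stacklevel=2)
            cov = None

    # monotonicity diagnostic of ln H over observed event times
    d = data.status == 1
    Xe, De = design.rows(data.df[d].reset_index(drop=True), np.log(data.time[d]))
    min_slope = float((De @ theta).min())

    return FittedExcessModel(
        design=design,
        theta=theta,
        cov=cov,
        loglik=float(-res.fun),
        converged=converged,
        n_iter=int(res.nit),
        min_dlnH_dlnt=min_slope,
    )
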