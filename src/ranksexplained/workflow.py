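"""Configuration-driven workflow: simulate, fit, measure, report.

A single YAML file describes the inputs (subject-level data, rate table,
column mapping), the excess-model formula, and the RE options; the workflow
functions (wrapped by the ``rexw`` command line) run the steps
deterministically and write JSON / delimited outputs with no timestamps, so
identical configurations yield byte-identical results.  No numeric value is
computed in the reporting layer: everything in a report is read back from an
:class:`~ranksexplained.core.REResult`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import simulate as sim
from .core import SUM_WEIGHTS_BAND, REResult, bootstrap_ci, compute_re
from .dataset import SurvivalDataset
from .excess import CovariateTerm, ExcessModelSpec, FittedExcessModel, fit
from .ratetable import RateTable, load_rate_table

__all__ = [
    "RunConfig", "load_config", "run_simulate", "run_fit", "run_re",
    "run_report", "variable_contributions",
]


# -- configuration schema -------------------------------------------------------

class RateTableConfig(BaseModel):
    path: str
    age: str = "age"
    period: str = "period"
    strata: list[str] = Field(default_factory=list)
    rate: str = "rate"
    units: Literal["per-year", "per-month", "probability"] = "per-year"


class ColumnsConfig(BaseModel):
    time: str = "time"
    status: str = "status"
    cause: Optional[str] = None
    covariates: list[str] = Field(default_factory=list)
    age: Optional[str] = None
    diagnosis_date: Optional[str] = None
    strata: dict[str, str] = Field(default_factory=dict)


class TermConfig(BaseModel):
    name: str
    transform: Literal["identity", "categorical", "rcs"] = "identity"
    df: int = 2
    tvc_df: int = 0
    levels: Optional[list] = None

    def to_term(self) -> CovariateTerm:
        return CovariateTerm(self.name, self.transform, df=self.df, tvc_df=self.tvc_df,
                             levels=None if self.levels is None else tuple(self.levels))


class ModelConfig(BaseModel):
    baseline_df: int = 3
    terms: list[TermConfig] = Field(default_factory=list)

    def to_spec(self) -> ExcessModelSpec:
        return ExcessModelSpec(self.baseline_df, tuple(t.to_term() for t in self.terms))


class BootstrapConfig(BaseModel):
    B: int = 1999
    level: float = 0.95
    seed: int = 1
    refit: bool = True


class REConfig(BaseModel):
    mode: Literal["overall", "cause_specific", "weighted"] = "weighted"
    tau: Optional[float] = None
    grid: Optional[list[float]] = None
    window: int = 20
    span: float = 0.3
    jitter: Union[bool, Literal["auto"]] = "auto"
    bootstrap: Optional[BootstrapConfig] = None


class SimulateConfig(BaseModel):
    scenario: Literal["s1", "s2", "s3"] = "s1"
    n: int = 2000
    seed: int = 0
    round_to_months: bool = False
    jitter_deaths: bool = True


class CompareConfig(BaseModel):
    """Nested-model comparison: inclusion/exclusion contribution of variables."""

    initial_terms: list[TermConfig]
    full_terms: list[TermConfig]
    variables: list[str]

    @field_validator("variables")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("compare.variables must not be empty")
        return v


class RunConfig(BaseModel):
    data: Optional[str] = None
    rate_table: Optional[RateTableConfig] = None
    columns: ColumnsConfig = Field(default_factory=ColumnsConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    re: REConfig = Field(default_factory=REConfig)
    simulate: Optional[SimulateConfig] = None
    compare: Optional[CompareConfig] = None
    output: str = "out"
    seed: int = 0

    def validate_for_re(self) -> None:
        if self.re.mode == "weighted" and self.rate_table is None:
            raise ValueError("config error: re.mode='weighted' requires a rate_table block")
        if self.re.mode == "cause_specific" and self.columns.cause is None:
            raise ValueError("config error: re.mode='cause_specific' requires columns.cause")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw or {})


# -- input loading --------------------------------------------------------------

def _load_rate_table(cfg: RunConfig) -> RateTable | None:
    if cfg.rate_table is None:
        return None
    rc = cfg.rate_table
    return load_rate_table(rc.path, {"age": rc.age, "period": rc.period,
                                     "strata": rc.strata, "rate": rc.rate},
                           rate_units=rc.units)


def load_dataset(cfg: RunConfig) -> SurvivalDataset:
    if cfg.data is None:
        raise ValueError("config error: no data path given")
    if not Path(cfg.data).exists():
        raise FileNotFoundError(f"data file not found: {cfg.data}")
    df = pd.read_csv(cfg.data)
    c = cfg.columns
    return SurvivalDataset(df, time_col=c.time, status_col=c.status, cause_col=c.cause,
                           covariate_cols=tuple(c.covariates), age_col=c.age,
                           diagnosis_date_col=c.diagnosis_date, strata_cols=c.strata)


# -- commands -------------------------------------------------------------------

_SCENARIOS = {"s1": sim.scenario_s1, "s2": sim.scenario_s2, "s3": sim.scenario_s3}


def run_simulate(cfg: RunConfig, outdir: str | Path | None = None) -> Path:
    """Write a simulated cohort (CSV) and its truth sidecar (JSON)."""
    sc = cfg.simulate or SimulateConfig()
    outdir = Path(outdir or cfg.output)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = _SCENARIOS[sc.scenario](n=sc.n, seed=sc.seed)
    ds = sim.assemble_dataset(spec, jitter_deaths=sc.jitter_deaths,
                              round_to_months=sc.round_to_months)
    data_path = outdir / "simulated_data.csv"
    ds.df.to_csv(data_path, index=False)
    truth = {
        "scenario": spec.name, "n": spec.n, "seed": sc.seed, "horizon": spec.horizon,
        "gamma": list(spec.gamma),
        "baseline_knots": {"boundary": list(spec.baseline.boundary_knots),
                           "interior": list(spec.baseline.interior_knots)},
        "effects": [
            {"column": e.column, "beta": e.beta, "alpha": e.alpha,
             "levels": None if e.levels is None else list(e.levels)}
            for e in spec.effects
        ],
        "n_deaths": int(ds.n_deaths),
        "n_cancer_deaths": int((ds.cause == "cancer").sum()),
    }
    (outdir / "simulated_truth.json").write_text(json.dumps(truth, indent=2))
    return data_path


def run_fit(cfg: RunConfig, outdir: str | Path | None = None) -> FittedExcessModel:
    """Fit the configured excess model and serialise it to JSON."""
    outdir = Path(outdir or cfg.output)
    outdir.mkdir(parents=True, exist_ok=True)
    data = load_dataset(cfg)
    rt = _load_rate_table(cfg)
    model = fit(data, rt, cfg.model.to_spec())
    (outdir / "model.json").write_text(model.to_json())
    return model


def _compute(cfg: RunConfig, data: SurvivalDataset, rt: RateTable | None,
             spec: ExcessModelSpec) -> tuple[FittedExcessModel, REResult]:
    model = fit(data, rt if cfg.re.mode == "weighted" else None, spec)
    re_cfg = cfg.re
    res = compute_re(data, model, re_cfg.mode, tau=re_cfg.tau, grid=re_cfg.grid,
                     expected=rt if re_cfg.mode == "weighted" else None,
                     jitter=re_cfg.jitter, jitter_seed=cfg.seed,
                     local_window=re_cfg.window, smooth_span=re_cfg.span)
    return model, res


def run_re(cfg: RunConfig, outdir: str | Path | None = None) -> REResult:
    """Full RE workflow: fit, measure, optional bootstrap, write outputs."""
    cfg.validate_for_re()
    outdir = Path(outdir or cfg.output)
    outdir.mkdir(parents=True, exist_ok=True)
    data = load_dataset(cfg)
    rt = _load_rate_table(cfg)
    model, res = _compute(cfg, data, rt, cfg.model.to_spec())
    if cfg.re.bootstrap is not None:
        bc = cfg.re.bootstrap
        lo, hi = bootstrap_ci(data, model, cfg.re.mode, tau=res.tau, B=bc.B,
                              level=bc.level, seed=bc.seed, refit=bc.refit,
                              fit_spec=cfg.model.to_spec(),
                              rate_table=rt if cfg.re.mode == "weighted" else None,
                              expected=rt if cfg.re.mode == "weighted" else None,
                              jitter=cfg.re.jitter)
        res.ci = (bc.level, lo, hi)
    (outdir / "model.json").write_text(model.to_json())
    (outdir / "re_result.json").write_text(res.to_json())
    res.grid_frame().to_csv(outdir / "re_cumulative.csv", index=False)
    if res.local_times is not None:
        res.local_frame().to_csv(outdir / "re_local.csv", index=False)
    if cfg.compare is not None:
        tbl = variable_contributions(cfg, data, rt)
        tbl.to_csv(outdir / "re_contributions.csv", index=False)
    return res


def variable_contributions(cfg: RunConfig, data: SurvivalDataset,
                           rt: RateTable | None) -> pd.DataFrame:
    """Inclusion/exclusion REw contribution of each declared variable.

    Inclusion: change in REw when the variable is added to the initial
    model, also as a percentage of the initial model's REw.  Exclusion:
    change when the variable is removed from the full model, as a
    percentage of the full model's REw.
    """
    cmp_cfg = cfg.compare
    if cmp_cfg is None:
        raise ValueError("no compare block in the configuration")

    def rew(terms: list[TermConfig]) -> float:
        spec = ExcessModelSpec(cfg.model.baseline_df, tuple(t.to_term() for t in terms))
        return _compute(cfg, data, rt, spec)[1].overall

    initial = rew(cmp_cfg.initial_terms)
    full = rew(cmp_cfg.full_terms)
    full_by_name = {t.name: t for t in cmp_cfg.full_terms}
    rows = []
    for var in cmp_cfg.variables:
        if var not in full_by_name:
            raise ValueError(f"compare variable {var!r} is not a term of the full model")
        with_v = rew(cmp_cfg.initial_terms + [full_by_name[var]])
        without_v = rew([t for t in cmp_cfg.full_terms if t.name != var])
        rows.append({
            "variable": var,
            "re_initial_plus": with_v,
            "inclusion_diff": with_v - initial,
            "inclusion_pct_of_initial": 100.0 * (with_v - initial) / initial if initial else np.nan,
            "re_full_minus": without_v,
            "exclusion_diff": full - without_v,
            "exclusion_pct_of_full": 100.0 * (full - without_v) / full if full else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["re_initial"] = initial
    out.attrs["re_full"] = full
    return out


def run_report(result_path) -> str:
    """Human-readable summary of a written REResult JSON (no new computation)."""
    with open(result_path) as fh:
        d = json.load(fh)
    lines = [
        f"Explained variation ({d['mode']} mode)",
        f"  horizon tau        : {d['tau']:.4g} years",
        f"  overall RE         : {d['overall']:.4f}" if d["overall"] is not None
        else "  overall RE         : undefined (zero denominator)",
    ]
    if d.get("ci"):
        ci = d["ci"]
        lines.append(f"  {ci['level']:.0%} bootstrap CI  : ({ci['lower']:.4f}, {ci['upper']:.4f})")
    prop = d["prop_cancer"]
    lo, hi = SUM_WEIGHTS_BAND
    ok = lo <= prop <= hi
    lines += [
        f"  deaths by tau      : {d['n_deaths']}",
        f"  sum of weights     : {d['sum_weights']:.1f} (estimated disease deaths)",
        f"  share of deaths    : {prop:.1%} "
        + (f"(within the {lo:.0%}-{hi:.0%} band)" if ok else f"(OUTSIDE the {lo:.0%}-{hi:.0%} band!)"),
    ]
    if d.get("grid_times"):
        lines.append("  cumulative RE(t)   : " + ", ".join(
            f"{t:.2f}y={v:.3f}" for t, v in zip(d["grid_times"][:6], d["grid_values"][:6])
            if v is not None))
    for w in d.get("warnings", []):
        lines.append(f"  warning: {w}")
    return "\n".join(lines)
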