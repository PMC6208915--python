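"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-evaluates the incremental outcomes at the low and high
endpoint of each input's range (tornado diagram data).  Probabilistic
analysis samples all inputs at once from their Table distributions —
correlated bivariate normal draws for each survival (intercept, log-scale)
pair, a normal on the log hazard ratio truncated at 1.00, beta draws for
proportions and utilities, gamma draws for costs — and summarises the
resulting incremental cloud as a cost-effectiveness acceptability curve and
net-monetary-benefit statistics on a willingness-to-pay grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TraceEngine, build_strategies
from .errors import DomainError, ParameterValidationError
from .parameters import (
    ModelParameters,
    ParameterDistribution,
    iter_scalar_ranges,
)
from .survival import LifeTable

__all__ = [
    "TornadoEntry",
    "PSADraws",
    "PSAResult",
    "one_way_dsa",
    "sample_psa",
    "run_psa",
    "tornado_frame",
]

# QALY differences below this are treated as structurally zero (floating-point
# noise from summing ~600-cycle accruals is ~1e-13 QALYs).
ZERO_QALY_TOL = 1e-10


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    """Incremental outcomes with one parameter pushed to one endpoint."""

    parameter: str
    direction: str          # "low" | "high"
    value: float
    delta_cost: float
    delta_qalys: float
    icer: float | None      # None when delta_qalys is structurally zero

    @property
    def zero_benefit(self) -> bool:
        return self.icer is None


def _incremental_at(engine: TraceEngine, p: ModelParameters):
    no_tdm, tdm = build_strategies(p)
    return engine.incremental(p, tdm, no_tdm)


def one_way_dsa(
    p: ModelParameters,
    dists: Sequence[ParameterDistribution],
    lt: LifeTable,
) -> list[TornadoEntry]:
    """Vary each scalar input to its low and high endpoint, all others at
    base, and record the incremental outcomes.  Entries are sorted by the
    swing in incremental cost, |dC(high) - dC(low)|, largest first."""
    engine = TraceEngine(p, lt)
    groups: list[tuple[float, list[TornadoEntry]]] = []
    for name, base, low, high in iter_scalar_ranges(dists):
        entries = []
        for direction, value in (("low", low), ("high", high)):
            try:
                p_mod = p.replace(**{name: value})
            except ParameterValidationError:
                raise
            dc, de = _incremental_at(engine, p_mod)
            icer = dc / de if abs(de) > ZERO_QALY_TOL else None
            entries.append(TornadoEntry(
                parameter=name, direction=direction, value=value,
                delta_cost=dc, delta_qalys=de, icer=icer))
        swing = abs(entries[1].delta_cost - entries[0].delta_cost)
        groups.append((swing, entries))
    groups.sort(key=lambda g: -g[0])
    return [e for _, entries in groups for e in entries]


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "direction": e.direction, "value": e.value,
        "delta_cost": e.delta_cost, "delta_qalys": e.delta_qalys,
        "icer": e.icer if e.icer is not None else float("nan"),
    } for e in entries])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSADraws:
    """Sampled parameter sets plus bookkeeping of truncation events."""

    n_trials: int
    seed: int
    frame: pd.DataFrame     # one column per scalar parameter + clip flags

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("p_high_start", "p_high_after_escalation",
                    "utility_dfs", "utility_rd"):
            if np.any((f[col] < 0) | (f[col] > 1)):
                raise ParameterValidationError(col, "draw outside [0, 1]")
        if np.any(f["hr_high_vs_low"] > 1.0):
            raise ParameterValidationError("hr_high_vs_low", "draw above 1.00")
        if np.any(f["utility_rd"] > f["utility_dfs"]):
            raise ParameterValidationError(
                "utility_rd", "draw above paired utility_dfs")
        cost_cols = [c for c in f.columns if c.startswith("cost_")]
        if np.any(f[cost_cols].to_numpy() < 0):
            raise ParameterValidationError("costs", "negative cost draw")

    def to_csv(self, path) -> None:
        self.frame.assign(trial=np.arange(self.n_trials)).to_csv(
            path, index=False)


def _pair_cholesky(d: ParameterDistribution, correlation) -> np.ndarray:
    q = d.params
    rho = q["correlation"] if correlation is None else correlation
    cov = np.array([
        [q["se_intercept"] ** 2, rho * q["se_intercept"] * q["se_log_scale"]],
        [rho * q["se_intercept"] * q["se_log_scale"], q["se_log_scale"] ** 2],
    ])
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DomainError(
            f"survival covariance for {d.target} is not positive "
            f"semi-definite") from exc


def sample_psa(
    dists: Sequence[ParameterDistribution],
    n: int,
    seed: int,
    survival_correlation: float | np.ndarray | None = None,
) -> PSADraws:
    """Draw ``n`` joint parameter sets (deterministic given ``seed``).

    Survival (intercept, log-scale) pairs are drawn jointly via the Cholesky
    factor of their covariance (standard errors backed out of the
    deterministic ranges; correlation defaults to 0, configurable through
    ``survival_correlation`` — a scalar applied to both pairs or a 2x2
    correlation matrix).  Hazard-ratio draws are truncated at 1.00 by
    clipping; the two exposure proportions share one uniform rank so that
    dose escalation can never lower the fraction of patients on target; the
    recurrent-disease utility is clipped to its paired disease-free utility.
    Clipping events are flagged per trial in the returned frame.
    """
    if n < 1:
        raise DomainError("n must be at least 1")
    if isinstance(survival_correlation, np.ndarray):
        if survival_correlation.shape != (2, 2):
            raise DomainError("correlation matrix must be 2x2")
        if not np.allclose(survival_correlation,
                           survival_correlation.T):
            raise DomainError("correlation matrix must be symmetric")
        corr = float(survival_correlation[0, 1])
    else:
        corr = survival_correlation

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    beta_cache: dict[str, ParameterDistribution] = {}

    for d in dists:
        if d.is_pair:
            chol = _pair_cholesky(d, corr)
            z = rng.standard_normal((n, 2))
            mean = np.array([d.params["mean_intercept"],
                             d.params["mean_log_scale"]])
            draws = mean + z @ chol.T
            cols[d.target[0]] = draws[:, 0]
            cols[d.target[1]] = draws[:, 1]
        elif d.family == "normal_on_log":
            log_draw = rng.normal(d.params["mean"], d.params["se"], n)
            hr = np.exp(log_draw)
            lo, hi = d.bounds
            clipped = np.zeros(n, dtype=bool)
            if hi is not None:
                clipped = hr > hi
                hr = np.minimum(hr, hi)
            if lo is not None:
                clipped |= hr < lo
                hr = np.maximum(hr, lo)
            cols[d.target] = hr
            cols[d.target + "_clipped"] = clipped
        elif d.family == "gamma":
            cols[d.target] = rng.gamma(d.params["shape"], d.params["scale"], n)
        elif d.family == "beta":
            beta_cache[d.target] = d
        # "fixed" rows contribute nothing

    # exposure proportions: one shared uniform through both inverse CDFs
    u = rng.random(n)
    for name in ("p_high_start", "p_high_after_escalation"):
        d = beta_cache.pop(name)
        cols[name] = stats.beta.ppf(u, d.params["alpha"], d.params["beta"])
    # utilities: independent draws, RD clipped to its paired DFS draw
    for name, d in beta_cache.items():
        cols[name] = rng.beta(d.params["alpha"], d.params["beta"], n)
    clipped_u = cols["utility_rd"] > cols["utility_dfs"]
    cols["utility_rd"] = np.minimum(cols["utility_rd"], cols["utility_dfs"])
    cols["utility_rd_clipped"] = clipped_u

    return PSADraws(n_trials=n, seed=seed, frame=pd.DataFrame(cols))


_DRAWN_FIELDS = (
    "dfs_low_intercept", "dfs_low_log_scale", "hr_high_vs_low",
    "bcmort_intercept", "bcmort_log_scale",
    "p_high_start", "p_high_after_escalation",
    "cost_dfs_annual", "cost_rd_annual", "cost_death_once", "cost_test",
    "utility_dfs", "utility_rd",
)


@dataclass(frozen=True)
class PSAResult:
    """Incremental cloud and summaries of a probabilistic analysis."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    draws: PSADraws
    wtp_grid: tuple[float, ...]
    ceac: pd.DataFrame          # wtp, probability_cost_effective
    nmb: pd.DataFrame           # wtp, mean, ci_low, ci_high

    @property
    def frac_hr_clipped(self) -> float:
        return float(self.draws.frame["hr_high_vs_low_clipped"].mean())

    @property
    def frac_utility_clipped(self) -> float:
        return float(self.draws.frame["utility_rd_clipped"].mean())

    @property
    def frac_no_benefit(self) -> float:
        return float((np.abs(self.delta_qalys) <= ZERO_QALY_TOL).mean())

    def ce_plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(self.delta_cost.size),
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
        })


def run_psa(
    p: ModelParameters,
    draws: PSADraws,
    lt: LifeTable,
    wtp_grid: Sequence[float] = (0.0, 20_000.0, 80_000.0),
    require_benefit: bool = True,
) -> PSAResult:
    """Evaluate both strategies on every drawn parameter set.

    CEAC(wtp) is the fraction of trials in which monitoring is
    cost-effective.  By default a trial counts only if it shows a QALY
    benefit *and* a positive net monetary benefit, so trials whose benefit
    was truncated away (hazard ratio at 1.00, equal state utilities) keep
    the curve from reaching 100% even though they may still save costs;
    ``require_benefit=False`` gives the literal NMB > 0 fraction.  NMB
    summaries give the mean and the 2.5/97.5 percentile interval.
    """
    if len(wtp_grid) == 0 or any(w < 0 for w in wtp_grid):
        raise DomainError("wtp_grid must be non-empty and non-negative")
    engine = TraceEngine(p, lt)
    f = draws.frame
    n = draws.n_trials
    dc = np.empty(n)
    de = np.empty(n)
    records = f[list(_DRAWN_FIELDS)].to_dict("records")
    for i, rec in enumerate(records):
        try:
            p_i = p.replace(**rec)
            dc[i], de[i] = _incremental_at(engine, p_i)
        except Exception as exc:
            raise RuntimeError(f"PSA trial {i} failed: {exc}") from exc

    wtps = np.asarray(list(wtp_grid), dtype=float)
    has_benefit = de > ZERO_QALY_TOL
    nmb_rows, ceac_rows = [], []
    for w in wtps:
        nmb = w * de - dc
        ce = (nmb > 0) & has_benefit if require_benefit else (nmb > 0)
        ceac_rows.append({"wtp": w,
                          "probability_cost_effective": float(ce.mean())})
        lo, hi = np.percentile(nmb, [2.5, 97.5])
        nmb_rows.append({"wtp": w, "mean": float(nmb.mean()),
                         "ci_low": float(lo), "ci_high": float(hi)})
    return PSAResult(
        delta_cost=dc, delta_qalys=de, draws=draws,
        wtp_grid=tuple(float(w) for w in wtps),
        ceac=pd.DataFrame(ceac_rows), nmb=pd.DataFrame(nmb_rows))
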