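"""Survival machinery: parametric curves, background mortality, KM utilities.

Disease events (recurrence, breast-cancer death) follow lognormal
accelerated-failure-time curves, S(t) = 1 - Phi((ln t - mu) / sigma),
parameterized by an intercept mu (log-years) and sigma = exp(log-scale) as
tabulated by survival-regression software.  Other-cause mortality comes from
an age-indexed period life table and is combined with the disease curve as
an independent additive hazard.  The module also reconstructs interval event
counts from published Kaplan-Meier summaries and fits/selects parametric
families on such data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, DataError, DomainError, FitError

__all__ = [
    "LognormalCurve",
    "SwitchCurve",
    "LifeTable",
    "KMDataset",
    "FitResult",
    "lognormal_survival",
    "apply_hazard_ratio",
    "background_survival",
    "overall_survival",
    "switched_survival",
    "reconstruct_event_counts",
    "fit_parametric",
    "select_best",
]


# ---------------------------------------------------------------------------
# parametric curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LognormalCurve:
    """Lognormal AFT survivor function with median exp(mu)."""

    mu: float      # intercept, log-years
    sigma: float   # exp(log-scale), > 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")

    @classmethod
    def from_intercept_log_scale(cls, intercept: float,
                                 log_scale: float) -> "LognormalCurve":
        return cls(mu=intercept, sigma=math.exp(log_scale))

    def survival(self, t):
        return lognormal_survival(self, t)

    @property
    def median(self) -> float:
        return math.exp(self.mu)


def lognormal_survival(curve: LognormalCurve, t):
    """S(t) = 1 - Phi((ln t - mu)/sigma); S(0) = 1.  Vectorized over ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("survival time must be non-negative")
    out = np.ones_like(t_arr)
    pos = t_arr > 0
    out[pos] = stats.norm.sf((np.log(t_arr[pos]) - curve.mu) / curve.sigma)
    return out if np.ndim(t) else float(out)


def apply_hazard_ratio(s_low, hr: float):
    """Proportional-hazards transform of a survivor value: ``s_low ** hr``.

    Multiplies the cumulative hazard by ``hr``; for hr < 1 the transformed
    survival dominates the baseline.
    """
    if hr <= 0:
        raise DomainError(f"hazard ratio must be positive, got {hr}")
    s_arr = np.asarray(s_low, dtype=float)
    if np.any((s_arr <= 0) & (s_arr != 0)) or np.any(s_arr > 1) or np.any(s_arr < 0):
        raise DomainError("survival values must lie in (0, 1]")
    out = s_arr ** hr
    return out if np.ndim(s_low) else float(out)


@dataclass(frozen=True)
class SwitchCurve:
    """Disease-free survival of a subcohort whose hazard drops at a switch.

    Before ``switch_time`` (years) the subcohort follows the low-exposure
    baseline; afterwards its hazard is multiplied by ``hr`` (conditional
    survival is grafted so the curve is continuous at the switch).
    ``switch_time = 0`` is "adequate from the start", ``inf`` is "low
    forever".
    """

    base: LognormalCurve
    hr: float = 1.0
    switch_time: float = math.inf

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise DomainError("hazard ratio must be positive")
        if self.switch_time < 0:
            raise DomainError("switch_time must be non-negative")

    def survival(self, t):
        return switched_survival(self, t)


def switched_survival(sc: SwitchCurve, t):
    """Piecewise survivor function, continuous at the switch time."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    s_low = lognormal_survival(sc.base, t_arr)
    if math.isinf(sc.switch_time) or sc.hr == 1.0:
        out = s_low
    else:
        s_high = s_low ** sc.hr
        if sc.switch_time == 0.0:
            out = s_high
        else:
            s_low_sw = lognormal_survival(sc.base, sc.switch_time)
            ratio = s_low_sw / s_low_sw ** sc.hr
            out = np.where(t_arr <= sc.switch_time, s_low, ratio * s_high)
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# background (other-cause) mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities q(x), ages contiguous."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.size == 0 or ages.size != qx.size:
            raise DataError("life table needs equal-length age and qx columns")
        if np.any(np.diff(ages) != 1):
            raise DataError("life-table ages must be contiguous integers")
        if np.any((qx < 0) | (qx >= 1)):
            raise DataError("all qx must lie in [0, 1)")
        # cumulative log-survival from the first tabulated age
        cum = np.concatenate([[0.0], np.cumsum(np.log1p(-qx))])
        object.__setattr__(self, "_cumlog", cum)

    # -- file I/O ---------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if list(df.columns) != ["age", "qx"]:
            raise DataError('life-table CSV must have header "age,qx"')
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    # -- survival ---------------------------------------------------------
    def _logsurv_at_age(self, age):
        """Cumulative log survival from the first tabulated age to ``age``
        (fractional ages use a constant hazard within the year)."""
        a = np.asarray(age, dtype=float)
        lo, hi = self.ages[0], self.ages[-1] + 1
        if np.any(a < lo) or np.any(a > hi):
            raise CoverageError(
                f"age range [{a.min():.2f}, {a.max():.2f}] outside life table "
                f"[{lo}, {hi}]")
        whole = np.minimum(np.floor(a).astype(int), self.ages[-1])
        frac = a - whole
        idx = whole - lo
        return self._cumlog[idx] + frac * np.log1p(-self.qx[idx])


def background_survival(lt: LifeTable, start_age: float, t):
    """Probability of surviving other-cause mortality from ``start_age`` over
    ``t`` years, with a constant hazard within each year of age."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be non-negative")
    ls = lt._logsurv_at_age(start_age + t_arr) - lt._logsurv_at_age(start_age)
    out = np.exp(ls)
    return out if np.ndim(t) else float(out)


def overall_survival(bc_curve: LognormalCurve, lt: LifeTable,
                     start_age: float, t):
    """OS(t) = S_bc(t) * S_bg(t): independent additive hazards of
    breast-cancer death and background (other-cause) death."""
    return lognormal_survival(bc_curve, t) * background_survival(lt, start_age, t)


# ---------------------------------------------------------------------------
# Kaplan-Meier reconstruction and parametric fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMDataset:
    """Published Kaplan-Meier summary: boundaries, survival, numbers at risk."""

    times: np.ndarray      # interval boundaries, years, increasing from 0
    survival: np.ndarray   # S at each boundary, starts at 1, non-increasing
    n_risk: np.ndarray     # at risk at each boundary, non-increasing

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        nr = np.asarray(self.n_risk, dtype=float)
        for name, arr in (("times", times), ("survival", surv), ("n_risk", nr)):
            object.__setattr__(self, name, arr)
        if not (times.size == surv.size == nr.size):
            raise DataError("KM columns must have equal length")
        if times.size < 2:
            raise DataError("KM dataset needs at least two boundaries")
        if np.any(np.diff(times) <= 0):
            raise DataError("KM times must be strictly increasing")
        if surv[0] != 1.0 or np.any(np.diff(surv) > 0):
            raise DataError("survival must start at 1 and be non-increasing")
        if np.any((surv < 0) | (surv > 1)):
            raise DataError("survival must lie in [0, 1]")
        if nr[0] <= 0 or np.any(np.diff(nr) > 0) or np.any(nr < 0):
            raise DataError("numbers at risk must be positive at t=0 and "
                            "non-increasing")

    @classmethod
    def from_csv(cls, path) -> "KMDataset":
        df = pd.read_csv(path)
        if list(df.columns) != ["time_years", "survival", "n_risk"]:
            raise DataError(
                'KM CSV must have header "time_years,survival,n_risk"')
        return cls(times=df["time_years"].to_numpy(),
                   survival=df["survival"].to_numpy(),
                   n_risk=df["n_risk"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_years": self.times, "survival": self.survival,
                      "n_risk": self.n_risk}).to_csv(path, index=False)


def _largest_remainder_round(values: np.ndarray) -> np.ndarray:
    """Round non-negative floats to integers preserving the rounded total."""
    total = int(round(values.sum()))
    floors = np.floor(values).astype(int)
    deficit = total - floors.sum()
    if deficit > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:deficit]] += 1
    return floors


def reconstruct_event_counts(km: KMDataset) -> pd.DataFrame:
    """Recover integer event/censoring counts per interval from a published
    Kaplan-Meier curve and its at-risk table.

    Within interval i, events ~ n_i * (1 - S_{i+1}/S_i) (deterministically
    rounded by largest remainder); censorings absorb the remaining decline in
    the at-risk count.  Implied negative counts raise :class:`DataError`.
    """
    s0, s1 = km.survival[:-1], km.survival[1:]
    n0, n1 = km.n_risk[:-1], km.n_risk[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        drop = np.where(s0 > 0, 1.0 - s1 / s0, 0.0)
    events_f = n0 * drop
    events = _largest_remainder_round(events_f)
    censored = np.round(n0 - n1).astype(int) - events
    if np.any(events < 0) or np.any(censored < 0):
        raise DataError("at-risk and survival columns imply negative counts")
    return pd.DataFrame({
        "interval_start": km.times[:-1],
        "interval_end": km.times[1:],
        "n_risk": n0.astype(int),
        "events": events,
        "censored": censored,
    })


def km_from_counts(counts: pd.DataFrame) -> np.ndarray:
    """Kaplan-Meier survival at interval boundaries recomputed from counts
    (round-trip check for :func:`reconstruct_event_counts`)."""
    factors = 1.0 - counts["events"].to_numpy() / counts["n_risk"].to_numpy()
    return np.concatenate([[1.0], np.cumprod(factors)])


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one parametric family."""

    family: str
    params: dict
    param_names: tuple
    log_likelihood: float
    aic: float
    bic: float
    param_covariance: np.ndarray
    n: int

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return math.sqrt(self.param_covariance[i, i])


_FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")


def _lifelines_fitter(family: str):
    import lifelines

    return {
        "exponential": lifelines.ExponentialFitter,
        "weibull": lifelines.WeibullFitter,
        "lognormal": lifelines.LogNormalFitter,
        "loglogistic": lifelines.LogLogisticFitter,
    }[family]()


def _natural_params(family: str, fitter) -> dict:
    if family == "exponential":
        return {"rate": 1.0 / fitter.lambda_, "mean": fitter.lambda_}
    if family == "weibull":
        return {"scale": fitter.lambda_, "shape": fitter.rho_}
    if family == "lognormal":
        return {"mu": fitter.mu_, "sigma": fitter.sigma_,
                "intercept": fitter.mu_, "log_scale": math.log(fitter.sigma_)}
    return {"alpha": fitter.alpha_, "beta": fitter.beta_}


def fit_parametric(data, family: str) -> FitResult:
    """Fit one parametric family by maximum likelihood.

    ``data`` is either a 1-D array of exact event times (all observed) or a
    DataFrame of interval counts as produced by
    :func:`reconstruct_event_counts` (interval-censored likelihood for the
    events, right-censoring at the interval start for drop-outs).
    """
    if family not in _FAMILIES:
        raise DomainError(f"unknown family {family!r}; choose from {_FAMILIES}")
    from lifelines.exceptions import ConvergenceError

    fitter = _lifelines_fitter(family)
    try:
        if isinstance(data, pd.DataFrame):
            lower, upper = _intervals_from_counts(data)
            if lower.size == 0:
                raise FitError("no events in interval data")
            fitter.fit_interval_censoring(lower, upper)
            n = lower.size
        else:
            times = np.asarray(data, dtype=float)
            if times.size == 0:
                raise FitError("no events to fit")
            if np.any(times <= 0):
                raise DomainError("event times must be positive")
            fitter.fit(times, event_observed=np.ones_like(times))
            n = times.size
    except ConvergenceError as exc:
        raise FitError(f"{family} fit did not converge: {exc}") from exc

    ll = float(fitter.log_likelihood_) * n if _ll_is_mean(fitter, n) \
        else float(fitter.log_likelihood_)
    k = len(fitter._fitted_parameter_names)
    cov = np.asarray(fitter.variance_matrix_)
    return FitResult(
        family=family,
        params=_natural_params(family, fitter),
        param_names=tuple(fitter._fitted_parameter_names),
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n) - 2 * ll,
        param_covariance=cov,
        n=n,
    )


def _ll_is_mean(fitter, n: int) -> bool:
    # lifelines univariate fitters report the *total* log-likelihood; guard in
    # case a future version switches to the per-observation mean.
    try:
        return abs(fitter.AIC_ - (2 * len(fitter._fitted_parameter_names)
                                  - 2 * fitter.log_likelihood_)) > 1e-6
    except AttributeError:
        return False


def _intervals_from_counts(counts: pd.DataFrame):
    """Expand interval counts to per-subject (lower, upper] bounds.

    Events get their interval; censored subjects are right-censored at the
    interval start (upper bound = inf).
    """
    lowers, uppers = [], []
    for row in counts.itertuples():
        if row.events:
            lowers.append(np.full(int(row.events),
                                  max(row.interval_start, 1e-9)))
            uppers.append(np.full(int(row.events), row.interval_end))
        if row.censored:
            lowers.append(np.full(int(row.censored),
                                  max(row.interval_start, 1e-9)))
            uppers.append(np.full(int(row.censored), np.inf))
    if not lowers:
        return np.array([]), np.array([])
    return np.concatenate(lowers), np.concatenate(uppers)


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Minimum AIC; ties broken by BIC, then by fewer parameters."""
    if not fits:
        raise ValueError("select_best requires at least one fit")
    return min(fits, key=lambda f: (f.aic, f.bic, len(f.param_names)))
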