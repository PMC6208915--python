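"""Partitioned-survival cohort traces and economic outcomes.

The three-state model (disease-free survival DFS, recurrent disease RD,
death) is evaluated by reading state occupancy directly from survival
curves on a 28-day cycle grid: overall survival OS is the breast-cancer
mortality curve multiplied by background survival, each subcohort's DFS
occupancy is its (possibly switched) disease-free-survival curve capped at
OS, and RD = OS - DFS.  Costs and QALYs accrue with a half-cycle
(trapezoidal) correction and are discounted at the cycle midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoverageError, ParameterValidationError
from .parameters import ModelParameters
from .survival import (
    LifeTable,
    LognormalCurve,
    SwitchCurve,
    background_survival,
    lognormal_survival,
)

__all__ = [
    "Strategy",
    "TestPoint",
    "CohortTrace",
    "EconomicSummary",
    "IncrementalSummary",
    "TraceEngine",
    "build_strategies",
    "run_trace",
    "summarize",
    "compare",
    "net_monetary_benefit",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TestPoint:
    """One scheduled serum test: when, and which share of the cohort.

    ``subcohorts`` lists the indices of the strategy subcohorts the test
    applies to (used by the patient-level simulator); the fraction must then
    equal the summed weight of those subcohorts.
    """

    time_days: float
    fraction: float
    subcohorts: tuple[int, ...] | None = None


@dataclass(frozen=True)
class Strategy:
    """A monitoring policy: a mixture of DFS subcohorts plus a test schedule."""

    name: str
    tdm_enabled: bool
    subcohorts: tuple[tuple[float, SwitchCurve], ...]
    tests: tuple[TestPoint, ...] = ()

    def __post_init__(self) -> None:
        weights = [w for w, _ in self.subcohorts]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ParameterValidationError(
                "subcohorts", f"weights sum to {sum(weights)}, expected 1")
        if any(w < 0 for w in weights):
            raise ParameterValidationError("subcohorts",
                                           "weights must be non-negative")
        for tp in self.tests:
            if not 0.0 <= tp.fraction <= 1.0:
                raise ParameterValidationError(
                    "tests", f"tested fraction {tp.fraction} outside [0, 1]")
            if tp.subcohorts is not None:
                wsum = sum(self.subcohorts[i][0] for i in tp.subcohorts)
                if abs(wsum - tp.fraction) > 1e-9:
                    raise ParameterValidationError(
                        "tests", "fraction does not match subcohort weights")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.subcohorts])


def build_strategies(p: ModelParameters) -> tuple[Strategy, Strategy]:
    """Construct the comparator (no monitoring) and intervention strategies.

    ``p_high_start`` of the cohort has adequate endoxifen from the start;
    under monitoring, the fraction on target rises to
    ``p_high_after_escalation`` once dose escalation has been confirmed, so
    the escalated-and-converted mass is the *difference* of the two
    proportions (escalation cannot lower the fraction on target, so the mass
    is floored at zero).  All monitored patients are tested once; the low
    fraction is retested after escalation.
    """
    low_curve = LognormalCurve.from_intercept_log_scale(
        p.dfs_low_intercept, p.dfs_low_log_scale)
    hr = p.hr_high_vs_low
    switch_day = (p.first_test_time if p.benefit_from_first_test
                  else p.second_test_time)
    t_switch = switch_day / DAYS_PER_YEAR

    high_from_start = SwitchCurve(low_curve, hr=hr, switch_time=0.0)
    low_forever = SwitchCurve(low_curve, hr=hr, switch_time=math.inf)
    converts = SwitchCurve(low_curve, hr=hr, switch_time=t_switch)

    p_start = p.p_high_start
    p_low = 1.0 - p_start
    converted = min(max(p.p_high_after_escalation - p_start, 0.0), p_low)

    no_tdm = Strategy(
        name="no_tdm", tdm_enabled=False,
        subcohorts=((p_start, high_from_start), (p_low, low_forever)))
    tdm = Strategy(
        name="tdm", tdm_enabled=True,
        subcohorts=((p_start, high_from_start),
                    (converted, converts),
                    (p_low - converted, low_forever)),
        tests=(TestPoint(p.first_test_time, 1.0, (0, 1, 2)),
               TestPoint(p.second_test_time, p_low, (1, 2))))
    return no_tdm, tdm


# ---------------------------------------------------------------------------
# trace engine
# ---------------------------------------------------------------------------

class TraceEngine:
    """Precomputes the cycle grid, discount factors and background survival
    for one (structural parameters, life table) pair so that many parameter
    draws can be traced cheaply (deterministic and probabilistic sensitivity
    analysis re-evaluate the model thousands of times)."""

    def __init__(self, p: ModelParameters, lt: LifeTable):
        self.base_params = p
        self.life_table = lt
        self.n_cycles = int(math.floor(
            (p.horizon_age - p.start_age) * DAYS_PER_YEAR / p.cycle_length))
        cyc_years = p.cycle_length / DAYS_PER_YEAR
        self.boundaries = np.arange(self.n_cycles + 1) * cyc_years
        self.boundaries_days = self.boundaries * DAYS_PER_YEAR
        self.midpoints = 0.5 * (self.boundaries[:-1] + self.boundaries[1:])
        self.cycle_years = cyc_years
        try:
            self.bg = background_survival(lt, p.start_age, self.boundaries)
        except CoverageError as exc:
            raise CoverageError(
                f"life table must cover ages {p.start_age} to "
                f"{p.horizon_age}: {exc}") from exc
        self.disc_costs = (1.0 + p.discount_rate_costs) ** (-self.midpoints)
        self.disc_effects = (1.0 + p.discount_rate_effects) ** (-self.midpoints)

    def test_cycle(self, time_days: float) -> int:
        """Cycle whose start boundary is nearest to a scheduled test day."""
        i = int(math.floor(time_days / self.base_params.cycle_length + 0.5))
        if i >= self.n_cycles:
            raise ConfigurationError(
                f"test scheduled at day {time_days} falls outside the "
                f"{self.n_cycles}-cycle horizon")
        return i

    def occupancy(self, p: ModelParameters, s: Strategy):
        """Boundary occupancy (dfs, rd, dead, os) for one drawn parameter set."""
        bc_curve = LognormalCurve.from_intercept_log_scale(
            p.bcmort_intercept, p.bcmort_log_scale)
        s_bc = lognormal_survival(bc_curve, self.boundaries)
        os_ = s_bc * self.bg
        dfs = np.zeros_like(self.boundaries)
        for w, curve in s.subcohorts:
            if w == 0.0:
                continue
            s_dfs = curve.survival(self.boundaries)
            if p.background_mortality_on_dfs:
                dfs += w * np.minimum(s_dfs, s_bc) * self.bg
            else:
                dfs += w * np.minimum(s_dfs, os_)
        dfs = np.minimum(dfs, os_)
        rd = os_ - dfs
        return dfs, rd, 1.0 - os_, os_

    def trace(self, p: ModelParameters, s: Strategy) -> "CohortTrace":
        dfs, rd, dead, os_ = self.occupancy(p, s)
        dfs_avg = 0.5 * (dfs[:-1] + dfs[1:])
        rd_avg = 0.5 * (rd[:-1] + rd[1:])
        new_deaths = os_[:-1] - os_[1:]

        dy = self.cycle_years
        qalys = (p.utility_dfs * dfs_avg + p.utility_rd * rd_avg) * dy
        cost_state = (p.cost_dfs_annual * dfs_avg
                      + p.cost_rd_annual * rd_avg) * dy
        cost_death = p.cost_death_once * new_deaths
        cost_test = np.zeros(self.n_cycles)
        for tp in s.tests:
            if tp.fraction == 0.0:
                continue
            i = self.test_cycle(tp.time_days)
            cost_test[i] += tp.fraction * p.cost_test * os_[i]

        costs = cost_state + cost_death + cost_test
        return CohortTrace(
            strategy=s.name,
            start_times_days=self.boundaries_days[:-1],
            dfs=dfs, rd=rd, dead=dead,
            new_deaths=new_deaths,
            cost_state=cost_state, cost_test=cost_test,
            cost_death=cost_death,
            qalys=qalys,
            disc_costs=costs * self.disc_costs,
            disc_qalys=qalys * self.disc_effects,
        )

    def incremental(self, p: ModelParameters,
                    intervention: Strategy, comparator: Strategy,
                    ) -> tuple[float, float]:
        """(delta_cost, delta_qalys), intervention minus comparator."""
        a = self.trace(p, intervention)
        b = self.trace(p, comparator)
        return (a.total_disc_cost - b.total_disc_cost,
                a.total_disc_qalys - b.total_disc_qalys)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy, accruals and discounted accruals for a strategy.

    Occupancy arrays hold boundary values (length n_cycles + 1); accrual
    arrays are per cycle (length n_cycles).
    """

    strategy: str
    start_times_days: np.ndarray
    dfs: np.ndarray
    rd: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray
    cost_state: np.ndarray
    cost_test: np.ndarray
    cost_death: np.ndarray
    qalys: np.ndarray
    disc_costs: np.ndarray
    disc_qalys: np.ndarray

    def __post_init__(self) -> None:
        occ = self.dfs + self.rd + self.dead
        assert np.all(np.abs(occ - 1.0) < 1e-9), "occupancy must sum to 1"
        assert np.all(np.diff(self.dead) >= -1e-12), "death must not decrease"

    @property
    def n_cycles(self) -> int:
        return self.start_times_days.size

    @property
    def total_cost(self) -> float:
        return float((self.cost_state + self.cost_test + self.cost_death).sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qalys.sum())

    @property
    def total_disc_cost(self) -> float:
        return float(self.disc_costs.sum())

    @property
    def total_disc_qalys(self) -> float:
        return float(self.disc_qalys.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        return pd.DataFrame({
            "time_days": self.start_times_days,
            "dfs": self.dfs[:n],
            "rd": self.rd[:n],
            "dead": self.dead[:n],
            "cost_state": self.cost_state,
            "cost_test": self.cost_test,
            "cost_death": self.cost_death,
            "qaly": self.qalys,
            "disc_cost": self.disc_costs,
            "disc_qaly": self.disc_qalys,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_trace(p: ModelParameters, s: Strategy, lt: LifeTable) -> CohortTrace:
    """Trace one strategy over the lifetime horizon (convenience wrapper
    around :class:`TraceEngine` for single evaluations)."""
    return TraceEngine(p, lt).trace(p, s)


# ---------------------------------------------------------------------------
# economic summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EconomicSummary:
    """Discounted and undiscounted totals of one strategy."""

    strategy: str
    total_cost: float
    total_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float


@dataclass(frozen=True)
class IncrementalSummary:
    """Incremental economics of intervention vs comparator at a given WTP."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    icer_label: str
    wtp: float
    nmb: float


def summarize(trace: CohortTrace) -> EconomicSummary:
    return EconomicSummary(
        strategy=trace.strategy,
        total_cost=trace.total_disc_cost,
        total_qalys=trace.total_disc_qalys,
        undiscounted_cost=trace.total_cost,
        undiscounted_qalys=trace.total_qalys,
    )


def net_monetary_benefit(delta_cost: float, delta_qalys: float,
                         wtp: float) -> float:
    """NMB = WTP * dQALY - dCost; positive means cost-effective at that WTP."""
    return wtp * delta_qalys - delta_cost


def compare(intervention: EconomicSummary, comparator: EconomicSummary,
            wtp: float = 20_000.0) -> IncrementalSummary:
    """Incremental cost, effect, ICER and net monetary benefit.

    A zero QALY difference leaves the ICER undefined (NMB remains valid);
    otherwise the ICER is labelled by its cost-effectiveness-plane quadrant
    ("dominant" = cheaper and more effective, "dominated" = the reverse).
    """
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qalys - comparator.total_qalys
    if de == 0.0:
        icer, label = None, "undefined"
    else:
        icer = dc / de
        if de > 0:
            label = "dominant" if dc < 0 else "icer"
        else:
            label = "dominated" if dc > 0 else "icer"
    return IncrementalSummary(
        delta_cost=dc, delta_qalys=de, icer=icer, icer_label=label,
        wtp=wtp, nmb=net_monetary_benefit(dc, de, wtp))
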