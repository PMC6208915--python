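"""Model inputs for the endoxifen monitoring cost-effectiveness model.

All point estimates, deterministic sensitivity ranges and sampling
distributions live here.  The base-case values describe a Dutch cohort of
women with ERα-positive breast cancer starting adjuvant tamoxifen at age 53:
lognormal disease-free-survival and breast-cancer-mortality curves, the
hazard ratio of recurrence for adequate ("high", ≥ 5.97 ng/mL) versus
inadequate ("low") serum endoxifen, the fractions of patients on target
before and after a tamoxifen dose escalation, Dutch state costs and
utilities, and the discount rates recommended by the Dutch National Health
Care Institute (4% for costs, 1.5% for effects).
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

from .errors import (
    ConfigurationError,
    ParameterValidationError,
    UnsupportedFamilyError,
)

__all__ = [
    "ModelParameters",
    "ParameterDistribution",
    "load_parameters",
    "table1_distributions",
    "distribution_mean",
    "iter_scalar_ranges",
    "parameters_to_yaml",
]


@dataclass(frozen=True)
class ModelParameters:
    """Point estimates and structural settings of the cohort model.

    Units: ages and the survival intercepts are in years (intercepts on the
    log-year scale), cycle length and test times in days, costs in euros,
    discount rates as annual fractions, the endoxifen threshold in ng/mL.
    """

    # cohort structure
    start_age: float = 53.0
    cycle_length: float = 28.0
    horizon_age: float = 100.0
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    # disease-free survival, patients with low endoxifen (lognormal AFT)
    dfs_low_intercept: float = 3.28
    dfs_low_log_scale: float = 0.61
    hr_high_vs_low: float = 0.74
    # breast-cancer mortality (lognormal AFT)
    bcmort_intercept: float = 3.71
    bcmort_log_scale: float = 0.40
    # endoxifen exposure fractions: on target at first test / after escalation
    p_high_start: float = 0.76
    p_high_after_escalation: float = 0.94
    # annual state costs, one-off costs [EUR]
    cost_dfs_annual: float = 2872.0
    cost_rd_annual: float = 16125.0
    cost_death_once: float = 8296.0
    cost_test: float = 113.0
    # utilities [per year in state]
    utility_dfs: float = 0.80
    utility_rd: float = 0.73
    # monitoring schedule and threshold
    first_test_time: float = 91.0
    second_test_time: float = 182.0
    endoxifen_threshold: float = 5.97
    # structural conventions (see docs/methods.md)
    background_mortality_on_dfs: bool = False
    benefit_from_first_test: bool = False

    def __post_init__(self) -> None:
        def err(name: str, msg: str) -> None:
            raise ParameterValidationError(name, msg)

        for name in ("p_high_start", "p_high_after_escalation",
                     "utility_dfs", "utility_rd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                err(name, f"must lie in [0, 1], got {v}")
        for name in ("cost_dfs_annual", "cost_rd_annual",
                     "cost_death_once", "cost_test"):
            v = getattr(self, name)
            if v < 0:
                err(name, f"costs must be non-negative, got {v}")
        if self.cycle_length <= 0:
            err("cycle_length", f"must be positive, got {self.cycle_length}")
        if self.horizon_age <= self.start_age:
            err("horizon_age",
                f"must exceed start_age {self.start_age}, got {self.horizon_age}")
        if self.utility_rd > self.utility_dfs:
            err("utility_rd",
                f"must not exceed utility_dfs ({self.utility_dfs}), "
                f"got {self.utility_rd}")
        if self.hr_high_vs_low <= 0:
            err("hr_high_vs_low",
                f"hazard ratio must be positive, got {self.hr_high_vs_low}")
        for name in ("discount_rate_costs", "discount_rate_effects"):
            if getattr(self, name) < 0:
                err(name, "discount rates must be non-negative")
        for name in ("first_test_time", "second_test_time"):
            if getattr(self, name) < 0:
                err(name, "test times must be non-negative")
        if self.second_test_time < self.first_test_time:
            err("second_test_time", "retest cannot precede the first test")
        if self.endoxifen_threshold <= 0:
            err("endoxifen_threshold", "threshold must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


def parameters_to_yaml(p: ModelParameters) -> str:
    """Serialize parameters to a flat YAML document (round-trips exactly)."""
    return yaml.safe_dump(p.to_dict(), sort_keys=True)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParameters)}


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution and deterministic range for one Table-1 row.

    ``family`` is one of ``fixed``, ``beta``, ``gamma``, ``normal_on_log``
    and ``correlated_lognormal_pair``.  For the survival pairs ``target``,
    ``base``, ``low`` and ``high`` are 2-tuples covering (intercept,
    log-scale); for every other family they are scalars.  ``low``/``high``
    are the endpoints used in one-way deterministic sensitivity analysis,
    ``bounds`` an optional truncation interval applied when sampling.
    """

    target: str | tuple[str, str]
    family: str
    params: Mapping[str, float]
    base: float | tuple[float, float]
    low: float | tuple[float, float]
    high: float | tuple[float, float]
    bounds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        positive = {
            "beta": ("alpha", "beta"),
            "gamma": ("shape", "scale"),
            "normal_on_log": ("se",),
            "correlated_lognormal_pair": ("se_intercept", "se_log_scale"),
            "fixed": (),
        }
        if self.family not in positive:
            raise ParameterValidationError(str(self.target),
                                           f"unknown family {self.family!r}")
        for key in positive[self.family]:
            if self.params.get(key, 1.0) <= 0:
                raise ParameterValidationError(
                    str(self.target), f"{key} must be positive")
        for b, lo, hi in zip(self._tup(self.base), self._tup(self.low),
                             self._tup(self.high)):
            if not lo <= b <= hi:
                raise ParameterValidationError(
                    str(self.target),
                    f"range [{lo}, {hi}] does not bracket base {b}")

    @staticmethod
    def _tup(v) -> tuple:
        return v if isinstance(v, tuple) else (v,)

    @property
    def is_pair(self) -> bool:
        return self.family == "correlated_lognormal_pair"


def distribution_mean(dist: ParameterDistribution) -> float:
    """Analytic central value implied by a distribution's parameters.

    Beta: alpha/(alpha+beta).  Gamma: shape*scale.  ``normal_on_log``:
    exp(mean), the median of the induced lognormal (the scale on which the
    hazard ratio is tabulated).
    """
    fam, q = dist.family, dist.params
    if fam == "beta":
        return q["alpha"] / (q["alpha"] + q["beta"])
    if fam == "gamma":
        return q["shape"] * q["scale"]
    if fam == "normal_on_log":
        return math.exp(q["mean"])
    raise UnsupportedFamilyError(
        f"no analytic mean for family {fam!r} of {dist.target!r}")


def _range_se(low: float, high: float) -> float:
    # deterministic range read as a 95% interval: SE = (high - low) / 3.92
    return (high - low) / 3.92


def table1_distributions() -> list[ParameterDistribution]:
    """The eleven non-fixed input rows: two correlated survival pairs, the
    hazard ratio, two exposure proportions, four costs and two utilities."""
    rows = [
        ParameterDistribution(
            target=("dfs_low_intercept", "dfs_low_log_scale"),
            family="correlated_lognormal_pair",
            params={"mean_intercept": 3.28, "mean_log_scale": 0.61,
                    "se_intercept": _range_se(3.20, 3.37),
                    "se_log_scale": _range_se(0.57, 0.64),
                    "correlation": 0.0},
            base=(3.28, 0.61), low=(3.20, 0.57), high=(3.37, 0.64)),
        ParameterDistribution(
            target="hr_high_vs_low", family="normal_on_log",
            params={"mean": -0.301, "se": 0.153},
            base=0.74, low=0.55, high=1.00, bounds=(None, 1.00)),
        ParameterDistribution(
            target=("bcmort_intercept", "bcmort_log_scale"),
            family="correlated_lognormal_pair",
            params={"mean_intercept": 3.71, "mean_log_scale": 0.40,
                    "se_intercept": _range_se(3.66, 3.76),
                    "se_log_scale": _range_se(0.37, 0.42),
                    "correlation": 0.0},
            base=(3.71, 0.40), low=(3.66, 0.37), high=(3.76, 0.42)),
        ParameterDistribution(
            target="p_high_start", family="beta",
            params={"alpha": 14.8, "beta": 4.7},
            base=0.76, low=0.57, high=0.94),
        ParameterDistribution(
            target="p_high_after_escalation", family="beta",
            params={"alpha": 13.2, "beta": 0.8},
            base=0.94, low=0.76, high=1.00),
        ParameterDistribution(
            target="cost_dfs_annual", family="gamma",
            params={"shape": 26.0, "scale": 110.4},
            base=2872.0, low=1769.0, high=3975.0),
        ParameterDistribution(
            target="cost_rd_annual", family="gamma",
            params={"shape": 26.5, "scale": 609.5},
            base=16125.0, low=9980.0, high=22270.0),
        ParameterDistribution(
            target="cost_death_once", family="gamma",
            params={"shape": 61.5, "scale": 135.0},
            base=8296.0, low=6222.0, high=10370.0),
        ParameterDistribution(
            target="cost_test", family="gamma",
            params={"shape": 61.5, "scale": 1.8},
            base=113.0, low=85.0, high=141.0),
        ParameterDistribution(
            target="utility_dfs", family="beta",
            params={"alpha": 99.55, "beta": 24.89},
            base=0.80, low=0.73, high=0.87),
        ParameterDistribution(
            target="utility_rd", family="beta",
            params={"alpha": 112.07, "beta": 41.45},
            base=0.73, low=0.66, high=0.80),
    ]
    return rows


def iter_scalar_ranges(
    dists: Sequence[ParameterDistribution],
) -> Iterator[tuple[str, float, float, float]]:
    """Yield ``(name, base, low, high)`` for every scalar input, flattening
    the correlated survival pairs into their two components."""
    for d in dists:
        if d.is_pair:
            for i, name in enumerate(d.target):
                yield name, d.base[i], d.low[i], d.high[i]
        else:
            yield d.target, d.base, d.low, d.high


def load_parameters(
    config_source: str | os.PathLike | Mapping | None = None,
) -> tuple[ModelParameters, list[ParameterDistribution]]:
    """Load model parameters, applying overrides from a flat config document.

    ``config_source`` may be ``None``/empty (all defaults), a mapping, a path
    to a YAML/JSON file, or YAML/JSON text.  Keys must be ``ModelParameters``
    field names; unknown keys raise :class:`ConfigurationError`, values that
    violate an invariant raise :class:`ParameterValidationError` naming the
    field.
    """
    data: Mapping = {}
    if config_source is None or config_source == "":
        data = {}
    elif isinstance(config_source, Mapping):
        data = config_source
    else:
        text = None
        if isinstance(config_source, os.PathLike):
            text = Path(config_source).read_text()
        elif isinstance(config_source, str):
            maybe = Path(config_source)
            try:
                is_file = maybe.is_file()
            except OSError:  # e.g. name too long to be a path
                is_file = False
            text = maybe.read_text() if is_file else config_source
        try:
            parsed = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config: {exc}") from exc
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, Mapping):
            raise ConfigurationError(
                "config must be a flat key-value document")
        data = parsed

    unknown = sorted(set(data) - _FIELD_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
    params = ModelParameters(**data)
    return params, table1_distributions()
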