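"""Discounted scenario outcomes and incremental cost-effectiveness.

Costs and effects are discounted at an annual rate (3% by default) under
the cycle-start convention: cycle t carries the factor (1+r)^-t, cycle 0
the factor 1.  Effectiveness is measured as disability-adjusted life
years within the simulated horizon: the mortality component is the
difference in discounted person-years alive (weight 1), the morbidity
component the disability-weighted discounted impaired person-years
(years lived with disability, YLD).  No age weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .cohort import CohortTrace
from .costs import CostBreakdown
from .parameters import ParameterSet

__all__ = [
    "discount_factor",
    "discount_factors",
    "ScenarioOutcome",
    "IncrementalOutcome",
    "Dominance",
    "WHOClass",
    "scenario_outcome",
    "incremental",
    "who_classification",
]


def discount_factor(cycle: int, rate: float) -> float:
    """(1 + rate)^-cycle; cycle 0 -> 1 exactly, rate 0 -> 1 for all cycles."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return float((1.0 + rate) ** (-cycle))


def discount_factors(horizon: int, rate: float) -> np.ndarray:
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-np.arange(horizon, dtype=float))


@dataclass
class ScenarioOutcome:
    """Discounted totals for one scenario arm (whole cohort)."""

    scenario: str
    horizon: int
    discounted_cost: float | np.ndarray
    discounted_life_years: float | np.ndarray
    discounted_yld: float | np.ndarray

    def to_row(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "scenario": self.scenario,
            "horizon": self.horizon,
            "discounted_cost": np.asarray(self.discounted_cost).mean(),
            "discounted_life_years": np.asarray(self.discounted_life_years).mean(),
            "discounted_yld": np.asarray(self.discounted_yld).mean(),
        }])


class Dominance(Enum):
    DOMINANT = "dominant"        # cheaper and more effective: ICER "<0"
    DOMINATED = "dominated"      # dearer and less effective
    ICER = "icer"                # finite ratio reported
    UNDEFINED = "undefined"      # zero effect difference: no division


class WHOClass(Enum):
    DOMINANT = "dominant"
    HIGHLY_COST_EFFECTIVE = "highly_cost_effective"
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"


@dataclass
class IncrementalOutcome:
    """Screening-minus-no-screening differences per cohort."""

    horizon: int
    delta_cost: float
    life_years_gained: float
    dalys_averted: float
    flag: Dominance
    icer: float | None = None

    def to_row(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "horizon": self.horizon,
            "delta_cost": self.delta_cost,
            "life_years_gained": self.life_years_gained,
            "dalys_averted": self.dalys_averted,
            "icer": "<0" if self.flag is Dominance.DOMINANT else self.icer,
            "flag": self.flag.value,
        }])


def scenario_outcome(trace: CohortTrace, costs: CostBreakdown,
                     params: ParameterSet, rate: float | None = None,
                     discount_life_years: bool = True) -> ScenarioOutcome:
    """Discount a trace + cost breakdown into scenario totals.

    ``discount_life_years=False`` reports undiscounted person-years (a
    sensitivity toggle); cost and YLD are always discounted.
    """
    horizon = trace.horizon
    r = params.discount_rate if rate is None else rate
    d = discount_factors(horizon, r)
    size = trace.cohort_size
    alive = trace.alive[..., :horizon]
    impaired = trace.impaired[..., :horizon]
    dw = np.asarray(params.disability_weight_smd)
    dw = dw[..., None] if dw.ndim > 0 else dw

    cost = (costs.total * d).sum(axis=-1)
    ly = (alive * (d if discount_life_years else 1.0)).sum(axis=-1) * size
    yld = (impaired * dw * d).sum(axis=-1) * size
    return ScenarioOutcome(scenario=trace.scenario.value, horizon=horizon,
                           discounted_cost=cost, discounted_life_years=ly,
                           discounted_yld=yld)


def incremental(out_screen: ScenarioOutcome,
                out_noscreen: ScenarioOutcome) -> IncrementalOutcome:
    """Incremental result of screening vs no screening (scalar outcomes).

    DALYs averted combine the life-year gain (mortality component) with
    the YLD reduction (morbidity component).  A finite ICER is reported
    only when screening costs more and averts DALYs; a cheaper, more
    effective screening arm is flagged dominant.
    """
    if out_screen.horizon != out_noscreen.horizon:
        raise ValueError("incremental comparison requires a common horizon")
    dc = float(out_screen.discounted_cost - out_noscreen.discounted_cost)
    lyg = float(out_screen.discounted_life_years - out_noscreen.discounted_life_years)
    averted = lyg + float(out_noscreen.discounted_yld - out_screen.discounted_yld)

    if averted == 0.0:
        flag, icer = Dominance.UNDEFINED, None
    elif dc < 0 and averted > 0:
        flag, icer = Dominance.DOMINANT, None
    elif dc > 0 and averted < 0:
        flag, icer = Dominance.DOMINATED, None
    else:
        flag, icer = Dominance.ICER, dc / averted
    return IncrementalOutcome(horizon=out_screen.horizon, delta_cost=dc,
                              life_years_gained=lyg, dalys_averted=averted,
                              flag=flag, icer=icer)


def who_classification(result: IncrementalOutcome | float,
                       gdp_per_capita: float) -> WHOClass:
    """WHO Commission on Macroeconomics and Health threshold classes:
    highly cost-effective below one GDP per head per DALY averted,
    cost-effective below three, otherwise not cost-effective."""
    if gdp_per_capita <= 0:
        raise ValueError("gdp_per_capita must be positive")
    if isinstance(result, IncrementalOutcome):
        if result.flag is Dominance.DOMINANT:
            return WHOClass.DOMINANT
        if result.icer is None:
            return WHOClass.NOT_COST_EFFECTIVE
        icer = result.icer
    else:
        icer = float(result)
    if icer < gdp_per_capita:
        return WHOClass.HIGHLY_COST_EFFECTIVE
    if icer < 3.0 * gdp_per_capita:
        return WHOClass.COST_EFFECTIVE
    return WHOClass.NOT_COST_EFFECTIVE
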