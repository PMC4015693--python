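"""Cost accrual (2010 EUR, provider perspective) on a cohort trace.

Cost components, per cycle and for the whole cohort:

    screening           marginal per-neonate screening cost, cycle 0,
                        screening arm only
    confirmation        confirmatory work-up (metabolites, mutation,
                        enzyme activity) for screen-positives at cycle 0
                        and for early (macrocephaly / high-risk) diagnoses
    clinical_diagnosis  diagnostic bundle after an acute encephalopathic
                        crisis, attached to every clinical presentation
    outpatient / inpatient / dietary
                        guideline treatment for every diagnosed-alive
                        person-year, on age-dependent schedules (identical
                        frequencies for asymptomatic and impaired)
    schooling           special schooling, impaired person-years ages 6-16
    special_care        special care, impaired person-years after age 6
    smd_overhead        annual lump-sum overhead per impaired person-year
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTrace, Scenario
from .parameters import ParameterSet

__all__ = [
    "COMPONENTS",
    "CostBreakdown",
    "direct_screening_cost",
    "confirmation_cost",
    "accrue_costs",
    "SCHOOLING_AGES",
    "SPECIAL_CARE_FROM_AGE",
]

COMPONENTS = (
    "screening",
    "confirmation",
    "clinical_diagnosis",
    "outpatient",
    "inpatient",
    "dietary",
    "schooling",
    "special_care",
    "smd_overhead",
)

#: "age 6 to 16" -> integer-age cycles 6..16 inclusive.
SCHOOLING_AGES = (6, 16)
#: "starting after age of 6" -> integer-age cycles 7 and above.
SPECIAL_CARE_FROM_AGE = 7


def direct_screening_cost(recall_rate: float, cost_recall_exam: float,
                          cost_recall_test: float) -> float:
    """Marginal cost per neonate of adding the C5DC marker to an existing
    MS/MS panel: only the additional recalls cost anything."""
    if recall_rate < 0 or cost_recall_exam < 0 or cost_recall_test < 0:
        raise ValueError("screening-cost inputs must be >= 0")
    return recall_rate * (cost_recall_exam + cost_recall_test)


def confirmation_cost(metabolite: float, mutation: float, enzyme: float,
                      enzyme_fraction: float) -> float:
    """Expected confirmatory-testing cost per screen-positive newborn:
    metabolite and mutation analysis always, enzyme activity only in the
    fraction of unclear cases."""
    if min(metabolite, mutation, enzyme) < 0:
        raise ValueError("confirmation-cost inputs must be >= 0")
    if not 0 <= enzyme_fraction <= 1:
        raise ValueError("enzyme_fraction must lie in [0, 1]")
    return metabolite + mutation + enzyme_fraction * enzyme


@dataclass
class CostBreakdown:
    """Undiscounted per-cycle cost by component, whole cohort, EUR.

    Component arrays cover cycles 0..horizon-1 (cycle-start person-year
    convention; event costs sit at the destination cycle of the
    transition that produced the event).  Batched parameter sets add a
    leading axis.
    """

    components: dict[str, np.ndarray]
    scenario: Scenario

    @property
    def total(self) -> np.ndarray:
        return sum(self.components[c] for c in COMPONENTS)

    def to_frame(self) -> pd.DataFrame:
        if self.components["screening"].ndim != 1:
            raise ValueError("to_frame supports scalar (unbatched) breakdowns only")
        n = len(self.components["screening"])
        frame = pd.DataFrame({"cycle": np.arange(n), "scenario": self.scenario.value,
                              **self.components})
        frame["total"] = self.total
        return frame


def _col(v) -> np.ndarray:
    """Broadcast a per-draw parameter against a trailing cycle axis."""
    a = np.asarray(v, dtype=float)
    return a[..., None] if a.ndim > 0 else a


def accrue_costs(trace: CohortTrace, scenario: Scenario,
                 params: ParameterSet) -> CostBreakdown:
    """Attach every cost component to a cohort trace.

    Raises if an age schedule does not cover the trace's horizon.
    """
    horizon = trace.horizon
    size = trace.cohort_size
    ages = np.arange(horizon)

    out_sched = params.outpatient_visits_by_age.values(horizon)
    in_sched = params.inpatient_stays_by_age.values(horizon)
    diet_sched = params.dietary_cost_by_age.values(horizon)

    diag_py = trace.diagnosed_alive[..., :horizon] * size
    imp_py = trace.impaired[..., :horizon] * size
    clin_events = trace.events["clinical_presentations"][..., :horizon] * size
    early_events = trace.events["early_diagnoses"][..., :horizon] * size

    comp = {c: np.zeros_like(diag_py) for c in COMPONENTS}

    if scenario is Scenario.SCREENING:
        comp["screening"][..., 0] = np.asarray(params.cost_screen_per_neonate) * size
        comp["confirmation"][..., 0] = (
            trace.initial_true_positives * size * np.asarray(params.cost_confirmation)
        )
    comp["confirmation"] = comp["confirmation"] \
        + early_events * _col(params.cost_confirmation)
    comp["clinical_diagnosis"] = clin_events * _col(params.cost_crisis_diagnosis)

    comp["outpatient"] = diag_py * out_sched * _col(params.cost_outpatient_visit)
    comp["inpatient"] = diag_py * in_sched * _col(params.cost_inpatient_stay)
    comp["dietary"] = diag_py * diet_sched

    school_mask = (ages >= SCHOOLING_AGES[0]) & (ages <= SCHOOLING_AGES[1])
    care_mask = ages >= SPECIAL_CARE_FROM_AGE
    comp["schooling"] = imp_py * school_mask * _col(params.cost_schooling_annual)
    comp["special_care"] = imp_py * care_mask * _col(params.cost_special_care_annual)
    comp["smd_overhead"] = imp_py * _col(params.cost_smd_overhead_annual)

    return CostBreakdown(components=comp, scenario=scenario)
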