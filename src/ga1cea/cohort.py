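"""Annual-cycle Markov cohort model of GA-I under screening / no screening.

The cohort of newborns is tracked through five public health states:

    UNAFFECTED              no GA-I
    UNDIAGNOSED             GA-I, alive, diagnosis not yet established
    ASYMPTOMATIC_DIAGNOSED  GA-I, diagnosed, no severe movement disorder
                            (includes milder movement disorders)
    IMPAIRED                severe movement disorder (sMD) after striatal
                            injury; higher cost and excess mortality
    DEAD                    absorbing

Internally the diagnosed-asymptomatic state is split into a pending-risk
sub-state (screen-detected newborns who may still develop sMD during the
manifestation window, total risk ``p_smd_given_diagnosed``) and a safe
sub-state, which keeps the process Markovian; the two are merged in every
public trace.

Disease dynamics follow the manifestation window of GA-I (irreversible
striatal injury essentially confined to ages 0-3): undiagnosed affected
children resolve uniformly over the three transitions into that window,
either by early (macrocephaly / high-risk) diagnosis or by clinical
presentation after an encephalopathic crisis, each route carrying its own
sMD risk.  From age 3 on no new presentations occur.  Background
mortality applies to all alive states; the impaired state carries an
additional constant annual excess death probability 1/le_impaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .parameters import LifeTable, ParameterSet

__all__ = [
    "HealthState",
    "Scenario",
    "CohortTrace",
    "initial_occupancy",
    "transition",
    "run_cohort",
    "microsim_oracle",
    "WINDOW_YEARS",
]

#: Manifestation window: diagnostic resolution and sMD onset complete by age 3.
WINDOW_YEARS = 3


class HealthState(Enum):
    UNAFFECTED = 0
    UNDIAGNOSED = 1
    ASYMPTOMATIC_DIAGNOSED = 2
    IMPAIRED = 3
    DEAD = 4


class Scenario(Enum):
    SCREENING = "screening"
    NO_SCREENING = "no_screening"


# internal state indices (DX split into pending-risk / safe sub-states)
_UNAFF, _UNDIAG, _DX_PEND, _DX_SAFE, _IMP, _DEAD = range(6)
_N_INTERNAL = 6

_EVENTS = ("clinical_presentations", "early_diagnoses", "smd_onsets", "deaths")


# ---------------------------------------------------------------------------
# Transition mechanics
# ---------------------------------------------------------------------------

def initial_occupancy(scenario: Scenario, params: ParameterSet) -> np.ndarray:
    """Occupancy vector at birth (internal 6-state layout).

    Under screening, detected affected newborns (prevalence x sensitivity)
    start diagnosed with pending sMD risk; false negatives start
    undiagnosed and follow the no-screening pathway.  Nobody is impaired
    or dead at birth.
    """
    p = np.asarray(params.prevalence, dtype=float)
    sens = np.asarray(params.test_sensitivity, dtype=float)
    shape = np.broadcast_shapes(p.shape, sens.shape)
    occ = np.zeros(shape + (_N_INTERNAL,))
    occ[..., _UNAFF] = 1.0 - p
    if scenario is Scenario.SCREENING:
        occ[..., _DX_PEND] = p * sens
        occ[..., _UNDIAG] = p * (1.0 - sens)
    else:
        occ[..., _UNDIAG] = p
    return occ


def transition(occ: np.ndarray, age: int, params: ParameterSet,
               qx_age: float) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """One annual transition from integer age ``age`` to ``age + 1``.

    Background mortality acts first on every alive state (the impaired
    state compounds the excess hazard as an independent risk); diagnostic
    resolution and sMD onset then act on survivors while the age lies in
    the manifestation window.  Returns the next occupancy and the event
    counts (as cohort fractions) realised during the transition.
    """
    occ = np.asarray(occ, dtype=float)
    q = qx_age
    h_ex = 1.0 / np.asarray(params.le_impaired, dtype=float)
    p_die_imp = 1.0 - (1.0 - q) * (1.0 - h_ex)

    deaths = q * (occ[..., _UNAFF] + occ[..., _UNDIAG]
                  + occ[..., _DX_PEND] + occ[..., _DX_SAFE]) \
        + p_die_imp * occ[..., _IMP]

    nxt = np.empty_like(occ)
    nxt[..., _UNAFF] = occ[..., _UNAFF] * (1.0 - q)
    undiag = occ[..., _UNDIAG] * (1.0 - q)
    pend = occ[..., _DX_PEND] * (1.0 - q)
    safe = occ[..., _DX_SAFE] * (1.0 - q)
    imp = occ[..., _IMP] * (1.0 - p_die_imp)
    nxt[..., _DEAD] = occ[..., _DEAD] + deaths

    zeros = np.zeros(np.shape(deaths))
    events = {
        "clinical_presentations": zeros.copy(),
        "early_diagnoses": zeros.copy(),
        "smd_onsets": zeros.copy(),
        "deaths": deaths,
    }

    if age < WINDOW_YEARS:
        p_early = np.asarray(params.p_early_diagnosis, dtype=float)
        p_dx = np.asarray(params.p_smd_given_diagnosed, dtype=float)
        p_cl = np.asarray(params.p_smd_given_clinical, dtype=float)
        _check_probability(p_dx, "p_smd_given_diagnosed")
        _check_probability(p_cl, "p_smd_given_clinical")

        # uniform thirds of the original mass: conditional fractions 1/3, 1/2, 1
        resolve = undiag / (WINDOW_YEARS - age)
        early = resolve * p_early
        clin = resolve * (1.0 - p_early)
        # pending-risk conversion so the total over the window is exactly p_dx
        conv = pend * (p_dx / WINDOW_YEARS) / (1.0 - age * p_dx / WINDOW_YEARS)

        new_imp = early * p_dx + clin * p_cl + conv
        undiag = undiag - resolve
        pend = pend - conv
        safe = safe + early * (1.0 - p_dx) + clin * (1.0 - p_cl)
        imp = imp + new_imp
        if age == WINDOW_YEARS - 1:  # window closes: residual risk exhausted
            safe = safe + pend
            pend = zeros.copy()
        events["clinical_presentations"] = clin
        events["early_diagnoses"] = early
        events["smd_onsets"] = new_imp

    nxt[..., _UNDIAG] = undiag
    nxt[..., _DX_PEND] = pend
    nxt[..., _DX_SAFE] = safe
    nxt[..., _IMP] = imp
    return nxt, events


def _check_probability(p: np.ndarray, name: str) -> None:
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{name}: composed probability outside [0, 1]")


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle state occupancy and event counts for one scenario.

    ``occupancy`` has shape (horizon + 1, 6) in the internal state layout
    (row t = start of cycle t); event arrays have length horizon + 1 and
    are indexed by the *destination* cycle of the transition that produced
    them (index 0 is therefore always zero).  For vectorised parameter
    batches a leading batch axis precedes these.
    """

    scenario: Scenario
    occupancy: np.ndarray
    events: dict[str, np.ndarray]
    cohort_size: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[-2] - 1

    def state_occupancy(self, state: HealthState) -> np.ndarray:
        """Public 5-state occupancy fractions per cycle."""
        o = self.occupancy
        if state is HealthState.ASYMPTOMATIC_DIAGNOSED:
            return o[..., _DX_PEND] + o[..., _DX_SAFE]
        return o[..., {HealthState.UNAFFECTED: _UNAFF,
                       HealthState.UNDIAGNOSED: _UNDIAG,
                       HealthState.IMPAIRED: _IMP,
                       HealthState.DEAD: _DEAD}[state]]

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[..., _DEAD]

    @property
    def impaired(self) -> np.ndarray:
        return self.occupancy[..., _IMP]

    @property
    def diagnosed_alive(self) -> np.ndarray:
        """Fraction alive and diagnosed (treated): asymptomatic + impaired."""
        o = self.occupancy
        return o[..., _DX_PEND] + o[..., _DX_SAFE] + o[..., _IMP]

    @property
    def initial_true_positives(self) -> np.ndarray:
        """Screen-detected affected newborns (fraction of the cohort)."""
        return self.occupancy[..., 0, _DX_PEND] if self.occupancy.ndim == 3 \
            else self.occupancy[0, _DX_PEND]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle table (scalar traces only)."""
        if self.occupancy.ndim != 2:
            raise ValueError("to_frame supports scalar (unbatched) traces only")
        rows = []
        for t in range(self.horizon + 1):
            for state in HealthState:
                rows.append({
                    "cycle": t,
                    "scenario": self.scenario.value,
                    "state": state.name,
                    "occupancy": float(self.state_occupancy(state)[t]),
                })
        frame = pd.DataFrame(rows)
        ev = pd.DataFrame({"cycle": np.arange(self.horizon + 1),
                           **{k: v for k, v in self.events.items()}})
        return frame.merge(ev, on="cycle")


def run_cohort(scenario: Scenario, params: ParameterSet, horizon: int,
               life_table: LifeTable, cohort_size: float = 100_000) -> CohortTrace:
    """Simulate the cohort for ``horizon`` annual cycles.

    Occupancy rows cover cycle starts 0..horizon; events are recorded at
    their destination cycle.  Works for scalar parameter sets and for
    vectorised batches alike.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if horizon > life_table.max_age:
        raise ValueError("horizon exceeds the life table's maximum age")
    occ = initial_occupancy(scenario, params)
    occupancy = np.empty(occ.shape[:-1] + (horizon + 1, _N_INTERNAL))
    occupancy[..., 0, :] = occ
    events = {k: np.zeros(occ.shape[:-1] + (horizon + 1,)) for k in _EVENTS}
    for t in range(horizon):
        occ, ev = transition(occ, t, params, float(life_table.qx[t]))
        occupancy[..., t + 1, :] = occ
        for k in _EVENTS:
            events[k][..., t + 1] = ev[k]
    return CohortTrace(scenario=scenario, occupancy=occupancy,
                       events=events, cohort_size=cohort_size)


# ---------------------------------------------------------------------------
# Individual-level microsimulation oracle
# ---------------------------------------------------------------------------

def microsim_oracle(scenario: Scenario, params: ParameterSet, n_individuals: int,
                    horizon: int, rng: np.random.Generator,
                    life_table: LifeTable) -> tuple[CohortTrace, np.ndarray]:
    """Monte Carlo simulation of individual newborns under identical hazards.

    Serves as an independent check of the cohort recursion: every hazard
    is realised by individual Bernoulli draws instead of expected-value
    bookkeeping.  Returns an occupancy-estimate trace plus the binomial
    standard error of each occupancy entry, shape (horizon+1, 6).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    p = float(params.prevalence)
    sens = float(params.test_sensitivity)
    p_early = float(params.p_early_diagnosis)
    p_dx = float(params.p_smd_given_diagnosed)
    p_cl = float(params.p_smd_given_clinical)
    h_ex = 1.0 / float(params.le_impaired)

    state = np.full(n_individuals, _UNAFF, dtype=np.int8)
    affected = rng.random(n_individuals) < p
    if scenario is Scenario.SCREENING:
        detected = affected & (rng.random(n_individuals) < sens)
        state[detected] = _DX_PEND
        state[affected & ~detected] = _UNDIAG
    else:
        state[affected] = _UNDIAG

    occupancy = np.zeros((horizon + 1, _N_INTERNAL))
    events = {k: np.zeros(horizon + 1) for k in _EVENTS}

    def _tally(t):
        counts = np.bincount(state, minlength=_N_INTERNAL)
        occupancy[t] = counts / n_individuals

    _tally(0)
    for t in range(horizon):
        q = float(life_table.qx[t])
        u_death = rng.random(n_individuals)
        alive = state != _DEAD
        die = alive & (u_death < q)
        die |= (state == _IMP) & ~die & (rng.random(n_individuals) < h_ex)
        events["deaths"][t + 1] = die.sum() / n_individuals
        state[die] = _DEAD

        if t < WINDOW_YEARS:
            u = rng.random(n_individuals)
            resolve = (state == _UNDIAG) & (u < 1.0 / (WINDOW_YEARS - t))
            early = resolve & (rng.random(n_individuals) < p_early)
            clin = resolve & ~early
            smd_route = np.where(early, p_dx, p_cl)
            to_imp = resolve & (rng.random(n_individuals) < smd_route)
            state[resolve] = _DX_SAFE
            state[to_imp] = _IMP
            conv_p = (p_dx / WINDOW_YEARS) / (1.0 - t * p_dx / WINDOW_YEARS)
            conv = (state == _DX_PEND) & (rng.random(n_individuals) < conv_p)
            state[conv] = _IMP
            if t == WINDOW_YEARS - 1:
                state[state == _DX_PEND] = _DX_SAFE
            events["clinical_presentations"][t + 1] = clin.sum() / n_individuals
            events["early_diagnoses"][t + 1] = early.sum() / n_individuals
            events["smd_onsets"][t + 1] = (to_imp.sum() + conv.sum()) / n_individuals
        _tally(t + 1)

    se = np.sqrt(np.clip(occupancy * (1.0 - occupancy), 0, None) / n_individuals)
    trace = CohortTrace(scenario=scenario, occupancy=occupancy,
                        events=events, cohort_size=float(n_individuals))
    return trace, se
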