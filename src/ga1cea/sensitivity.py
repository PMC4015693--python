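"""Sensitivity analysis: one-way, probabilistic (Monte Carlo), screening-cost
threshold, and the prevalence x screening-cost grid.

The probabilistic sensitivity analysis draws every distributed input
jointly and independently over its full range (50,000 repetitions by
default) and propagates each draw through both scenario arms of the
cohort model; uncertainty is summarised by the empirical mean and
2.5/97.5 percentiles.  Incremental cost is affine in the per-neonate
screening cost with slope equal to the cohort size (the screening fee is
paid once, at cycle 0, undiscounted), which the threshold and grid
analyses exploit exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Scenario, run_cohort
from .costs import accrue_costs
from .outcomes import ScenarioOutcome, incremental, scenario_outcome
from .parameters import (LifeTable, ModelConfig, ParameterSet, base_case,
                         build_life_table, draw_parameter_set)

__all__ = [
    "PSAResult",
    "OneWayResult",
    "evaluate_parameter_set",
    "run_psa",
    "one_way",
    "icer_vs_screening_cost",
    "break_even_screening_cost",
    "prevalence_grid",
]


def _life_table_for(config: ModelConfig,
                    life_table: LifeTable | None) -> LifeTable:
    if life_table is not None:
        return life_table
    return build_life_table(config.life_expectancy_at_birth, config.max_age)


def evaluate_parameter_set(params: ParameterSet, horizon: int,
                           life_table: LifeTable, cohort_size: float,
                           discount_life_years: bool = True
                           ) -> tuple[ScenarioOutcome, ScenarioOutcome]:
    """Run both scenario arms for one parameter set (scalar or batched)."""
    outs = []
    for scenario in (Scenario.SCREENING, Scenario.NO_SCREENING):
        trace = run_cohort(scenario, params, horizon, life_table, cohort_size)
        breakdown = accrue_costs(trace, scenario, params)
        outs.append(scenario_outcome(trace, breakdown, params,
                                     discount_life_years=discount_life_years))
    return outs[0], outs[1]


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Empirical distribution of the incremental outcome over PSA draws."""

    horizon: int
    n_draws: int
    seed: int | None
    delta_cost: np.ndarray
    life_years_gained: np.ndarray
    dalys_averted: np.ndarray

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    def percentiles(self, values: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(values, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def fraction_cost_saving(self) -> float:
        return float(np.mean(self.delta_cost < 0))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, v in (("delta_cost", self.delta_cost),
                        ("life_years_gained", self.life_years_gained),
                        ("dalys_averted", self.dalys_averted)):
            lo, hi = self.percentiles(v)
            rows.append({"quantity": name, "mean": float(v.mean()),
                         "p2.5": lo, "p97.5": hi})
        return pd.DataFrame(rows)

    def mean_icer(self) -> float | None:
        """ICER of mean incremental cost over mean DALYs averted; None
        (dominant, printed "<0") when the mean cost difference is negative."""
        dc, de = float(self.delta_cost.mean()), float(self.dalys_averted.mean())
        if de <= 0:
            return None
        return None if dc < 0 else dc / de


def run_psa(config: ModelConfig, horizon: int, n_draws: int = 50_000,
            seed: int | None = None, life_table: LifeTable | None = None,
            chunk_size: int = 10_000,
            discount_life_years: bool = True) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    All distributed inputs are drawn jointly for ``n_draws`` repetitions
    up front (so results do not depend on ``chunk_size``), then evaluated
    through both arms in vectorised chunks.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    lt = _life_table_for(config, life_table)
    rng = np.random.default_rng(seed)
    params = draw_parameter_set(config, rng, size=n_draws)

    dc = np.empty(n_draws)
    lyg = np.empty(n_draws)
    averted = np.empty(n_draws)
    for start in range(0, n_draws, chunk_size):
        sl = slice(start, min(start + chunk_size, n_draws))
        batch = _slice_params(params, sl)
        s, ns = evaluate_parameter_set(batch, horizon, lt, config.cohort_size,
                                       discount_life_years)
        dc[sl] = s.discounted_cost - ns.discounted_cost
        lyg[sl] = s.discounted_life_years - ns.discounted_life_years
        averted[sl] = lyg[sl] + (ns.discounted_yld - s.discounted_yld)
    return PSAResult(horizon=horizon, n_draws=n_draws, seed=seed,
                     delta_cost=dc, life_years_gained=lyg,
                     dalys_averted=averted)


def _slice_params(params: ParameterSet, sl: slice) -> ParameterSet:
    from .parameters import _SAMPLED_FIELDS
    return params.with_(**{f: np.asarray(getattr(params, f))[sl]
                           for f in _SAMPLED_FIELDS})


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class OneWayResult:
    """Incremental outcomes with one input at its min / base / max."""

    parameter: str
    horizon: int
    at_min: object
    at_base: object
    at_max: object

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, out in (("min", self.at_min), ("base", self.at_base),
                           ("max", self.at_max)):
            row = out.to_row()
            row.insert(0, "setting", label)
            row.insert(0, "parameter", self.parameter)
            frames.append(row)
        return pd.concat(frames, ignore_index=True)


def one_way(config: ModelConfig, parameter_name: str, horizon: int,
            life_table: LifeTable | None = None) -> OneWayResult:
    """Vary a single ranged input over min / base / max, all else base case."""
    if parameter_name not in config.distributions:
        raise KeyError(f"unknown parameter {parameter_name!r}")
    spec = config.distributions[parameter_name]
    if not spec.has_range:
        raise ValueError(f"{parameter_name}: no range to vary")
    lt = _life_table_for(config, life_table)
    bc = base_case(config)
    lo, hi = spec.bounds()
    results = {}
    for label, value in (("min", lo), ("base", spec.base_value()), ("max", hi)):
        p = bc.with_(**{parameter_name: value})
        p.validate()
        s, ns = evaluate_parameter_set(p, horizon, lt, config.cohort_size)
        results[label] = incremental(s, ns)
    return OneWayResult(parameter=parameter_name, horizon=horizon,
                        at_min=results["min"], at_base=results["base"],
                        at_max=results["max"])


# ---------------------------------------------------------------------------
# Screening-cost threshold analysis
# ---------------------------------------------------------------------------

def _psa_at_zero_screening_cost(config: ModelConfig, horizon: int,
                                n_draws: int, seed: int | None,
                                life_table: LifeTable | None) -> PSAResult:
    from .parameters import DistributionSpec
    dists = dict(config.distributions)
    dists["cost_screen_per_neonate"] = DistributionSpec(kind="point", value=0.0)
    cfg0 = replace(config, distributions=dists)
    return run_psa(cfg0, horizon, n_draws, seed, life_table)


def icer_vs_screening_cost(config: ModelConfig, horizon: int,
                           cost_grid: np.ndarray, n_draws: int = 50_000,
                           seed: int | None = None,
                           life_table: LifeTable | None = None) -> pd.DataFrame:
    """Mean incremental cost and ICER as a function of the per-neonate
    screening cost.

    Incremental cost is exactly affine in the screening cost (slope =
    cohort size, paid at cycle 0), so a single PSA at zero screening cost
    determines the whole curve.
    """
    cost_grid = np.asarray(cost_grid, dtype=float)
    if np.any(cost_grid < 0):
        raise ValueError("screening costs must be >= 0")
    psa0 = _psa_at_zero_screening_cost(config, horizon, n_draws, seed, life_table)
    mean_dc0 = float(psa0.delta_cost.mean())
    mean_daly = float(psa0.dalys_averted.mean())
    rows = []
    for c in cost_grid:
        mean_dc = mean_dc0 + config.cohort_size * c
        icer = mean_dc / mean_daly if (mean_dc > 0 and mean_daly > 0) else None
        rows.append({"screening_cost": c, "mean_delta_cost": mean_dc,
                     "icer": icer, "dominant": mean_dc < 0})
    return pd.DataFrame(rows)


def break_even_screening_cost(config: ModelConfig, horizon: int,
                              n_draws: int = 50_000, seed: int | None = None,
                              life_table: LifeTable | None = None,
                              psa0: PSAResult | None = None) -> float | None:
    """Per-neonate screening cost at which the mean incremental cost is
    zero: the cost-saving margin at zero screening cost divided by the
    cohort size (the affine root).  None when the model is not
    cost-saving even at zero screening cost."""
    if psa0 is None:
        psa0 = _psa_at_zero_screening_cost(config, horizon, n_draws, seed,
                                           life_table)
    mean_dc0 = float(psa0.delta_cost.mean())
    if mean_dc0 >= 0:
        return None
    return -mean_dc0 / config.cohort_size


# ---------------------------------------------------------------------------
# Prevalence x screening-cost grid
# ---------------------------------------------------------------------------

def _recentre_prevalence(config: ModelConfig, target: float) -> ModelConfig:
    """Scale the prevalence distribution multiplicatively so its mode equals
    ``target`` (relative uncertainty preserved)."""
    spec = config.distributions["prevalence"]
    if spec.kind != "triangular":
        raise ValueError("prevalence re-centring expects a triangular spec")
    factor = target / spec.mode
    new = replace(spec, mode=spec.mode * factor, min=spec.min * factor,
                  max=spec.max * factor)
    dists = dict(config.distributions)
    dists["prevalence"] = new
    return replace(config, distributions=dists)


def prevalence_grid(config: ModelConfig, prevalences: np.ndarray,
                    screening_costs: np.ndarray, horizon: int,
                    n_draws: int = 50_000, seed: int | None = None,
                    life_table: LifeTable | None = None) -> pd.DataFrame:
    """PSA per grid cell of prevalence x per-neonate screening cost.

    Each prevalence level uses an independent, deterministic random
    substream keyed on (seed, prevalence value), so results do not
    depend on evaluation order.  Screening-cost columns reuse the same
    draws through the exact affine shift.  The ICER interval is the
    percentile interval of per-draw ratios over draws with positive DALY
    denominators; the fraction of draws straddling dominance is reported.
    """
    prevalences = np.asarray(prevalences, dtype=float)
    screening_costs = np.asarray(screening_costs, dtype=float)
    if np.any((prevalences <= 0) | (prevalences >= 1)):
        raise ValueError("prevalence values must lie in (0, 1)")
    lt = _life_table_for(config, life_table)
    rows = []
    for prev in prevalences:
        cfg = _recentre_prevalence(config, prev)
        cell_key = int(round(prev * 10**12))  # stable per-value substream key
        cell_seed = np.random.SeedSequence([0 if seed is None else seed, cell_key])
        cell_rng_seed = int(cell_seed.generate_state(1)[0] % (2**31))
        psa0 = _psa_at_zero_screening_cost(cfg, horizon, n_draws,
                                           cell_rng_seed, lt)
        for c in screening_costs:
            dc = psa0.delta_cost + config.cohort_size * c
            mean_dc = float(dc.mean())
            lo, hi = np.percentile(dc, [2.5, 97.5])
            mean_daly = float(psa0.dalys_averted.mean())
            dominant = mean_dc < 0
            icer = mean_dc / mean_daly if (not dominant and mean_daly > 0) else None
            pos = psa0.dalys_averted > 0
            ratios = dc[pos] / psa0.dalys_averted[pos]
            icer_lo, icer_hi = (np.percentile(ratios, [2.5, 97.5])
                                if ratios.size else (np.nan, np.nan))
            rows.append({
                "prevalence": prev, "screening_cost": float(c),
                "mean_delta_cost": mean_dc,
                "delta_cost_p2.5": float(lo), "delta_cost_p97.5": float(hi),
                "dominant": dominant, "icer": icer,
                "icer_p2.5": float(icer_lo), "icer_p97.5": float(icer_hi),
                "fraction_cost_saving": float(np.mean(dc < 0)),
            })
    return pd.DataFrame(rows)
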