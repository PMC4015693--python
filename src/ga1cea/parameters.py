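"""Model inputs: distributions, parameter sets, age schedules, life table.

Every input of the decision model is declared in a structured YAML
configuration (the packaged default reproduces the published input table
row-by-row).  Uncertain inputs are ``DistributionSpec`` objects (point /
triangular / uniform); deterministic runs collapse each to a base-case
value, probabilistic sensitivity analysis samples them independently.

Background mortality of the healthy (and asymptomatic diagnosed)
population is represented by a synthetic period life table calibrated so
that discrete life expectancy at birth matches a configured target
(79.45 years, the German 2009 figure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "ConfigError",
    "DistributionSpec",
    "AgeSchedule",
    "ParameterSet",
    "LifeTable",
    "ModelConfig",
    "load_config",
    "base_case",
    "sample_distribution",
    "draw_parameter_set",
    "build_life_table",
    "life_expectancy",
    "TABLE1_MANIFEST",
]


class ConfigError(ValueError):
    """A configuration value violates its declared constraint."""


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------

_KINDS = ("point", "triangular", "uniform")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampled-or-fixed model input.

    kind = "point"      : fixed at ``value``.
    kind = "triangular" : triangular on [min, max] with ``mode``.
    kind = "uniform"    : uniform on [min, max].

    ``base`` optionally overrides the deterministic base-case value
    (default: point -> value, triangular -> mode, uniform -> midpoint).
    """

    kind: str
    value: float | None = None
    mode: float | None = None
    min: float | None = None
    max: float | None = None
    base: float | None = None

    def validate(self, name: str = "parameter") -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"{name}: unknown distribution kind {self.kind!r}")
        if self.kind == "point":
            if self.value is None or not np.isfinite(self.value):
                raise ConfigError(f"{name}: point distribution needs a finite 'value'")
        elif self.kind == "triangular":
            if self.min is None or self.mode is None or self.max is None:
                raise ConfigError(f"{name}: triangular needs 'min', 'mode', 'max'")
            if not (self.min <= self.mode <= self.max):
                raise ConfigError(
                    f"{name}: triangular requires min <= mode <= max "
                    f"(got {self.min}, {self.mode}, {self.max})"
                )
        else:  # uniform
            if self.min is None or self.max is None:
                raise ConfigError(f"{name}: uniform needs 'min' and 'max'")
            if not (self.min <= self.max):
                raise ConfigError(f"{name}: uniform requires min <= max")

    @property
    def has_range(self) -> bool:
        """True when the input actually varies (used by sensitivity analysis)."""
        if self.kind == "point":
            return False
        return bool(self.min < self.max)

    def base_value(self) -> float:
        if self.base is not None:
            return float(self.base)
        if self.kind == "point":
            return float(self.value)
        if self.kind == "triangular":
            return float(self.mode)
        return float(0.5 * (self.min + self.max))

    def bounds(self) -> tuple[float, float]:
        if self.kind == "point":
            return float(self.value), float(self.value)
        return float(self.min), float(self.max)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution (point mass returns the value exactly)."""
        self.validate()
        if self.kind == "point":
            v = float(self.value)
            return v if size is None else np.full(size, v)
        if self.min == self.max:  # degenerate support
            v = float(self.min)
            return v if size is None else np.full(size, v)
        if self.kind == "triangular":
            out = rng.triangular(self.min, self.mode, self.max, size=size)
        else:
            out = rng.uniform(self.min, self.max, size=size)
        return float(out) if size is None else out


def _coerce_number(v, name: str) -> float:
    """Accept plain numbers or the ``{one_in: N}`` rate notation."""
    if isinstance(v, Mapping):
        if set(v) != {"one_in"}:
            raise ConfigError(f"{name}: unrecognised value mapping {v!r}")
        n = float(v["one_in"])
        if n <= 0:
            raise ConfigError(f"{name}: one_in denominator must be positive")
        return 1.0 / n
    return float(v)


def _spec_from_dict(d: Mapping, name: str) -> DistributionSpec:
    if not isinstance(d, Mapping) or "kind" not in d:
        raise ConfigError(f"{name}: expected a mapping with a 'kind' field")
    kwargs = {}
    for key in ("value", "mode", "min", "max", "base"):
        if key in d and d[key] is not None:
            kwargs[key] = _coerce_number(d[key], f"{name}.{key}")
    spec = DistributionSpec(kind=str(d["kind"]), **kwargs)
    spec.validate(name)
    return spec


# ---------------------------------------------------------------------------
# Age schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeSchedule:
    """Piecewise-constant annual quantity by integer age band (inclusive)."""

    bands: tuple[tuple[int, int, float], ...]

    @classmethod
    def from_config(cls, rows: Sequence[Mapping], name: str) -> "AgeSchedule":
        try:
            bands = tuple(
                (int(r["age_min"]), int(r["age_max"]), float(r["annual_value"]))
                for r in rows
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{name}: each band needs age_min, age_max, annual_value") from exc
        sched = cls(bands)
        sched.validate(name)
        return sched

    def validate(self, name: str = "schedule") -> None:
        if not self.bands:
            raise ConfigError(f"{name}: empty schedule")
        prev_end = -1
        for lo, hi, v in sorted(self.bands):
            if lo > hi:
                raise ConfigError(f"{name}: band {lo}-{hi} has age_min > age_max")
            if lo != prev_end + 1:
                raise ConfigError(
                    f"{name}: bands must tile the ages without gap/overlap "
                    f"(band starting at {lo} follows one ending at {prev_end})"
                )
            if v < 0:
                raise ConfigError(f"{name}: annual_value must be >= 0 in band {lo}-{hi}")
            prev_end = hi
        if min(lo for lo, _, _ in self.bands) != 0:
            raise ConfigError(f"{name}: schedule must start at age 0")

    @property
    def max_age(self) -> int:
        return max(hi for _, hi, _ in self.bands)

    def values(self, max_age: int) -> np.ndarray:
        """Annual value for every integer age 0..max_age-1."""
        if max_age - 1 > self.max_age:
            raise ConfigError(
                f"schedule covers ages 0-{self.max_age} but age {max_age - 1} required"
            )
        out = np.empty(max_age)
        for lo, hi, v in self.bands:
            out[lo : min(hi, max_age - 1) + 1] = v
        return out


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

_SAMPLED_FIELDS = (
    # canonical sampling order: one rng stream, fixed order, reproducible
    "test_specificity",
    "test_sensitivity",
    "prevalence",
    "p_early_diagnosis",
    "p_smd_given_diagnosed",
    "p_smd_given_clinical",
    "le_healthy",
    "le_impaired",
    "disability_weight_smd",
    "cost_crisis_diagnosis",
    "cost_confirmation",
    "cost_screen_per_neonate",
    "cost_outpatient_visit",
    "cost_inpatient_stay",
    "cost_schooling_annual",
    "cost_special_care_annual",
    "cost_smd_overhead_annual",
)

#: Input-table row name -> ParameterSet field (completeness checked in tests).
TABLE1_MANIFEST: dict[str, str] = {
    "Test Specificity (including confirmation by enzyme analysis)": "test_specificity",
    "Test Sensitivity": "test_sensitivity",
    "Prevalence based on positive test result": "prevalence",
    "Probability of early diagnosis before the onset of sMD": "p_early_diagnosis",
    "Probability that severe movement disorder develops in previously diagnosed children": "p_smd_given_diagnosed",
    "Probability that severe movement disorder occur following clinical manifestation": "p_smd_given_clinical",
    "Life expectancy of healthy population": "le_healthy",
    "Life expectancy in impaired health state": "le_impaired",
    "Initial medical cost for children experiencing an acute encephalopathic crisis": "cost_crisis_diagnosis",
    "Cost for genetic and enzymatic confirmation studies": "cost_confirmation",
    "Direct screening cost per neonate": "cost_screen_per_neonate",
    "Cost per outpatient visit": "cost_outpatient_visit",
    "Cost per inpatient treatment": "cost_inpatient_stay",
    "Number of outpatient treatments per year": "outpatient_visits_by_age",
    "Number of inpatient treatments per year": "inpatient_stays_by_age",
    "Cost for basic dietary treatment per year": "dietary_cost_by_age",
    "Annual cost for special schooling (included for age 6 to 16)": "cost_schooling_annual",
    "Annual cost for special care, starting after age of 6": "cost_special_care_annual",
    "Annual overhead cost in case of severe movement disorder": "cost_smd_overhead_annual",
}


@dataclass
class ParameterSet:
    """One concrete realisation of every model input.

    Sampled fields may be scalars (one deterministic run) or 1-D arrays of
    equal length (a whole batch of PSA draws evaluated vectorised).
    """

    test_specificity: float | np.ndarray
    test_sensitivity: float | np.ndarray
    prevalence: float | np.ndarray
    p_early_diagnosis: float | np.ndarray
    p_smd_given_diagnosed: float | np.ndarray
    p_smd_given_clinical: float | np.ndarray
    le_healthy: float | np.ndarray
    le_impaired: float | np.ndarray
    disability_weight_smd: float | np.ndarray
    cost_crisis_diagnosis: float | np.ndarray
    cost_confirmation: float | np.ndarray
    cost_screen_per_neonate: float | np.ndarray
    cost_outpatient_visit: float | np.ndarray
    cost_inpatient_stay: float | np.ndarray
    cost_schooling_annual: float | np.ndarray
    cost_special_care_annual: float | np.ndarray
    cost_smd_overhead_annual: float | np.ndarray
    outpatient_visits_by_age: AgeSchedule
    inpatient_stays_by_age: AgeSchedule
    dietary_cost_by_age: AgeSchedule
    discount_rate: float = 0.03
    recall_rate: float = 0.0008
    cost_recall_exam: float = 31.01
    cost_recall_test: float = 7.00

    def validate(self) -> None:
        probs = {
            "test_specificity": self.test_specificity,
            "test_sensitivity": self.test_sensitivity,
            "prevalence": self.prevalence,
            "p_early_diagnosis": self.p_early_diagnosis,
            "p_smd_given_diagnosed": self.p_smd_given_diagnosed,
            "p_smd_given_clinical": self.p_smd_given_clinical,
            "disability_weight_smd": self.disability_weight_smd,
            "recall_rate": self.recall_rate,
        }
        for name, v in probs.items():
            if not np.all((np.asarray(v) >= 0) & (np.asarray(v) <= 1)):
                raise ConfigError(f"{name}: probability outside [0, 1]")
        costs = {
            "cost_crisis_diagnosis": self.cost_crisis_diagnosis,
            "cost_confirmation": self.cost_confirmation,
            "cost_screen_per_neonate": self.cost_screen_per_neonate,
            "cost_outpatient_visit": self.cost_outpatient_visit,
            "cost_inpatient_stay": self.cost_inpatient_stay,
            "cost_schooling_annual": self.cost_schooling_annual,
            "cost_special_care_annual": self.cost_special_care_annual,
            "cost_smd_overhead_annual": self.cost_smd_overhead_annual,
            "cost_recall_exam": self.cost_recall_exam,
            "cost_recall_test": self.cost_recall_test,
        }
        for name, v in costs.items():
            if not np.all(np.asarray(v) >= 0):
                raise ConfigError(f"{name}: cost must be >= 0")
        if not np.all(np.asarray(self.le_impaired) > 0):
            raise ConfigError("le_impaired: must be positive")
        if not np.all(np.asarray(self.le_impaired) < np.asarray(self.le_healthy)):
            raise ConfigError("le_impaired: must be below le_healthy")
        if not np.all(
            np.asarray(self.p_smd_given_diagnosed) < np.asarray(self.p_smd_given_clinical)
        ):
            raise ConfigError(
                "p_smd_given_diagnosed: must be below p_smd_given_clinical "
                "(the model's central effectiveness assumption)"
            )
        if self.discount_rate < 0:
            raise ConfigError("discount_rate: must be >= 0")
        for name in ("outpatient_visits_by_age", "inpatient_stays_by_age", "dietary_cost_by_age"):
            getattr(self, name).validate(name)

    @property
    def size(self) -> int | None:
        """Batch length when fields are arrays, else None."""
        v = np.asarray(self.test_sensitivity)
        return None if v.ndim == 0 else int(v.shape[0])

    def with_(self, **overrides) -> "ParameterSet":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# Configuration container and loading
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    distributions: dict[str, DistributionSpec]
    schedules: dict[str, AgeSchedule]
    screening: dict[str, float]
    confirmation: dict[str, float]
    cohort_size: int = 100_000
    discount_rate: float = 0.03
    horizons: tuple[int, ...] = (20, 70)
    gdp_per_capita: float = 38_170.0
    life_expectancy_at_birth: float = 79.45
    max_age: int = 110

    def validate(self) -> None:
        missing = [f for f in _SAMPLED_FIELDS if f not in self.distributions]
        if missing:
            raise ConfigError(f"missing parameter(s): {', '.join(missing)}")
        for name, spec in self.distributions.items():
            spec.validate(name)
        for name in ("outpatient_visits_by_age", "inpatient_stays_by_age", "dietary_cost_by_age"):
            if name not in self.schedules:
                raise ConfigError(f"missing schedule: {name}")
            self.schedules[name].validate(name)
        for key in ("recall_rate", "cost_recall_exam", "cost_recall_test"):
            if key not in self.screening:
                raise ConfigError(f"screening: missing key {key}")
        for key in ("cost_metabolite", "cost_mutation", "cost_enzyme", "enzyme_fraction"):
            if key not in self.confirmation:
                raise ConfigError(f"confirmation: missing key {key}")
        if self.cohort_size <= 0:
            raise ConfigError("cohort_size: must be positive")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate: must be >= 0")
        base_case(self).validate()


def _config_from_dict(raw: Mapping) -> ModelConfig:
    try:
        params = raw["parameters"]
        scheds = raw["schedules"]
    except KeyError as exc:
        raise ConfigError(f"config: missing top-level section {exc.args[0]!r}") from exc
    distributions = {
        name: _spec_from_dict(d, name) for name, d in params.items()
    }
    schedules = {
        name: AgeSchedule.from_config(rows, name) for name, rows in scheds.items()
    }
    lt = raw.get("life_table", {})
    cfg = ModelConfig(
        distributions=distributions,
        schedules=schedules,
        screening={k: float(v) for k, v in raw.get("screening", {}).items()},
        confirmation={k: float(v) for k, v in raw.get("confirmation", {}).items()},
        cohort_size=int(raw.get("cohort_size", 100_000)),
        discount_rate=float(raw.get("discount_rate", 0.03)),
        horizons=tuple(int(h) for h in raw.get("horizons", (20, 70))),
        gdp_per_capita=float(raw.get("gdp_per_capita", 38_170.0)),
        life_expectancy_at_birth=float(lt.get("life_expectancy_at_birth", 79.45)),
        max_age=int(lt.get("max_age", 110)),
    )
    cfg.validate()
    return cfg


def load_config(path: str | None = None) -> ModelConfig:
    """Load and validate a model configuration (packaged default if no path)."""
    if path is None:
        text = resources.files("ga1cea").joinpath("data/default_config.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return _config_from_dict(raw)


def _assemble(config: ModelConfig, values: Mapping[str, float | np.ndarray]) -> ParameterSet:
    ps = ParameterSet(
        **{f: values[f] for f in _SAMPLED_FIELDS},
        outpatient_visits_by_age=config.schedules["outpatient_visits_by_age"],
        inpatient_stays_by_age=config.schedules["inpatient_stays_by_age"],
        dietary_cost_by_age=config.schedules["dietary_cost_by_age"],
        discount_rate=config.discount_rate,
        recall_rate=config.screening["recall_rate"],
        cost_recall_exam=config.screening["cost_recall_exam"],
        cost_recall_test=config.screening["cost_recall_test"],
    )
    return ps


def base_case(config: ModelConfig) -> ParameterSet:
    """Deterministic parameter set: modes / midpoints / point values."""
    values = {f: config.distributions[f].base_value() for f in _SAMPLED_FIELDS}
    return _assemble(config, values)


def sample_distribution(spec: DistributionSpec, rng: np.random.Generator,
                        size: int | None = None):
    """Draw from a single input distribution (thin convenience wrapper)."""
    return spec.sample(rng, size)


def draw_parameter_set(config: ModelConfig, rng: np.random.Generator,
                       size: int | None = None) -> ParameterSet:
    """Independent joint draw of every distributed input (one PSA draw, or a
    batch of ``size`` draws as vectorised fields)."""
    values = {f: config.distributions[f].sample(rng, size) for f in _SAMPLED_FIELDS}
    return _assemble(config, values)


# ---------------------------------------------------------------------------
# Synthetic background-mortality life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx for integer ages 0..max_age-1."""

    qx: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.qx, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ConfigError("life table: every qx must lie in [0, 1]")
        object.__setattr__(self, "qx", q)

    @property
    def max_age(self) -> int:
        return len(self.qx)

    @property
    def e0(self) -> float:
        return life_expectancy(self.qx)


def life_expectancy(qx: np.ndarray) -> float:
    """Discrete life expectancy at birth under the cycle-start convention:
    each year of age x lived counts one year if alive at its start, so
    e0 = sum_x l(x) with l(0)=1 and l(x+1) = l(x)(1-qx).  All qx = 0 gives
    e0 = max_age exactly (the table's horizon bound)."""
    q = np.asarray(qx, dtype=float)
    l = np.concatenate([[1.0], np.cumprod(1.0 - q[:-1])])
    return float(l.sum())


def _qx_from_level(b: float, max_age: int, infant: float, slope: float) -> np.ndarray:
    ages = np.arange(max_age)
    hazard = b * np.exp(slope * ages)
    hazard[0] += infant
    return 1.0 - np.exp(-hazard)


def build_life_table(e0_target: float = 79.45, max_age: int = 110,
                     infant_hazard: float = 0.003,
                     gompertz_slope: float = 0.095) -> LifeTable:
    """Synthesise a period life table with a given life expectancy at birth.

    The hazard is an infant-mortality term at age 0 plus Gompertz adult
    aging ``b * exp(slope * age)``; the level ``b`` is calibrated by
    one-dimensional root finding so that the implied e0 equals
    ``e0_target``.  Raises if the target cannot be bracketed.
    """
    if not 0 < e0_target <= max_age:
        raise ConfigError(f"life table: e0 target {e0_target} not in (0, {max_age}]")

    def gap(log_b: float) -> float:
        qx = _qx_from_level(np.exp(log_b), max_age, infant_hazard, gompertz_slope)
        return life_expectancy(qx) - e0_target

    lo, hi = np.log(1e-10), np.log(0.5)
    if gap(lo) < 0 or gap(hi) > 0:
        raise ConfigError("life table: calibration failed to bracket the e0 target")
    log_b = brentq(gap, lo, hi, xtol=1e-12)
    return LifeTable(_qx_from_level(np.exp(log_b), max_age, infant_hazard, gompertz_slope))
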