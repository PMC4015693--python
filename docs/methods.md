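# Methods

## Model structure

The model is a discrete-time Markov cohort model with annual cycles.
A closed cohort of 100,000 newborns is tracked through five health
states: unaffected, undiagnosed GA-I, asymptomatic diagnosed GA-I
(which also covers milder movement disorders), impaired (severe
movement disorder, sMD), and dead. Two strategies are compared that
differ only in the starting distribution and in screening-related
costs:

- **Screening**: affected newborns are detected at birth with
  sensitivity 0.945 (triangular 0.90–0.99) and perfect post-confirmation
  specificity; detected cases start asymptomatic-diagnosed, false
  negatives start undiagnosed and follow the no-screening pathway.
- **No screening**: all affected newborns start undiagnosed.

### Manifestation window

Irreversible striatal injury in GA-I is essentially confined to the
first three years of life. The model therefore resolves all diagnostic
uncertainty uniformly over the three transitions into that window
(ages 0→1, 1→2, 2→3): at each of these transitions one third of the
original undiagnosed mass resolves (conditional fractions 1/3, 1/2, 1).
A resolving case is diagnosed early (macrocephaly / high-risk
screening) with probability 0.15, otherwise presents clinically after
an encephalopathic crisis. Early-diagnosed cases carry the sMD risk of
treated patients (0.115), clinical presenters the untreated risk
(0.74); each resolving tranche realises its outcome at the resolution
transition (a decision-tree step, exactly equivalent under zero
mortality to carrying a residual hazard for the rest of the window and
numerically indistinguishable at realistic infant mortality).
Screen-detected newborns carry their total risk 0.115 as an explicit
pending-risk sub-state converted uniformly over the same three
transitions, so the process stays Markovian. After age 3 no new
presentations occur; the undiagnosed state is empty by construction.

Under zero mortality the fraction of unscreened affected children
ending impaired is exactly 0.85·0.74 + 0.15·0.115 = 0.64625.

### Mortality

Background mortality comes from a synthetic period life table: hazard
= infant term (0.003 at age 0) + Gompertz aging b·exp(0.095·age), with
b calibrated by Brent root-finding so that discrete life expectancy at
birth equals 79.45 years. Life expectancy uses the same cycle-start
convention as the cohort accounting, e0 = Σ l(x) over ages
0..max_age−1 (an immortal table gives exactly the horizon bound).
The impaired state adds a constant annual excess death probability
1/le_impaired (base case 1/35, reproducing the assumed mean survival
of 35 years to first order), compounded with background mortality as
independent risks. Death is absorbing.

### Conventions

No half-cycle correction. Person-years, costs and discounting use the
cycle-start convention: occupancy at the start of cycle t counts one
person-year at discount factor (1+r)^−t (cycle 0 factor 1, r = 3%/y).
Event costs (crisis diagnosis, early-diagnosis confirmation) attach to
the destination cycle of the transition that produced the event. A
horizon of H years accrues cycles 0..H−1.

## Costs (2010 EUR, provider perspective)

- Marginal screening cost 0.031 EUR per neonate, paid once at cycle 0
  in the screening arm. It is the recall-based construction
  0.0008 × (31.01 + 7.00) = 0.0304 rounded up: adding C5DC to an
  existing MS/MS panel costs only the additional recalls.
- Confirmation 865 EUR (= 25 metabolite + 800 mutation + 0.05 × 800
  enzyme) per screen-positive at cycle 0 and per early (non-crisis)
  diagnosis; clinical presenters instead incur the 3,000 EUR
  (triangular 2,000–8,000) crisis-diagnosis bundle, which already
  includes confirmation — this applies to every presentation event
  whether or not sMD follows.
- Every diagnosed-alive person-year accrues guideline treatment:
  outpatient visits × 127 EUR, inpatient stays × 1,335 EUR, plus the
  annual dietary cost, all on age-dependent schedules. The same visit
  frequencies apply to asymptomatic and impaired patients.
- Impaired person-years additionally accrue special schooling
  (5,689 EUR/y, integer ages 6–16 inclusive), special care
  (2,700 EUR/y, ages 7 and above — "after age 6"), and an overhead
  lump sum (uniform 0–3,000 EUR/y).

**Placeholder schedules.** The visit counts and the dietary cost are
published only as "age-depending". The packaged defaults — outpatient
4/y to age 6 then 2/y; inpatient 1/y then 0.2/y; diet 3,000 EUR/y
through age 6 (lysine-free amino-acid supplements covering ~40% of
intake, plus high-dose levocarnitine) then 300 EUR/y (maintenance
carnitine) — are guideline-informed stand-ins. Levocarnitine dosing is
folded into the dietary schedule rather than modelled with body-weight
curves. **All absolute money totals (incremental cost, break-even
screening cost, grid cells) are schedule-dependent**; the qualitative
results (dominance, affine structure) are not.

## Effectiveness

DALYs averted are computed as within-horizon discounted person-year
differences: the mortality component is the between-arm difference in
discounted person-years alive (weight 1), the morbidity component the
disability-weighted (0.471, uniform 0.443–0.471 in the PSA) discounted
impaired person-years. No age weighting. This construction makes the
DALY figure grow with the horizon, which is the behaviour a
within-horizon measure must have; see Limitations. Life years gained
are discounted by default (a toggle reports them undiscounted).

## Parameter distributions and base case

Uncertain inputs are point / triangular / uniform per the published
input table. The deterministic base case uses the mode for triangular,
the midpoint for uniform (impaired life expectancy 25–45 → 35, the
stated mean; overhead → 1,500), and two documented exceptions: the
disability weight uses its published point value 0.471 rather than the
range midpoint. Prevalence is sampled on the probability scale
(triangular over 1/129,455 – 1/112,700 – 1/95,953). PSA draws are
mutually independent across parameters. Point estimates (specificity
1.0, healthy life expectancy, the per-neonate screening fee) are held
fixed in the PSA.

## Sensitivity machinery

- **PSA**: all distributed inputs drawn jointly for n repetitions up
  front (results independent of the evaluation chunk size), evaluated
  vectorised through both arms; summaries are empirical means and
  2.5/97.5 percentiles (percentile rather than normal intervals, since
  cost outcomes are skewed). 50,000 draws at both horizons run in a few
  seconds.
- **Threshold analysis**: the incremental cost is exactly affine in the
  per-neonate screening cost with slope = cohort size (the fee is paid
  once, at cycle 0, undiscounted), so one PSA at zero screening cost
  determines the whole ICER-vs-cost curve; the break-even cost is the
  affine root of the mean incremental cost. A bisection on full model
  evaluations agrees to 1e-6 (tested).
- **Prevalence grid**: the prevalence triangular is re-centred
  multiplicatively (mode → grid value, preserving relative
  uncertainty); each prevalence uses an independent substream keyed on
  (seed, value), so the grid is invariant to evaluation order. ICER
  intervals are percentile intervals of per-draw ratios over draws with
  positive DALY denominators.
- **One-way analysis**: three full evaluations (min / base / max) with
  all other inputs at base case; point estimates raise a "no range to
  vary" error.

## Validation

An individual-level microsimulation with the identical hazards serves
as an independent oracle: at one million simulated newborns the cohort
occupancies agree at the 3σ level at ages 5, 20 and 70 (rare states,
expected counts < 30, are judged by the exact binomial test at the
matching significance, where the normal ±3 SE band misstates the
tail). Further invariants under test: occupancy conservation to 1e-12,
absorbing death, screening never increasing cumulative sMD onsets,
the zero-prevalence and equal-risk nulls, the DALY ≡ life-year
identity at disability weight 0, discount monotonicity, and
Kolmogorov–Smirnov calibration of the triangular sampler (< 0.01 at
1e5 draws).

## Problem sizes

Default analyses use the full study conditions: cohort 100,000, PSA
50,000 repetitions, horizons 20 and 70 years, life table to age 110.
The microsimulation check uses 1e6 individuals per draw.

## Known limitations

- The within-horizon DALY construction cannot reproduce one feature of
  the published effectiveness table: there the morbidity component
  (DALYs averted minus life years gained) *shrinks* from the 20-year to
  the 70-year horizon, whereas any accounting in which the screened arm
  has weakly fewer impaired person-years in every cycle — a property
  this model provably has, and tests enforce — yields a morbidity
  component that is non-decreasing in the horizon. The model therefore
  reports a larger 70-year DALY figure than the published one; the
  20-year figures and all qualitative conclusions (dominance, orders of
  magnitude) agree.
- What passing tests show is internal consistency and agreement with
  the stated inputs under the synthetic life table and placeholder
  schedules — not validity of the clinical assumptions themselves,
  which rest on small historical cohorts.
- No modelling of crisis recurrence, genotype strata, adult-onset
  presentation, treatment non-adherence beyond the 11.5% figure, QALYs,
  inflation/currency adjustment, or societal costs.
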