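# Methods

## Model

All three indicators (near miss, maternal death, severe maternal outcome)
are synthetic-cohort period measures: the age-specific ratios, fertility
rates and survivorship observed in one calendar year are treated as if a
cohort of girls lived through them. The lifetime risk conditional on
survival to age 15 is the sum over five-year age groups of

    ratio(x, n) * f(x, n) * L(x, n) / l(15)

The product `ratio * f` converts an events-per-live-birth ratio into an
events-per-woman-year rate, and `L(x,n)/l(15)` is the expected years lived
in the interval by a girl who reached 15, so each term is an expected event
count and the sum a cumulative probability (valid while small; the package
rejects values ≥ 1 as a unit error). Equivalent entry points exist for an
event-rate schedule directly (`ltr_from_rate`) and for a single aggregate
ratio with either the fertility–survival sum (`ltr_summary`) or the
published-aggregate shortcut `ratio * NRR * (SRB/100 + 1) * l0/l15`
(`ltr_summary_nrr`). The two summary forms are algebraically identical when
the NRR is computed from the same fertility schedule and life table with an
age-constant sex ratio at birth; the test suite verifies this to 1e-9
relative on 500 synthetic bundles.

Assumptions inherited from the synthetic-cohort design:

- rates are constant within each five-year interval and over the period;
- no parity-specific risk: fertility captures repeated exposure, but a
  prior near miss does not alter a woman's subsequent near-miss, fertility
  or mortality schedules (a population-average reading);
- severe maternal outcome is the plain sum of the near-miss and death
  risks — no competing-risk correction between the two, consistent with
  counting both event types over the same births.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| morbidity ratio | events per live birth (per-1000/per-100 000 accepted on input) | — | the measured quantity |
| fertility f(x,n) | live births per woman-year (per-1000 accepted) | — | repeated exposure |
| L(x,n), l(15), l0 | person-years, persons | radix 100 000 | survival conditioning |
| NRR | daughters per woman | — | summary shortcut only |
| SRB | boys per 100 girls | 105 where unstated | daughters-to-all-births factor SRB/100 + 1 |
| stillbirth rate | per 1000 total births | — | total births → live births, multiply by (1 − SBR/1000) |
| institutional delivery rate | proportion in (0, 1] | — | multiplies a facility ratio (denominator inflation); a warning is emitted below 0.5 |

Unit normalisation happens exactly once, at construction/read time; all
internal values are pure proportions. Age grids must match exactly
(strict (start, length) equality); no re-binning is attempted because silent
re-aggregation would corrupt the age-specific route.

## Age-pattern simulator

Age-disaggregated near-miss data are rare, so the simulator builds ratio
schedules `c * profile(g)` under six qualitative shape families and solves
for `c` so the birth-weighted aggregate hits the requested target exactly.
Integer case columns are produced by largest-remainder apportionment of the
expected counts (ties to younger ages), conserving the rounded total; the
count-based aggregate therefore matches the target to within half an event.
The default profiles are fixed relative-risk vectors: the J-shape is the
Namibia 2019 observed pattern (elevated adolescent risk, minimum at 20–24,
rising thereafter, as relative risks {1.885, 1.0, 1.291, 2.465, 2.674,
3.346, 3.956}); the U-, N-, increasing and decreasing families are
stylised monotone/unimodal vectors with roughly four-fold range, chosen as
plausible against what is known about maternal-death risk by age. Shape
calibration is deterministic — nothing about a sweep depends on a seed.

The synthetic bundle generator (`make_synthetic_bundle`) emulates the study
conditions of a southern-African setting: survival to 15 near 0.95,
five-year death probabilities rising from 0.006 to 0.045 across the
reproductive ages, total fertility 3.41, aggregate ratio 8.03 per 1000,
SRB 101, with lognormal jitter (5% coefficient of variation) on the age
patterns from a single seeded generator. It produces internally consistent
bundles (the stored NRR is recomputed from the generated schedules). What it
does **not** emulate: correlation between mortality and fertility levels,
within-woman event clustering, reporting error in surveillance counts, or
migration. Passing tests on these bundles therefore demonstrate the
estimators' algebraic correctness and calibration under ideal sampling, not
robustness to real surveillance artefacts.

The `namibia2019` preset is not generated: it is the embedded published
table, byte-identical to the printed columns. Two reconciliations are worth
knowing. First, the published per-age ratio column agrees with the published
integer case and birth columns only to within one event per group (the
source evidently printed pre-rounding simulated ratios); the fixture stores
the printed ratios verbatim and the schedule type tolerates exactly that
one-event slack between counts and ratios. Second, the published NRR (1.554)
derives from unrounded source inputs; recomputing it from the rounded
printed schedule gives 1.558. The fixture carries the published 1.554 as the
shortcut input, and the recomputed value is asserted separately. For the
same reason the published lifetime risk of maternal death (0.00702, "1 in
142") is treated as a printed *input* when composing the severe-outcome
risk: recomputing it from the rounded mortality ratio (223 per 100 000)
gives ≈ 0.0073, and the unrounded inputs behind the published figure are not
recoverable.

The fixture's life-table survivor column is published only at age 15; the
other `l(x)` entries are reconstructed through the trapezoidal identity
`L(x,5) = 2.5 (l(x) + l(x+5))` purely to satisfy the container's
monotonicity invariants — only `l(15)` and `L(x,n)` enter any result.

## Uncertainty

Counts are modelled as independent Poisson across age groups. The
frequentist interval on a count is the exact Garwood (chi-square inversion)
interval — appropriate because per-group counts can be small (11 events in
the oldest Namibia group) — and the 80% "uncertainty interval" convention is
the 10th/90th percentile pair of a Gamma(k + 1/2) posterior (Jeffreys
prior); the latter is a percentile-reporting convention, not a fitted
Bayesian model. Summary-route risks are linear and increasing in the ratio,
so interval endpoints map through the estimator exactly; age-specific risks
propagate jointly by a seeded parametric bootstrap (default 10 000 draws)
over independent Poisson counts with equal-tailed quantiles. Bootstrap
quantiles are clamped to bracket the analytic point estimate in degenerate
tiny-count cases. Independence across groups and across repeat events within
a woman is an acknowledged simplification: a near miss is a potentially
repeating, non-independent event, and these intervals do not reflect that
clustering.

## Numerical choices

- Internal consistency checks use relative tolerance 1e-9; risks are kept
  unrounded internally, with rounding (4 d.p. for risks, 2 d.p. for ratios
  and survival weights) applied only at presentation.
- "1 in n" uses nearest-integer rounding of the reciprocal — the only rule
  consistent with every published rendering this package reproduces
  (0.0282→35, 0.0263→38, 0.0333→30, 0.00702→142).
- Largest-remainder ties break toward younger ages, making case allocation
  deterministic.
- Degenerate inputs fail loudly: `l(15) = 0`, grids that do not match,
  negative rates, ratios implying a risk ≥ 1, shape profiles violating their
  family's monotonicity each raise a named error.

## Problem sizes

The test suite and the acceptance script run at desk scale: the worked
example is seven age groups; property checks use 500 synthetic bundles,
1000-replicate coverage simulations and 10 000–40 000 bootstrap draws, which
keeps the full suite within a few minutes on one CPU while leaving
Monte-Carlo tolerances (coverage ≥ 93% for nominal 95%, two significant
figures for propagation consistency) comfortably wide of their thresholds.

## Known limitations

- A period measure: not a forecast for any real cohort.
- Heterogeneity (elevated post-near-miss mortality, altered subsequent
  fertility) can bias the population-average risk in either direction.
- Facility-based ratios adjusted by the institutional delivery rate can
  remain overestimates when the data derive from tertiary facilities only;
  the adjustment warns below a 0.5 delivery rate.
- The summary route is a lower bound whenever the true ratio rises with age,
  as the sensitivity sweep illustrates.
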