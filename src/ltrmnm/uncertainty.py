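"""Facility-to-population adjustment and uncertainty intervals.

Event counts per age group are modelled as independent Poisson variables.
Near-miss counts can be small (the Namibia 45-49 group has 11 cases), so the
frequentist interval on a count is the exact Poisson (Garwood) interval
rather than a normal approximation.  The 80% "uncertainty interval"
convention reports the 10th/90th percentiles of a Gamma posterior under the
Jeffreys prior on each count; it is a percentile-reporting convention, not a
full Bayesian model of the surveillance process.

Because every lifetime-risk estimator is linear and monotone in the
morbidity ratio(s), summary-route intervals propagate exactly by evaluating
the estimator at the ratio bounds.  Age-specific intervals propagate the
joint uncertainty by Monte Carlo over independent Poisson counts.

Independence of counts across age groups (and across repeat events within a
woman) is an assumption: a near miss is a potentially repeating,
non-independent event, so these intervals understate clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .demog import (
    AbridgedLifeTable,
    FertilitySchedule,
    MorbiditySchedule,
    survival_weights,
)
from .errors import InputError, UsageError
from .indicators import ltr_age_specific, ltr_summary

__all__ = [
    "IntervalEstimate",
    "facility_adjust",
    "ratio_interval",
    "ltr_interval_summary",
    "ltr_interval_age_specific",
    "ltr_interval",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with lower/upper bounds at a stated coverage level."""

    point: float
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise InputError("coverage level must lie in (0, 1)")
        if not self.lower <= self.point <= self.upper:
            raise InputError(
                f"interval bounds must bracket the point: {self.lower} <= {self.point} <= {self.upper}"
            )


def facility_adjust(facility_ratio: float, institutional_delivery_rate: float) -> float:
    """Adjust a facility-based ratio to the whole community.

    A woman with a true near miss would most likely have died without
    facility care, so the facility case count approximates the community
    numerator; the denominator, facility live births, undercounts community
    births by the institutional delivery rate.  Dividing the denominator by
    that rate is equivalent to multiplying the ratio by it.
    """
    if not 0 < institutional_delivery_rate <= 1:
        raise InputError("institutional delivery rate must lie in (0, 1]")
    if facility_ratio < 0:
        raise InputError("facility ratio must be non-negative")
    if institutional_delivery_rate < 0.5:
        warnings.warn(
            "institutional delivery rate below 0.5: facility births undercount "
            "community births severely (often tertiary-only data) and the "
            "adjusted ratio may remain an overestimate",
            stacklevel=2,
        )
    return facility_ratio * institutional_delivery_rate


def ratio_interval(
    cases: float,
    live_births: float,
    level: float = 0.95,
    method: str = "garwood",
) -> IntervalEstimate:
    """Interval for an event ratio from a single Poisson count.

    ``method="garwood"`` gives the exact (chi-square inversion) Poisson
    interval; ``method="jeffreys"`` gives equal-tailed Gamma(k + 1/2)
    posterior percentiles.  With zero cases the lower bound is exactly 0.
    """
    if live_births <= 0:
        raise InputError("live births must be positive")
    if cases < 0:
        raise InputError("case count must be non-negative")
    if not 0 < level < 1:
        raise InputError("coverage level must lie in (0, 1)")
    alpha = 1.0 - level
    if method == "garwood":
        lo = 0.0 if cases == 0 else stats.chi2.ppf(alpha / 2, 2 * cases) / 2.0
        hi = stats.chi2.ppf(1 - alpha / 2, 2 * cases + 2) / 2.0
    elif method == "jeffreys":
        post = stats.gamma(cases + 0.5)
        lo = 0.0 if cases == 0 else float(post.ppf(alpha / 2))
        hi = float(post.ppf(1 - alpha / 2))
    else:
        raise InputError(f"unknown interval method {method!r}; use 'garwood' or 'jeffreys'")
    return IntervalEstimate(
        point=cases / live_births,
        lower=lo / live_births,
        upper=hi / live_births,
        level=level,
        method=method,
    )


def ltr_interval_summary(
    ratio_iv: IntervalEstimate,
    fert: FertilitySchedule,
    lt: AbridgedLifeTable,
    event_kind: str = "mnm",
) -> IntervalEstimate:
    """Propagate a ratio interval through the summary estimator.

    Exact, because the summary-route risk is linear and increasing in the
    aggregate ratio: each bound maps to the risk at that bound.
    """
    vals = [
        ltr_summary(r, fert, lt, event_kind).value
        for r in (ratio_iv.point, ratio_iv.lower, ratio_iv.upper)
    ]
    return IntervalEstimate(vals[0], vals[1], vals[2], ratio_iv.level, ratio_iv.method)


def ltr_interval_age_specific(
    morb: MorbiditySchedule,
    fert: FertilitySchedule,
    lt: AbridgedLifeTable,
    level: float = 0.95,
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> IntervalEstimate:
    """Joint interval for the age-specific risk by parametric bootstrap.

    Each age group's case count is resampled as Poisson with mean equal to
    the observed count (independently across groups); the risk is recomputed
    for every draw and equal-tailed percentiles at ``level`` are reported.
    """
    if morb.cases is None or morb.live_births is None:
        raise UsageError("age-specific intervals need case and live-birth counts")
    if n_draws < 100:
        raise InputError("use at least 100 Monte Carlo draws")
    if not 0 < level < 1:
        raise InputError("coverage level must lie in (0, 1)")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    point = ltr_age_specific(morb, fert, lt)
    w = fert.rates * survival_weights(lt)  # risk per (ratio unit) per group
    draws = rng.poisson(morb.cases, size=(n_draws, len(morb.cases)))
    values = (draws / morb.live_births) @ w
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    # Monte Carlo quantiles can sit on either side of the analytic point in
    # pathological tiny-count cases; clamp so the invariant holds.
    return IntervalEstimate(
        point=point.value,
        lower=min(float(lo), point.value),
        upper=max(float(hi), point.value),
        level=level,
        method="poisson_mc",
    )


def ltr_interval(
    route: str,
    *,
    ratio_iv: IntervalEstimate | None = None,
    morb: MorbiditySchedule | None = None,
    fert: FertilitySchedule,
    lt: AbridgedLifeTable,
    level: float = 0.95,
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = None,
    event_kind: str = "mnm",
) -> IntervalEstimate:
    """Dispatch to the summary or age-specific interval for the chosen route."""
    if route == "summary":
        if ratio_iv is None:
            raise UsageError("summary-route intervals need a ratio interval")
        return ltr_interval_summary(ratio_iv, fert, lt, event_kind)
    if route == "age_specific":
        if morb is None:
            raise UsageError("age-specific intervals need a morbidity schedule")
        return ltr_interval_age_specific(morb, fert, lt, level, n_draws, rng)
    raise UsageError(f"no interval propagation defined for route {route!r}")
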