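"""Lifetime-risk estimators.

Each estimator answers the same question for a synthetic period cohort: what
is the probability that a girl who survives to her 15th birthday experiences
the event (a maternal near miss, a maternal death, or either) before the end
of her 49th year, given current age-specific fertility and all-cause female
mortality?

Three routes are provided:

* **age-specific** — the ratio schedule is age-disaggregated:
  ``LTR = sum_g ratio(g) * f(g) * L(g)/l(15)``.
* **summary** — a single aggregate ratio for ages 15-49, assumed constant
  over age: ``LTR = ratio * sum_g f(g) * L(g)/l(15)``.
* **summary via NRR** — the same, with the fertility-survival sum replaced by
  published aggregates: ``LTR = ratio * NRR * (SRB/100 + 1) * l0/l15``.

All three are linear and monotone in the morbidity ratio(s), which is what
makes interval propagation in :mod:`ltrmnm.uncertainty` exact for the summary
routes.
"""

from __future__ import annotations

import numpy as np

from .demog import (
    AbridgedLifeTable,
    FertilitySchedule,
    LifetimeRisk,
    MorbiditySchedule,
    SummaryInputs,
    survival_weights,
)
from .errors import InputError, UsageError

__all__ = [
    "ltr_age_specific",
    "ltr_from_rate",
    "ltr_summary",
    "ltr_summary_nrr",
    "srb_scaling_factor",
    "ltr_smo",
    "morbidity_share",
    "one_in_n",
]


def ltr_age_specific(
    morb: MorbiditySchedule, fert: FertilitySchedule, lt: AbridgedLifeTable
) -> LifetimeRisk:
    """Age-disaggregated lifetime risk.

    Each group contributes ``ratio(g) * f(g) * L(g)/l(15)``; the risk is the
    sum.  Works identically for near-miss and maternal-death ratio schedules
    (the result's ``event_kind`` follows the input schedule's label).
    """
    rlt = lt.reproductive_slice()
    morb.grid.require_same(rlt.grid, "morbidity schedule and life table")
    fert.grid.require_same(rlt.grid, "fertility schedule and life table")
    contrib = morb.ratio * fert.rates * survival_weights(rlt)
    return LifetimeRisk(
        value=float(contrib.sum()),
        route="age_specific",
        event_kind=morb.event_kind,
        per_age_contributions=contrib,
        grid=rlt.grid,
    )


def ltr_from_rate(
    rates: np.ndarray | list[float],
    lt: AbridgedLifeTable,
    event_kind: str = "mnm",
) -> LifetimeRisk:
    """Lifetime risk from an event *rate* schedule (events per woman-year).

    ``LTR = sum_g rate(g) * L(g)/l(15)``.  Equals :func:`ltr_age_specific`
    when ``rate(g) = ratio(g) * f(g)``, since the ratio-times-fertility
    product is exactly the event rate per woman-year.
    """
    rlt = lt.reproductive_slice()
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (len(rlt.grid),):
        raise InputError("rate schedule needs one rate per reproductive age group")
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise InputError("event rates must be finite and non-negative")
    contrib = rates * survival_weights(rlt)
    return LifetimeRisk(
        value=float(contrib.sum()),
        route="age_specific",
        event_kind=event_kind,  # type: ignore[arg-type]
        per_age_contributions=contrib,
        grid=rlt.grid,
    )


def ltr_summary(
    aggregate_ratio: float,
    fert: FertilitySchedule,
    lt: AbridgedLifeTable,
    event_kind: str = "mnm",
) -> LifetimeRisk:
    """Summary-route lifetime risk, assuming the ratio is constant over age.

    ``LTR = aggregate_ratio * sum_g f(g) * L(g)/l(15)``.
    """
    if aggregate_ratio < 0:
        raise InputError("aggregate ratio must be non-negative")
    rlt = lt.reproductive_slice()
    fert.grid.require_same(rlt.grid, "fertility schedule and life table")
    value = aggregate_ratio * float((fert.rates * survival_weights(rlt)).sum())
    return LifetimeRisk(value=value, route="summary", event_kind=event_kind)  # type: ignore[arg-type]


def srb_scaling_factor(srb: float) -> float:
    """Convert daughters-only reproduction to all births: ``SRB/100 + 1``.

    101 boys per 100 girls gives 2.01; the typical 105 gives 2.05.
    """
    if srb <= 0:
        raise InputError("SRB must be positive (boys per 100 girls)")
    return srb / 100.0 + 1.0


def ltr_summary_nrr(s: SummaryInputs, event_kind: str = "mnm") -> LifetimeRisk:
    """Summary route from published aggregates only.

    ``LTR = ratio * NRR * (SRB/100 + 1) * l0/l15``.  The NRR counts daughters
    per woman, so the SRB factor restores births of both sexes, and ``l0/l15``
    removes the life table's pre-age-15 mortality to condition on survival to
    15.  Algebraically identical to :func:`ltr_summary` whenever the NRR is
    computed from the same fertility schedule and life table.
    """
    value = (
        s.aggregate_ratio * s.nrr * srb_scaling_factor(s.srb) * s.l0 / s.l15
    )
    return LifetimeRisk(value=value, route="summary_nrr", event_kind=event_kind)  # type: ignore[arg-type]


def ltr_smo(ltr_md: LifetimeRisk, ltr_mnm: LifetimeRisk) -> LifetimeRisk:
    """Lifetime risk of severe maternal outcome: plain sum of the two risks.

    No competing-risk correction is applied between near misses and deaths;
    the severe-maternal-outcome definition is the union of the two event
    counts over the same births, so the ratio schedules — and hence the
    risks — add.
    """
    kinds = {ltr_md.event_kind, ltr_mnm.event_kind}
    if kinds != {"maternal_death", "mnm"}:
        raise UsageError(
            f"severe maternal outcome combines a maternal_death risk with an mnm risk, got {sorted(kinds)}"
        )
    md = ltr_md if ltr_md.event_kind == "maternal_death" else ltr_mnm
    nm = ltr_mnm if md is ltr_md else ltr_md
    both_age_specific = (
        md.route == nm.route == "age_specific"
        and md.per_age_contributions.size == nm.per_age_contributions.size
    )
    if both_age_specific:
        return LifetimeRisk(
            value=md.value + nm.value,
            route="age_specific",
            event_kind="smo",
            per_age_contributions=md.per_age_contributions + nm.per_age_contributions,
            grid=md.grid,
        )
    # mixed or summary routes carry no per-age decomposition
    route = md.route if md.route == nm.route and md.route != "age_specific" else "summary"
    return LifetimeRisk(value=md.value + nm.value, route=route, event_kind="smo")


def morbidity_share(ltr_mnm: LifetimeRisk, ltr_smo: LifetimeRisk) -> float:
    """Percentage of the severe-outcome risk attributable to morbidity."""
    if ltr_smo.value <= 0:
        raise InputError("severe-outcome risk must be positive to take a share")
    return 100.0 * ltr_mnm.value / ltr_smo.value


def one_in_n(value: float) -> tuple[int, str]:
    """Express a probability as a '1 in n' risk, n rounded to nearest integer."""
    if not 0 < value < 1:
        raise InputError(f"'1 in n' requires a probability strictly in (0, 1), got {value}")
    n = int(round(1.0 / value))
    return n, f"1 in {n}"
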