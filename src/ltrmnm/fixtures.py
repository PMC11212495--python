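"""The Namibia 2019 worked example, embedded as a fixture.

Sources of the numbers: a 2019 national near-miss surveillance study (cases
and live births by five-year maternal age group, under the J-shaped age
profile) and the UN World Population Prospects 2019 revision for Namibia
(age-specific fertility, person-years lived, survivors to age 15, net
reproduction rate, sex ratio at birth, maternal mortality ratio).

The life table's survivor column ``l(x)`` is only published at exact age 15;
the remaining entries here are a *synthetic* reconstruction from the
published person-years via the trapezoidal identity
``L(x,5) = 2.5 * (l(x) + l(x+5))``, which preserves monotone survivorship and
the type invariants.  Only ``l(15)`` and ``L(x,n)`` enter any lifetime-risk
computation, so the reconstruction never affects results.
"""

from __future__ import annotations

import numpy as np

from .demog import (
    AbridgedLifeTable,
    AgeGrid,
    FertilitySchedule,
    MorbiditySchedule,
)
from .errors import InputError

NAMIBIA_2019 = {
    "age_start": [15, 20, 25, 30, 35, 40, 45],
    "mnm_cases": [68, 82, 107, 143, 91, 44, 11],
    "live_births": [7939, 18050, 18241, 12772, 7492, 2895, 612],
    # published ratio column; agrees with cases/live_births only to within one
    # event per group (the source's simulated ratios pre-date integer rounding)
    "mnm_ratio_per_1000": [8.57, 4.57, 5.86, 11.19, 12.19, 15.06, 17.57],
    "asfr_per_1000": [66.9, 154.3, 160.0, 140.9, 103.9, 45.6, 11.2],
    "Lx": [474931.6, 470667.4, 464275.4, 455466.6, 443928.0, 429401.3, 411688.2],
    "l15": 95283.0,
    "radix": 100000.0,
    "nrr": 1.554,  # published WPP value (recomputing from the rounded schedule gives ~1.558)
    "srb": 101.0,  # boys per 100 girls
    "stillbirth_rate_per_1000": 17.68,
    "mm_ratio_per_100000": 223.0,  # maternal deaths per 100 000 live births
    "summary_mnm_ratio_per_1000": 8.03,
}


def _trapezoid_lx(l15: float, Lx: np.ndarray) -> tuple[np.ndarray, float]:
    """Reconstruct survivors at each group start from L(x,5) = 2.5*(l(x)+l(x+5))."""
    lx = [l15]
    for L in Lx:
        lx.append(2.0 * L / 5.0 - lx[-1])
    return np.asarray(lx[:-1]), lx[-1]


def namibia_2019_life_table() -> AbridgedLifeTable:
    d = NAMIBIA_2019
    Lx = np.asarray(d["Lx"], dtype=float)
    lx, lx_end = _trapezoid_lx(d["l15"], Lx)
    return AbridgedLifeTable(AgeGrid.reproductive(), lx, Lx, d["radix"], lx_end)


def namibia_2019_fertility() -> FertilitySchedule:
    return FertilitySchedule.from_rates(NAMIBIA_2019["asfr_per_1000"], units="per_1000")


def namibia_2019_morbidity() -> MorbiditySchedule:
    d = NAMIBIA_2019
    return MorbiditySchedule(
        AgeGrid.reproductive(),
        ratio=np.asarray(d["mnm_ratio_per_1000"]) / 1000.0,
        cases=np.asarray(d["mnm_cases"], dtype=float),
        live_births=np.asarray(d["live_births"], dtype=float),
        event_kind="mnm",
    )


def load_fixture(name: str):
    """Return the named built-in input bundle.

    Currently only ``"namibia2019"`` exists: the complete worked example
    (546 near misses over 68 001 live births, aggregate ratio 8.03 per 1000).
    """
    from .age_patterns import SyntheticBundle

    if name != "namibia2019":
        raise InputError(f"unknown fixture {name!r}; available fixtures: ['namibia2019']")
    d = NAMIBIA_2019
    return SyntheticBundle(
        life_table=namibia_2019_life_table(),
        fertility=namibia_2019_fertility(),
        morbidity=namibia_2019_morbidity(),
        srb=d["srb"],
        nrr=d["nrr"],
        seed=None,
    )
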