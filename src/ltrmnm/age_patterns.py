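"""Age patterns of the near-miss ratio, and the synthetic-data engine.

Age-disaggregated near-miss data are rarely available; what is usually
published is a single aggregate ratio for ages 15-49.  This module builds
plausible age-disaggregated schedules that are *exactly* consistent with a
given aggregate ratio, under one of six qualitative shape families
(J-shaped, U-shaped, N-shaped, constant, increasing, decreasing), and sweeps
the lifetime risk across all of them to show how sensitive the indicator is
to the assumed age pattern.

It also houses the stillbirth adjustment (total births -> live births) and a
generator of fully consistent synthetic input bundles (life table +
fertility + morbidity + sex ratio at birth) used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demog import (
    AbridgedLifeTable,
    AgeGrid,
    FertilitySchedule,
    MorbiditySchedule,
    nrr_from_schedules,
)
from .errors import InputError
from .indicators import ltr_age_specific, one_in_n

FAMILY_NAMES = ("j_shape", "u_shape", "n_shape", "constant", "increasing", "decreasing")

# Relative-risk multipliers on the 7-group reproductive grid.  The shapes are
# qualitative families; these defaults are fixed, documented vectors.  The
# J-shape default is the Namibia 2019 observed pattern (elevated adolescent
# risk, minimum at 20-24, rising with age thereafter), expressed as relative
# risks; the others are symmetric stylisations of their family.
DEFAULT_PROFILES: dict[str, tuple[float, ...]] = {
    "j_shape": (1.885, 1.0, 1.291, 2.465, 2.674, 3.346, 3.956),
    "u_shape": (2.2, 1.2, 1.0, 1.1, 1.4, 1.8, 2.4),
    "n_shape": (0.7, 1.1, 1.5, 1.8, 1.5, 1.1, 0.7),
    "constant": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    "increasing": (1.0, 1.3, 1.7, 2.2, 2.8, 3.5, 4.3),
    "decreasing": (4.3, 3.5, 2.8, 2.2, 1.7, 1.3, 1.0),
}


def _check_shape(name: str, p: np.ndarray) -> None:
    d = np.diff(p)
    if name == "constant":
        ok = np.allclose(p, p[0])
    elif name == "increasing":
        ok = np.all(d > 0)
    elif name == "decreasing":
        ok = np.all(d < 0)
    elif name == "j_shape":
        # elevated at 15-19, minimum at 20-24, strictly increasing thereafter
        ok = p[0] > p[1] and np.argmin(p) == 1 and np.all(d[1:] > 0)
    elif name == "u_shape":
        i = int(np.argmin(p))
        ok = 0 < i < len(p) - 1 and np.all(d[:i] < 0) and np.all(d[i:] > 0)
    elif name == "n_shape":
        i = int(np.argmax(p))
        ok = 0 < i < len(p) - 1 and np.all(d[:i] > 0) and np.all(d[i:] < 0)
    else:
        raise InputError(f"unknown shape family {name!r}; known: {list(FAMILY_NAMES)}")
    if not ok:
        raise InputError(f"profile {p.tolist()} does not satisfy the {name!r} shape invariants")


@dataclass(frozen=True)
class ShapeFamily:
    """A named qualitative age pattern with its relative-risk profile."""

    name: str
    profile: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=float)
        if p.shape != (7,):
            raise InputError("shape profiles are defined on the 7-group reproductive grid")
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            raise InputError("shape profile multipliers must be positive and finite")
        _check_shape(self.name, p)

    @classmethod
    def default(cls, name: str) -> "ShapeFamily":
        if name not in DEFAULT_PROFILES:
            raise InputError(f"unknown shape family {name!r}; known: {list(FAMILY_NAMES)}")
        return cls(name, DEFAULT_PROFILES[name])


def default_families() -> list[ShapeFamily]:
    return [ShapeFamily.default(n) for n in FAMILY_NAMES]


def stillbirth_adjust(births, sbr: float) -> np.ndarray:
    """Convert total births to live births given a stillbirth rate.

    ``sbr`` is stillbirths per 1000 *total* births, so live births are
    ``births * (1 - sbr/1000)``, rounded half-up to whole births per group.
    """
    if not 0 <= sbr < 1000:
        raise InputError("stillbirth rate must lie in [0, 1000) per 1000 total births")
    births = np.asarray(births, dtype=float)
    if np.any(births < 0):
        raise InputError("birth counts must be non-negative")
    return np.floor(births * (1.0 - sbr / 1000.0) + 0.5)


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment conserving the total; ties go to younger ages."""
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    # stable sort on descending remainder => earlier (younger) group wins ties
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def ratios_from_shape(
    family: ShapeFamily,
    live_births,
    target_aggregate: float,
    event_kind: str = "mnm",
) -> MorbiditySchedule:
    """Build an age-disaggregated schedule matching an aggregate ratio exactly.

    The ratio column is ``c * profile(g)`` with the scalar ``c`` chosen so the
    birth-weighted aggregate equals ``target_aggregate`` (events per 1000 live
    births) exactly, pre-rounding.  The case column is the integer
    apportionment (largest remainder) of the implied expected counts, summing
    to ``round(target/1000 * total births)``.
    """
    births = np.asarray(live_births, dtype=float)
    if births.shape != (7,) or np.any(births <= 0):
        raise InputError("live births must be positive for each of the 7 reproductive groups")
    if target_aggregate <= 0:
        raise InputError("target aggregate ratio must be positive (per 1000 live births)")
    p = np.asarray(family.profile, dtype=float)
    c = (target_aggregate / 1000.0) * births.sum() / (p * births).sum()
    ratios = c * p
    expected = ratios * births
    total_cases = int(np.floor(target_aggregate / 1000.0 * births.sum() + 0.5))
    quotas = expected * (total_cases / expected.sum())
    cases = _largest_remainder(quotas, total_cases)
    return MorbiditySchedule(
        AgeGrid.reproductive(), ratios, cases.astype(float), births, event_kind  # type: ignore[arg-type]
    )


def sensitivity_sweep(
    families: list[ShapeFamily],
    fert: FertilitySchedule,
    lt: AbridgedLifeTable,
    live_births,
    target_aggregate: float,
) -> pd.DataFrame:
    """Lifetime risk under every assumed age pattern of the ratio.

    Returns one row per family with the risk and its '1 in n' rendering, plus
    a ``band`` entry in ``DataFrame.attrs`` summarising the min/max n.
    """
    rows = []
    for fam in families:
        morb = ratios_from_shape(fam, live_births, target_aggregate)
        ltr = ltr_age_specific(morb, fert, lt)
        n, rendered = one_in_n(ltr.value)
        rows.append({"family": fam.name, "ltr": ltr.value, "one_in_n": n, "rendered": rendered})
    out = pd.DataFrame(rows)
    lo, hi = int(out["one_in_n"].min()), int(out["one_in_n"].max())
    out.attrs["band"] = (lo, hi)
    out.attrs["band_summary"] = f"between 1 in {hi} and 1 in {lo}"
    return out


@dataclass(frozen=True)
class SyntheticBundle:
    """A fully consistent set of inputs for one lifetime-risk computation."""

    life_table: AbridgedLifeTable
    fertility: FertilitySchedule
    morbidity: MorbiditySchedule
    srb: float
    nrr: float
    seed: int | None

    def aggregate_ratio(self) -> float:
        """Count-based aggregate (cases over births when counts are stored)."""
        return self.morbidity.aggregate_ratio()

    def aggregate_ratio_exact(self) -> float:
        """Birth-weighted aggregate of the calibrated (pre-rounding) ratios."""
        m = self.morbidity
        if m.live_births is None:
            raise InputError("bundle has no live-birth weights")
        return float((m.ratio * m.live_births).sum() / m.live_births.sum())


# Baseline five-year death probabilities across the reproductive ages for the
# synthetic life table, patterned on a southern-African mortality level
# (survival to 15 about 0.95, rising adult mortality with age).
_BASE_Q5 = np.array([0.006, 0.012, 0.015, 0.022, 0.028, 0.037, 0.045])
_BASE_ASFR = np.array([66.9, 154.3, 160.0, 140.9, 103.9, 45.6, 11.2]) / 1000.0


def make_synthetic_bundle(
    seed: int | None = 0,
    grid: AgeGrid | None = None,
    mortality_level: float = 1.0,
    fertility_level: float = 3.41,
    target_aggregate: float = 8.03,
    family: str | ShapeFamily = "j_shape",
    srb: float = 101.0,
    women_per_group: float = 17_000.0,
    radix: float = 100_000.0,
    survival_to_15: float = 0.953,
    jitter: float = 0.05,
) -> SyntheticBundle:
    """Generate a reproducible, internally consistent input bundle.

    Defaults emulate the Namibia 2019 study conditions: survival to age 15 of
    about 0.95, total fertility around 3.4 births per woman, an aggregate
    near-miss ratio of 8.03 per 1000 live births under a J-shaped age
    profile, and a sex ratio at birth of 101 boys per 100 girls.

    Parameters
    ----------
    mortality_level : multiplies the baseline five-year death probabilities
        (1.0 is Namibia-like; must keep every probability below 1).
    fertility_level : total fertility rate, births per woman.
    target_aggregate : aggregate ratio, events per 1000 live births.
    jitter : coefficient of variation of the lognormal noise applied to the
        age patterns of mortality and fertility (0 disables it).
    seed : drives the single random generator behind all stochastic choices;
        the same seed always returns an identical bundle.

    Use ``load_fixture("namibia2019")`` for the exact worked-example columns;
    this generator produces *new* bundles around those conditions.
    """
    if grid is not None and grid != AgeGrid.reproductive():
        raise InputError("synthetic bundles are generated on the 5-year reproductive grid")
    if not 0 < survival_to_15 <= 1:
        raise InputError("survival_to_15 must lie in (0, 1]")
    if mortality_level < 0 or fertility_level < 0 or women_per_group <= 0:
        raise InputError("mortality, fertility and population knobs must be non-negative")
    fam = family if isinstance(family, ShapeFamily) else ShapeFamily.default(family)
    rng = np.random.default_rng(seed)

    noise = lambda k: np.exp(rng.normal(0.0, jitter, k)) if jitter > 0 else np.ones(k)
    q5 = np.clip(_BASE_Q5 * mortality_level * noise(7), 0.0, None)
    if np.any(q5 >= 1.0):
        raise InputError("mortality_level too high: a five-year death probability reaches 1")
    l15 = radix * survival_to_15
    lx = l15 * np.concatenate([[1.0], np.cumprod(1.0 - q5)])
    Lx = 2.5 * (lx[:-1] + lx[1:])
    lt = AbridgedLifeTable(AgeGrid.reproductive(), lx[:-1], Lx, radix, float(lx[-1]))

    shape = _BASE_ASFR * noise(7)
    asfr = shape * fertility_level / (5.0 * shape.sum())
    fert = FertilitySchedule(AgeGrid.reproductive(), asfr)

    births = np.maximum(np.floor(asfr * 5.0 * women_per_group + 0.5), 1.0)
    morb = ratios_from_shape(fam, births, target_aggregate)
    nrr = nrr_from_schedules(lt, fert, srb)
    return SyntheticBundle(lt, fert, morb, srb, nrr, seed)
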