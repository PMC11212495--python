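"""Core demographic containers: age grids, abridged life tables, fertility and
morbidity schedules, and the net reproduction rate.

Conventions
-----------
* All rates and ratios are **stored as pure proportions** (per woman-year, per
  live birth).  Per-1000 / per-100 000 inputs are normalised exactly once, at
  construction time, via the ``units`` argument of the ``from_*`` helpers.
* Age grids are strict: two schedules interoperate only if their
  (start age, interval length) pairs are identical.  No re-binning is ever
  attempted, because silently re-aggregating age-specific inputs would corrupt
  the age-disaggregated estimators.
* The default reproductive grid is the seven five-year groups
  [15, 20), [20, 25), ..., [45, 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import GridAlignmentError, InputError, UsageError

#: Relative tolerance for internal consistency checks (counts vs ratios etc.).
RTOL = 1e-9

EventKind = Literal["mnm", "maternal_death", "smo"]
Route = Literal["age_specific", "summary", "summary_nrr"]

RATIO_UNITS = {"per_birth": 1.0, "per_1000": 1e-3, "per_100000": 1e-5}
RATE_UNITS = {"per_woman": 1.0, "per_1000": 1e-3}


def _as_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AgeGrid:
    """A contiguous, ascending sequence of age groups [x, x+n)."""

    start_ages: tuple[float, ...]
    interval_lengths: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = np.asarray(self.start_ages, dtype=float)
        lengths = np.asarray(self.interval_lengths, dtype=float)
        if starts.size == 0 or starts.size != lengths.size:
            raise InputError("age grid needs equal, non-empty start/length vectors")
        if np.any(lengths <= 0):
            raise InputError("age-interval lengths must be positive")
        if not np.allclose(starts[1:], starts[:-1] + lengths[:-1]):
            raise InputError("age groups must be contiguous, non-overlapping and ascending")

    @classmethod
    def reproductive(cls) -> "AgeGrid":
        """The default grid: [15,20), [20,25), ..., [45,50)."""
        return cls(tuple(range(15, 50, 5)), (5.0,) * 7)

    def __len__(self) -> int:
        return len(self.start_ages)

    def index_of(self, start_age: float) -> int:
        try:
            return self.start_ages.index(start_age)
        except ValueError:
            raise InputError(
                f"age group starting at {start_age} not in grid {self.start_ages}"
            ) from None

    def labels(self) -> list[str]:
        return [
            f"{int(x)}-{int(x + n) - 1}"
            for x, n in zip(self.start_ages, self.interval_lengths)
        ]

    def require_same(self, other: "AgeGrid", what: str = "schedules") -> None:
        if self != other:
            mine = set(zip(self.start_ages, self.interval_lengths))
            theirs = set(zip(other.start_ages, other.interval_lengths))
            odd = sorted(mine.symmetric_difference(theirs))
            raise GridAlignmentError(
                f"{what} are on different age grids; offending (start, length) groups: {odd}"
            )


@dataclass(frozen=True)
class AbridgedLifeTable:
    """Female survivorship on an abridged (typically 5-year) age grid.

    Parameters
    ----------
    grid : AgeGrid
        May extend below 15 and above 50; lifetime-risk computations only use
        the reproductive groups.
    lx : survivors at the exact start age of each group, from a radix ``l0``.
    Lx : person-years lived in each group, ``L(x, n)``.
    radix : the life-table radix ``l0`` (default 100 000).
    lx_end : optional survivors at the exact end age of the final group,
        enabling the ``n*l(x+n) <= L(x,n)`` check for that group too.
    """

    grid: AgeGrid
    lx: np.ndarray
    Lx: np.ndarray
    radix: float = 100_000.0
    lx_end: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lx", _as_array(self.lx, "lx"))
        object.__setattr__(self, "Lx", _as_array(self.Lx, "Lx"))
        if len(self.lx) != len(self.grid) or len(self.Lx) != len(self.grid):
            raise InputError("lx and Lx must have one value per age group")
        if self.radix <= 0:
            raise InputError("radix l0 must be positive")
        if np.any(self.lx < 0) or np.any(self.lx > self.radix * (1 + RTOL)):
            raise InputError("survivors l(x) must satisfy 0 <= l(x) <= l0")
        if np.any(np.diff(self.lx) > RTOL * self.radix):
            bad = self.grid.start_ages[int(np.argmax(np.diff(self.lx) > RTOL * self.radix)) + 1]
            raise InputError(f"l(x) must be non-increasing; it rises at age {bad}")
        n = np.asarray(self.grid.interval_lengths)
        upper = n * self.lx
        lower = np.empty_like(upper)
        lower[:-1] = n[:-1] * self.lx[1:]
        lower[-1] = n[-1] * (self.lx_end if self.lx_end is not None else 0.0)
        tol = RTOL * self.radix * n
        if np.any(self.Lx > upper + tol) or np.any(self.Lx < lower - tol):
            bad = [
                x
                for x, ok in zip(
                    self.grid.start_ages,
                    (self.Lx <= upper + tol) & (self.Lx >= lower - tol),
                )
                if not ok
            ]
            raise InputError(
                f"L(x,n) outside [n*l(x+n), n*l(x)] for groups starting at {bad}"
            )

    def survivors_at(self, exact_age: float) -> float:
        """l(x) at an exact age that starts one of the grid's groups."""
        return float(self.lx[self.grid.index_of(exact_age)])

    @property
    def l15(self) -> float:
        return self.survivors_at(15)

    def reproductive_slice(self) -> "AbridgedLifeTable":
        """Restrict to the seven [15, 50) groups (no-op if already there)."""
        repro = AgeGrid.reproductive()
        if self.grid == repro:
            return self
        idx = [self.grid.index_of(x) for x in repro.start_ages]
        if any(
            self.grid.interval_lengths[i] != n
            for i, n in zip(idx, repro.interval_lengths)
        ):
            raise GridAlignmentError("life table does not contain the 5-year reproductive groups")
        end = idx[-1] + 1
        lx_end = float(self.lx[end]) if end < len(self.grid) else self.lx_end
        return AbridgedLifeTable(repro, self.lx[idx], self.Lx[idx], self.radix, lx_end)


def survival_weight(lt: AbridgedLifeTable, start_age: float) -> float:
    """Expected years lived in [x, x+n) by a girl who survived to age 15.

    Returns ``L(x, n) / l(15)``.  For Namibia 2019 this is 4.98 years for the
    15-19 group and 4.32 for 45-49.
    """
    l15 = lt.l15
    if l15 <= 0:
        raise InputError("l(15) must be positive to condition on survival to age 15")
    i = lt.grid.index_of(start_age)
    return float(lt.Lx[i] / l15)


def survival_weights(lt: AbridgedLifeTable) -> np.ndarray:
    """Vector of ``L(x,n)/l(15)`` over the reproductive groups."""
    rlt = lt.reproductive_slice()
    if rlt.l15 <= 0:
        raise InputError("l(15) must be positive to condition on survival to age 15")
    return rlt.Lx / rlt.l15


@dataclass(frozen=True)
class FertilitySchedule:
    """Age-specific fertility rates f(x,n), live births per woman-year."""

    grid: AgeGrid
    rates: np.ndarray  # per woman-year, stored as proportions

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", _as_array(self.rates, "fertility rates"))
        if len(self.rates) != len(self.grid):
            raise InputError("fertility schedule needs one rate per age group")
        if np.any(self.rates < 0):
            raise InputError("fertility rates must be non-negative")

    @classmethod
    def from_rates(
        cls, rates: Sequence[float], grid: AgeGrid | None = None, units: str = "per_woman"
    ) -> "FertilitySchedule":
        if units not in RATE_UNITS:
            raise InputError(f"unknown fertility units {units!r}; use one of {sorted(RATE_UNITS)}")
        grid = grid or AgeGrid.reproductive()
        return cls(grid, np.asarray(rates, dtype=float) * RATE_UNITS[units])


@dataclass(frozen=True)
class MorbiditySchedule:
    """Per-age-group event counts, live births and ratios.

    Represents MNM ratio schedules and maternal-mortality ratio schedules
    alike: the event kind is a label, not a structural difference.  When both
    counts and ratios are stored, the ratio must agree with cases/births to
    within one event per group — ratios produced by calibrated simulation are
    exact while their case columns are integer-apportioned, so consistency is
    enforced at the one-event level rather than to float round-off.
    """

    grid: AgeGrid
    ratio: np.ndarray  # events per live birth
    cases: np.ndarray | None = None
    live_births: np.ndarray | None = None
    event_kind: EventKind = "mnm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio", _as_array(self.ratio, "ratio"))
        if len(self.ratio) != len(self.grid):
            raise InputError("morbidity schedule needs one ratio per age group")
        if np.any(self.ratio < 0):
            raise InputError("morbidity ratios must be non-negative")
        for name in ("cases", "live_births"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _as_array(v, name))
                if len(getattr(self, name)) != len(self.grid):
                    raise InputError(f"{name} needs one value per age group")
                if np.any(getattr(self, name) < 0):
                    raise InputError(f"{name} must be non-negative")
        if self.cases is not None and self.live_births is not None:
            if np.any((self.cases > 0) & (self.live_births <= 0)):
                raise InputError("live_births must be positive wherever cases occur")
            with np.errstate(invalid="ignore", divide="ignore"):
                implied = np.where(self.live_births > 0, self.cases / np.maximum(self.live_births, 1), 0.0)
            # one-event slack per group covers integer apportionment
            slack = 1.0 / np.maximum(self.live_births, 1.0)
            if np.any(np.abs(self.ratio - implied) > slack + RTOL):
                raise InputError("ratio column disagrees with cases/live_births")

    @classmethod
    def from_counts(
        cls,
        cases: Sequence[float],
        live_births: Sequence[float],
        grid: AgeGrid | None = None,
        event_kind: EventKind = "mnm",
    ) -> "MorbiditySchedule":
        grid = grid or AgeGrid.reproductive()
        cases = _as_array(cases, "cases")
        births = _as_array(live_births, "live_births")
        if np.any(births <= 0):
            raise InputError("live_births must be positive to derive ratios from counts")
        return cls(grid, cases / births, cases, births, event_kind)

    @classmethod
    def from_ratios(
        cls,
        ratios: Sequence[float],
        grid: AgeGrid | None = None,
        units: str = "per_birth",
        event_kind: EventKind = "mnm",
    ) -> "MorbiditySchedule":
        if units not in RATIO_UNITS:
            raise InputError(f"unknown ratio units {units!r}; use one of {sorted(RATIO_UNITS)}")
        grid = grid or AgeGrid.reproductive()
        return cls(grid, np.asarray(ratios, dtype=float) * RATIO_UNITS[units], event_kind=event_kind)

    def aggregate_ratio(self) -> float:
        """Birth-weighted aggregate ratio over all groups (events per live birth)."""
        if self.cases is not None and self.live_births is not None:
            return float(self.cases.sum() / self.live_births.sum())
        if self.live_births is not None:
            return float((self.ratio * self.live_births).sum() / self.live_births.sum())
        raise UsageError("aggregate ratio needs live-birth weights; none are stored")


@dataclass(frozen=True)
class SummaryInputs:
    """Inputs to the summary (NRR/SRB shortcut) route.

    aggregate_ratio : events per live birth, ages 15-49 combined.
    nrr : net reproduction rate, daughters per woman.
    srb : sex ratio at birth, boys per 100 girls.
    l0, l15 : radix and survivors to exact age 15 of the female life table.
    """

    aggregate_ratio: float
    nrr: float
    srb: float
    l0: float = 100_000.0
    l15: float = 100_000.0

    def __post_init__(self) -> None:
        if self.aggregate_ratio < 0:
            raise InputError("aggregate ratio must be non-negative")
        if self.nrr < 0:
            raise InputError("NRR must be non-negative")
        if self.srb <= 0:
            raise InputError("SRB must be positive (boys per 100 girls)")
        if self.l0 <= 0 or self.l15 <= 0:
            raise InputError("l0 and l15 must be positive")


@dataclass(frozen=True)
class LifetimeRisk:
    """A lifetime-risk value with its per-age decomposition and provenance."""

    value: float
    route: Route
    event_kind: EventKind
    per_age_contributions: np.ndarray = field(default_factory=lambda: np.array([]))
    grid: AgeGrid | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_age_contributions", np.asarray(self.per_age_contributions, dtype=float)
        )
        if not np.isfinite(self.value) or self.value < 0:
            raise InputError("lifetime risk must be a finite non-negative probability")
        if self.value >= 1:
            raise InputError(
                f"lifetime risk {self.value:.4f} >= 1 is not a probability; check input units"
            )
        if self.route == "age_specific":
            s = float(self.per_age_contributions.sum())
            if abs(s - self.value) > RTOL * max(1.0, abs(self.value)):
                raise InputError("age-specific value must equal the sum of its contributions")

    @property
    def one_in_n(self) -> int:
        from .indicators import one_in_n

        return one_in_n(self.value)[0]

    def render(self) -> str:
        from .indicators import one_in_n

        return one_in_n(self.value)[1]


def nrr_from_schedules(
    lt: AbridgedLifeTable, fert: FertilitySchedule, srb: float
) -> float:
    """Net reproduction rate: expected daughters per newborn girl.

    NRR = sum over groups of ``f(x,n) * L(x,n)/l0 * 100/(100+SRB)``, where the
    last factor converts all-births fertility to daughters only.
    """
    if srb <= 0:
        raise InputError("SRB must be positive (boys per 100 girls)")
    rlt = lt.reproductive_slice()
    fert.grid.require_same(rlt.grid, "fertility schedule and life table")
    return float((fert.rates * rlt.Lx).sum() / rlt.radix * 100.0 / (100.0 + srb))
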