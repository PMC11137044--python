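"""Mechanistic phenological occupancy model for an emperor penguin colony.

The breeding season (March 1 to February 28 of the next year) is described by
a fixed, ordered set of colony-wide arrival and departure waves.  Each wave is
a Gaussian distribution of individual event dates; the expected number of
individuals of a cohort present on day t is the signed sum of event CDFs
scaled by the number of participants.  Fourteen parameters place and scale
the waves: arrival timing and spread, courtship duration, the female's long
incubation absence, the breeding population and its success ratios, and the
foraging-trip duration ramps of the guarding and creching phases.

Time is measured in continuous day-of-year of the season's starting calendar
year: March 1 = day 60, February 28 of the next year = day 424.  Day-of-year
values above 365 simply run into the next calendar year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.special import ndtr

__all__ = [
    "PhenologyParams",
    "PhenologyEvent",
    "EventSchedule",
    "OccupancyCurve",
    "BreedingOutcome",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "SEASON_START_DAY",
    "SEASON_END_DAY",
    "N_GUARD_TRIPS",
    "N_CRECHE_TRIPS",
    "season_grid",
    "season_day_to_date",
    "trip_durations",
    "total_time_at_sea_colony",
    "build_event_schedule",
    "occupancy",
    "breeding_outcome",
    "event_dates",
    "agent_oracle",
    "oracle_standard_error",
]

SEASON_START_DAY = 60  # March 1 (non-leap day-of-year)
SEASON_END_DAY = 424  # February 28 of the following year

#: Trip counts are fixed model structure, not free parameters: two parental
#: switches per sex while the chick is brooded, seven feeding/foraging trips
#: per sex after thermal emancipation.
N_GUARD_TRIPS = 2
N_CRECHE_TRIPS = 7

PARAM_NAMES = (
    "t0",
    "dt0",
    "m",
    "b",
    "db",
    "bp",
    "nb",
    "hr",
    "f",
    "c_max",
    "c_min",
    "s_max",
    "s_min",
    "s_fem",
)

#: Box bounds per parameter (widest physiological ranges).  Ordering
#: constraints (c_min <= c_max, s_min/s_fem in [c_max, s_max], F <= Hr,
#: db >= dt0) are enforced separately.
PARAM_BOUNDS = {
    "t0": (50.0, 150.0),
    "dt0": (4.0, 14.0),
    "m": (28.0, 42.0),
    "b": (50.0, 100.0),
    "db": (0.0, 14.0),
    "bp": (2000.0, 15000.0),
    "nb": (0.0, 1.0),
    "hr": (0.0, 1.0),
    "f": (0.0, 1.0),
    "c_max": (1.0, 5.0),
    "c_min": (1.0, 5.0),
    "s_max": (1.0, 21.0),
    "s_min": (1.0, 21.0),
    "s_fem": (1.0, 21.0),
}


@dataclass(frozen=True)
class PhenologyParams:
    """One colony-season's phenology.

    Attributes
    ----------
    t0, dt0 : float
        Peak arrival day-of-year and its standard deviation (days).
    m : float
        Courtship duration: arrival to first female departure (days).
    b, db : float
        Female absence duration after laying and its standard deviation.
        ``db`` is shared by every post-return event and must be >= ``dt0``.
    bp : float
        Number of breeding pairs.
    nb : float
        Non-breeder to breeding-pair ratio (individual birds).
    hr, f : float
        Hatching and fledging success ratios (pairs surviving to hatching
        and fledging, relative to ``bp``); ``f <= hr``.
    c_max, c_min : float
        Maximum/minimum time at the colony per trip (days).
    s_max, s_min : float
        Maximum/minimum time at sea per trip (days).
    s_fem : float
        The female's first post-hatching trip at sea (days), <= s_max.
    """

    t0: float
    dt0: float
    m: float
    b: float
    db: float
    bp: float
    nb: float
    hr: float
    f: float
    c_max: float
    c_min: float
    s_max: float
    s_min: float
    s_fem: float

    def violations(self) -> list[str]:
        """Human-readable list of bound/ordering violations (empty if valid)."""
        out = []
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                out.append(f"{name}={v} outside [{lo}, {hi}]")
        if self.c_min > self.c_max:
            out.append("c_min > c_max")
        if self.s_max < self.c_max:
            out.append("s_max < c_max")
        if not (self.c_max <= self.s_min <= self.s_max):
            out.append("s_min outside [c_max, s_max]")
        if not (self.c_max <= self.s_fem <= self.s_max):
            out.append("s_fem outside [c_max, s_max]")
        if self.f > self.hr:
            out.append("f > hr")
        if self.db < self.dt0:
            out.append("db < dt0")
        return out

    def validate(self) -> "PhenologyParams":
        v = self.violations()
        if v:
            raise ValueError("invalid phenology parameters: " + "; ".join(v))
        return self

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "PhenologyParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, theta))))

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "PhenologyParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PhenologyEvent:
    """One colony-wide Gaussian arrival (+) or departure (-) wave."""

    label: str
    cohort: str  # female_breeder | male_breeder | non_breeder | chick
    mean_day: float
    sd_day: float
    magnitude: float  # signed individuals

    def __post_init__(self) -> None:
        if self.sd_day <= 0:
            raise ValueError(f"event {self.label}: sd_day must be positive")


@dataclass
class EventSchedule:
    """Ordered signed Gaussian events for all cohorts of one season."""

    events: list[PhenologyEvent]
    params: PhenologyParams
    season_start: float = float(SEASON_START_DAY)
    season_end: float = float(SEASON_END_DAY)

    def for_cohort(self, cohort: str) -> list[PhenologyEvent]:
        return [e for e in self.events if e.cohort == cohort]

    @property
    def last_event_day(self) -> float:
        return max(e.mean_day for e in self.events)

    def to_records(self) -> list[dict]:
        return [asdict(e) for e in self.events]


@dataclass
class OccupancyCurve:
    """Expected counts per cohort on a daily season grid."""

    days: np.ndarray
    females: np.ndarray
    males: np.ndarray
    non_breeders: np.ndarray
    chicks: np.ndarray

    @property
    def adults(self) -> np.ndarray:
        return self.females + self.males + self.non_breeders

    @property
    def total(self) -> np.ndarray:
        return self.adults + self.chicks

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.days,
                "females": self.females,
                "males": self.males,
                "non_breeders": self.non_breeders,
                "chicks": self.chicks,
                "adults": self.adults,
                "total": self.total,
            }
        )


@dataclass(frozen=True)
class BreedingOutcome:
    """Season outcome split; the three parts sum to the number of pairs."""

    fledged: float
    dead_chicks: float
    lost_eggs: float

    @property
    def total(self) -> float:
        return self.fledged + self.dead_chicks + self.lost_eggs


def season_grid(step: float = 1.0) -> np.ndarray:
    """Daily day-of-year grid from March 1 (60) to February 28 (424)."""
    return np.arange(SEASON_START_DAY, SEASON_END_DAY + step / 2, step)


def season_day_to_date(day: float, start_year: int) -> dt.date:
    """Convert a continuous season day-of-year to a calendar date.

    Day 1 = January 1 of ``start_year``; values above 365 run into the next
    calendar year (a 365-day year is assumed for the season axis).
    """
    return dt.date(start_year, 1, 1) + dt.timedelta(days=float(day) - 1)


def trip_durations(p: PhenologyParams) -> dict:
    """Per-trip (time_at_sea, time_at_colony) for both breeding phases.

    Guarding trips (2 per sex) use the maximum durations ``s_max``/``c_max``;
    the female's first post-hatch trip is shortened to ``s_fem``.  Creche trip
    k (k = 1..7) interpolates linearly from (s_max, c_max) at k = 1 to
    (s_min, c_min) at k = 7, reflecting the field-observed shortening of
    foraging trips towards fledging.
    """
    p.validate()
    creche = []
    for k in range(N_CRECHE_TRIPS):
        w = k / (N_CRECHE_TRIPS - 1)
        sea = p.s_max + w * (p.s_min - p.s_max)
        col = p.c_max + w * (p.c_min - p.c_max)
        creche.append((sea, col))
    guard_male = [(p.s_max, p.c_max)] * N_GUARD_TRIPS
    guard_female = [(p.s_fem, p.c_max)] + [(p.s_max, p.c_max)] * (N_GUARD_TRIPS - 1)
    return {
        "guard": {"female": guard_female, "male": guard_male},
        "creche": {"female": list(creche), "male": list(creche)},
    }


def total_time_at_sea_colony(p: PhenologyParams) -> tuple[float, float]:
    """Total (days at sea, days at colony) during creching, sex-averaged."""
    trips = trip_durations(p)["creche"]
    sea = np.mean([sum(t[0] for t in trips[s]) for s in ("female", "male")])
    col = np.mean([sum(t[1] for t in trips[s]) for s in ("female", "male")])
    return float(sea), float(col)


def build_event_schedule(
    p: PhenologyParams,
    validate_season: bool = True,
) -> EventSchedule:
    """Construct the fixed event structure from one parameter set.

    Event means are laid out as follows (all magnitudes in individuals,
    positive = arrival):

    * arrival of BP females, BP males and NB*BP non-breeders at t0 (sd dt0);
    * departure of females and non-breeders at t0 + m (sd dt0; courtship is
      equally long for everyone, so these share the arrival spread);
    * female return at t_r = t0 + m + b (sd db) with magnitude Hr*BP — only
      pairs whose egg hatched keep provisioning, and hatching coincides with
      the female's return;
    * guarding: the parents strictly alternate so the chick is never alone;
      the returning forager spends the feeding stay c_max at the colony
      before the partner departs, so every switch overlaps by c_max.  The
      male departs at t_r + c_max (all BP males leave then; failed breeders
      never return) and makes two s_max trips; the female's trips are s_fem
      then s_max, each interleaved with the male's;
    * thermal emancipation at t_e = t_r + 5*c_max + 3*s_max + s_fem, when
      the female ends the final guard stint: chicks "enter" the countable
      colony with magnitude Hr*BP and both parents depart on the first
      creche trip;
    * seven creche trips per sex with linearly shrinking durations; the
      surviving-pair fraction declines linearly from Hr to F across the seven
      returns (abandonments happen at sea), with matching chick losses;
    * fledging: the remaining F*BP chicks and F*BP adults of each sex leave
      after the last feeding stay.

    All post-return events share the spread ``db``.  Raises ``ValueError``
    when parameters are invalid or (with ``validate_season``) when the
    schedule runs past February 28.
    """
    p.validate()
    ev: list[PhenologyEvent] = []
    bp, nb, hr, f = p.bp, p.nb, p.hr, p.f
    sd1, sd2 = p.dt0, p.db
    c = p.c_max
    t_arr = p.t0
    t_dep = p.t0 + p.m
    t_ret = p.t0 + p.m + p.b  # female return == hatching wave

    def add(label, cohort, mean, sd, mag):
        if mag != 0.0:
            ev.append(PhenologyEvent(label, cohort, float(mean), float(sd), float(mag)))

    add("arrival", "female_breeder", t_arr, sd1, +bp)
    add("arrival", "male_breeder", t_arr, sd1, +bp)
    add("arrival", "non_breeder", t_arr, sd1, +nb * bp)
    add("courtship_departure", "female_breeder", t_dep, sd1, -bp)
    add("courtship_departure", "non_breeder", t_dep, sd1, -nb * bp)
    add("female_return", "female_breeder", t_ret, sd2, +hr * bp)

    trips = trip_durations(p)

    # Guarding: alternating stints with a c_max feeding overlap per switch.
    m_dep1 = t_ret + c
    m_ret1 = m_dep1 + p.s_max
    f_dep1 = m_ret1 + c
    f_ret1 = f_dep1 + p.s_fem
    m_dep2 = f_ret1 + c
    m_ret2 = m_dep2 + p.s_max
    f_dep2 = m_ret2 + c
    f_ret2 = f_dep2 + p.s_max
    t_e = f_ret2 + c  # thermal emancipation

    add("male_departure", "male_breeder", m_dep1, sd2, -bp)
    add("guard_return_1", "male_breeder", m_ret1, sd2, +hr * bp)
    add("guard_departure_2", "male_breeder", m_dep2, sd2, -hr * bp)
    add("guard_return_2", "male_breeder", m_ret2, sd2, +hr * bp)
    add("guard_departure_1", "female_breeder", f_dep1, sd2, -hr * bp)
    add("guard_return_1", "female_breeder", f_ret1, sd2, +hr * bp)
    add("guard_departure_2", "female_breeder", f_dep2, sd2, -hr * bp)
    add("guard_return_2", "female_breeder", f_ret2, sd2, +hr * bp)

    add("emancipation_entry", "chick", t_e, sd2, +hr * bp)

    # Creche: both sexes run the same dep/ret ladder from emancipation.
    # Pair survival declines linearly from Hr to F across the 7 returns.
    q = [hr - (j / N_CRECHE_TRIPS) * (hr - f) for j in range(N_CRECHE_TRIPS + 1)]
    for cohort in ("female_breeder", "male_breeder"):
        t = t_e
        add("emancipation_departure", cohort, t, sd2, -q[0] * bp)
        for j, (sea, col) in enumerate(trips["creche"][cohort.split("_")[0]], start=1):
            t += sea
            add(f"creche_return_{j}", cohort, t, sd2, +q[j] * bp)
            t += col
            if j < N_CRECHE_TRIPS:
                add(f"creche_departure_{j + 1}", cohort, t, sd2, -q[j] * bp)
            else:
                add("fledging_departure", cohort, t, sd2, -q[j] * bp)
        t_fledge = t

    # Chick losses ride on the creche returns; fledging empties the creche.
    t = t_e
    for j, (sea, col) in enumerate(trips["creche"]["male"], start=1):
        t += sea
        add(f"chick_loss_{j}", "chick", t, sd2, -(q[j - 1] - q[j]) * bp)
        t += col
    add("fledging", "chick", t_fledge, sd2, -f * bp)

    sched = EventSchedule(events=ev, params=p)
    if validate_season and sched.last_event_day > sched.season_end:
        raise ValueError(
            f"schedule extends to day {sched.last_event_day:.1f}, past the "
            f"season end (day {sched.season_end:.0f}, Feb 28)"
        )
    return sched


_COHORTS = ("female_breeder", "male_breeder", "non_breeder", "chick")


def _cohort_arrays(schedule: EventSchedule) -> dict[str, tuple[np.ndarray, ...]]:
    out = {}
    for cohort in _COHORTS:
        evs = schedule.for_cohort(cohort)
        mu = np.array([e.mean_day for e in evs])
        sd = np.array([e.sd_day for e in evs])
        mag = np.array([e.magnitude for e in evs])
        out[cohort] = (mu, sd, mag)
    return out


def occupancy(schedule: EventSchedule, days: np.ndarray | None = None) -> OccupancyCurve:
    """Expected per-cohort counts: signed sum of Gaussian event CDFs.

    count_c(t) = sum_e magnitude_e * Phi((t - mean_e) / sd_e), clipped at 0
    against floating-point undershoot.
    """
    if days is None:
        days = season_grid()
    days = np.asarray(days, dtype=float)
    arrays = _cohort_arrays(schedule)
    counts = {}
    for cohort, (mu, sd, mag) in arrays.items():
        if mu.size == 0:
            counts[cohort] = np.zeros_like(days)
            continue
        z = (days[:, None] - mu[None, :]) / sd[None, :]
        counts[cohort] = np.clip(ndtr(z) @ mag, 0.0, None)
    return OccupancyCurve(
        days=days,
        females=counts["female_breeder"],
        males=counts["male_breeder"],
        non_breeders=counts["non_breeder"],
        chicks=counts["chick"],
    )


def occupancy_at(
    schedule: EventSchedule, days: np.ndarray, which: str = "adults"
) -> np.ndarray:
    """Expected counts at arbitrary days for one aggregate (fast path).

    ``which`` is one of ``adults`` (breeders + non-breeders), ``total``
    (adults + chicks), ``chicks``.
    """
    days = np.asarray(days, dtype=float)
    if which == "adults":
        cohorts = _COHORTS[:3]
    elif which == "total":
        cohorts = _COHORTS
    elif which == "chicks":
        cohorts = ("chick",)
    else:
        raise ValueError(f"unknown aggregate {which!r}")
    evs = [e for e in schedule.events if e.cohort in cohorts]
    mu = np.array([e.mean_day for e in evs])
    sd = np.array([e.sd_day for e in evs])
    mag = np.array([e.magnitude for e in evs])
    z = (days[:, None] - mu[None, :]) / sd[None, :]
    return np.clip(ndtr(z) @ mag, 0.0, None)


def breeding_outcome(p: PhenologyParams) -> BreedingOutcome:
    """Split the breeding pairs into fledged, dead-chick and lost-egg pairs.

    fledged = F*BP, dead_chicks = (Hr - F)*BP, lost_eggs = (1 - Hr)*BP;
    lost eggs are computed as the remainder so the three parts sum to BP
    exactly.
    """
    if p.f > p.hr:
        raise ValueError("fledging success cannot exceed hatching success")
    fledged = p.f * p.bp
    dead = p.hr * p.bp - fledged
    lost = p.bp - fledged - dead
    return BreedingOutcome(fledged=fledged, dead_chicks=dead, lost_eggs=lost)


def event_dates(p: PhenologyParams) -> dict[str, float]:
    """Central (mean) dates of the named phenological events, in day-of-year.

    Note the field convention records the *first occurrence* of a behaviour,
    which systematically precedes these central dates by roughly two standard
    deviations of the event spread; the model reports central dates and makes
    no correction.
    """
    sched = build_event_schedule(p, validate_season=False)
    by_label = {}
    for e in sched.events:
        by_label.setdefault((e.label, e.cohort), e.mean_day)
    t_e = by_label[("emancipation_entry", "chick")]
    t_fl = by_label[("fledging", "chick")]
    return {
        "arrival": p.t0,
        "female_departure": p.t0 + p.m,
        "female_return": p.t0 + p.m + p.b,
        "hatching": p.t0 + p.m + p.b,
        "emancipation": t_e,
        "fledging": t_fl,
    }


def oracle_standard_error(
    p: PhenologyParams,
    n_pairs: int,
    days: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Exact per-day standard deviation of the agent oracle, per cohort.

    The simulated count is a signed sum of binomial contributions whose
    participation indicators share one uniform draw per pair (nested
    survival), so the variance has both binomial terms and participation
    covariances; both are computed in closed form here, in animal units on
    the analytic (BP) scale.  Used to compare the oracle with the analytic
    occupancy at a known Monte-Carlo resolution.
    """
    if days is None:
        days = season_grid()
    days = np.asarray(days, dtype=float)
    sched = build_event_schedule(p, validate_season=False)
    scale = n_pairs / p.bp
    out = {}
    for cohort, (mu, sd, mag) in _cohort_arrays(sched).items():
        if mu.size == 0:
            out[cohort] = np.zeros(days.size)
            continue
        prob = ndtr((days[:, None] - mu[None, :]) / sd[None, :])  # (T, E)
        if cohort == "non_breeder":
            n_nb = int(round(p.nb * n_pairs))
            var = n_nb * np.sum(prob * (1.0 - prob), axis=1)
        else:
            frac = np.abs(mag) / p.bp
            sign = np.sign(mag)
            x = frac[None, :] * prob
            diag = np.sum(x * (1.0 - x), axis=1)
            pair_cov = np.minimum.outer(frac, frac) - np.outer(frac, frac)
            weighted = (np.outer(sign, sign) * pair_cov)[None, :, :] * (
                prob[:, :, None] * prob[:, None, :]
            )
            off = np.sum(weighted, axis=(1, 2)) - np.sum(
                (frac - frac**2)[None, :] * prob**2, axis=1
            )
            var = n_pairs * (diag + off)
        out[cohort] = np.sqrt(np.maximum(var, 0.0)) / scale
    return out


def agent_oracle(
    p: PhenologyParams,
    n_pairs: int,
    seed: int,
    days: np.ndarray | None = None,
) -> OccupancyCurve:
    """Individual-based simulation whose expectation is the occupancy curve.

    Each simulated pair draws every one of its event dates independently from
    the corresponding Gaussian; survival through hatching and the seven
    creche trips is a single nested uniform draw per pair (survive trip j iff
    u < q_j), which reproduces the analytic participation fractions exactly.
    Counts are integers per day and bitwise-reproducible for a fixed seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if days is None:
        days = season_grid()
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(seed)
    sched = build_event_schedule(p, validate_season=False)
    scale = n_pairs / p.bp

    # Participation masks from one nested uniform per pair.
    u = rng.random(n_pairs)
    n_nb = int(round(p.nb * n_pairs))

    counts = {c: np.zeros(days.size) for c in _COHORTS}
    for e in sched.events:
        frac = abs(e.magnitude) / p.bp
        if e.cohort == "non_breeder":
            n_e = n_nb if frac > 0 else 0
            mask_n = n_e
        else:
            # nested participation: the frac*n_pairs pairs with smallest u
            mask_n = int(np.count_nonzero(u < frac + 1e-12))
        if mask_n == 0:
            continue
        times = rng.normal(e.mean_day, e.sd_day, size=mask_n)
        order = np.sort(times)
        cum = np.searchsorted(order, days, side="right")
        counts[e.cohort] += np.sign(e.magnitude) * cum

    for c in counts:
        counts[c] = np.clip(counts[c], 0.0, None) / scale
    return OccupancyCurve(
        days=days,
        females=counts["female_breeder"],
        males=counts["male_breeder"],
        non_breeders=counts["non_breeder"],
        chicks=counts["chick"],
    )
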