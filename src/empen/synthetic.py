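"""Synthetic colony seasons with known ground truth.

Generates the three observation streams the fitting stages consume — weekly
individual counts, meteorological records, and colony-area measurements —
from a known phenology and windchill parameter set, so that every stage of
the package is testable end-to-end without field data.  Weather is a
seasonal + diurnal sinusoid process with Gaussian noise (it emulates the
statistical structure the models assume, not any reanalysis product); count
and density noise are lognormal, matching the models' error conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenology import PhenologyParams, build_event_schedule, occupancy, agent_oracle, season_grid
from .windchill import WindchillParams, apparent_temperature, density_from_apparent_temperature
from .inference import CountSeries

__all__ = [
    "WeatherSettings",
    "GeneratorSpec",
    "random_phenology_params",
    "pg_like_params",
    "ab_like_params",
    "default_windchill_params",
    "generate_weather",
    "generate_counts",
    "generate_areas",
]


def random_phenology_params(rng: np.random.Generator) -> PhenologyParams:
    """One parameter set drawn uniformly subject to all ordering constraints.

    Used for property tests and simulation studies that probe the whole
    physiological box rather than one typical season.
    """
    from .phenology import PARAM_BOUNDS

    u = rng.uniform
    dt0 = u(*PARAM_BOUNDS["dt0"])
    hr = u(0.0, 1.0)
    c_max = u(*PARAM_BOUNDS["c_max"])
    s_max = u(c_max, PARAM_BOUNDS["s_max"][1])
    return PhenologyParams(
        t0=u(*PARAM_BOUNDS["t0"]),
        dt0=dt0,
        m=u(*PARAM_BOUNDS["m"]),
        b=u(*PARAM_BOUNDS["b"]),
        db=u(dt0, PARAM_BOUNDS["db"][1]),
        bp=u(*PARAM_BOUNDS["bp"]),
        nb=u(0.0, 1.0),
        hr=hr,
        f=u(0.0, hr),
        c_max=c_max,
        c_min=u(PARAM_BOUNDS["c_min"][0], c_max),
        s_max=s_max,
        s_min=u(c_max, s_max),
        s_fem=u(c_max, s_max),
    )


def pg_like_params() -> PhenologyParams:
    """Typical season at the more northerly reference colony (~66.7 deg S).

    Arrival peaks April 7 (day 97) with ~3900 breeding pairs; the female
    absence is set so the return date lands on the local first sunrise after
    midwinter (June 29) + 27.4 days.
    """
    return PhenologyParams(
        t0=97.0, dt0=6.0, m=35.0, b=75.0, db=9.0,
        bp=3900.0, nb=0.15, hr=0.85, f=0.70,
        c_max=3.0, c_min=1.5, s_max=12.0, s_min=8.0, s_fem=8.0,
    )


def ab_like_params() -> PhenologyParams:
    """Typical season at the more southerly reference colony (~70.7 deg S).

    Later arrival (around April 27) and a larger population (~8600 pairs);
    the longer female absence aligns the return with the later first sunrise
    (July 28) + 27.4 days.
    """
    return pg_like_params().replace(t0=117.0, b=84.0, bp=8600.0)


def default_windchill_params() -> WindchillParams:
    """Representative huddling response for generating synthetic seasons."""
    return WindchillParams(c_w=-1.5, c_r=0.02, c_h=-0.05, t_c=-28.0, b_0=5.0)


@dataclass(frozen=True)
class WeatherSettings:
    """Sinusoidal weather process (coastal-Antarctic flavour).

    Temperature peaks in mid-January and bottoms out in July; solar
    radiation follows a seasonal envelope that vanishes during the polar
    winter, modulated by a diurnal cycle.  All noise terms are Gaussian with
    the stated standard deviations; wind is truncated at 0, humidity clipped
    to [0, 100] %.
    """

    t_mean: float = -15.0  # annual-mean air temperature, degC
    t_seasonal_amp: float = 10.0  # seasonal half-range, degC
    t_diurnal_amp: float = 3.0  # diurnal half-range, degC
    t_noise_sd: float = 4.0
    w_mean: float = 6.0  # mean wind speed, m/s
    w_noise_sd: float = 3.0
    r_max: float = 350.0  # midsummer noon solar radiation, W/m^2
    r_noise_sd: float = 40.0
    h_mean: float = 70.0  # mean relative humidity, %
    h_noise_sd: float = 12.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to generate one season with known ground truth."""

    phenology: PhenologyParams = field(default_factory=pg_like_params)
    windchill: WindchillParams = field(default_factory=default_windchill_params)
    weather: WeatherSettings = field(default_factory=WeatherSettings)
    start_year: int = 2018
    count_noise_sd_log: float = 0.10  # lognormal sd of observed counts
    area_noise_sd_log: float = 0.0  # multiplicative noise on areas
    density_floor: float = 1e-3  # animals/m^2 below which areas are skipped
    seed: int = 0

    def replace(self, **kw) -> "GeneratorSpec":
        return replace(self, **kw)


def _seasonal_phase(days: np.ndarray) -> np.ndarray:
    # midsummer (warmest, brightest) around day-of-year 15
    return 2.0 * np.pi * (days - 15.0) / 365.0


def generate_weather(spec: GeneratorSpec, days: np.ndarray) -> pd.DataFrame:
    """Weather records at (possibly fractional) season day-of-year values.

    Returns a frame with columns day, timestamp, temp_c, wind_ms, rad_wm2,
    rh_pct; reproducible from (spec, spec.seed) alone.
    """
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(spec.seed)
    ws = spec.weather
    frac = days - np.floor(days)
    diurnal = np.cos(2.0 * np.pi * (frac - 14.0 / 24.0))
    temp = (
        ws.t_mean
        + ws.t_seasonal_amp * np.cos(_seasonal_phase(days))
        + ws.t_diurnal_amp * diurnal
        + rng.normal(0.0, ws.t_noise_sd, size=days.size)
    )
    wind = np.clip(rng.normal(ws.w_mean, ws.w_noise_sd, size=days.size), 0.0, None)
    envelope = np.clip(np.cos(_seasonal_phase(days)), 0.0, None)
    rad = np.clip(
        ws.r_max * envelope * np.clip(diurnal, 0.0, None)
        + rng.normal(0.0, ws.r_noise_sd, size=days.size),
        0.0,
        None,
    )
    hum = np.clip(rng.normal(ws.h_mean, ws.h_noise_sd, size=days.size), 0.0, 100.0)
    ts = pd.Timestamp(spec.start_year, 1, 1) + pd.to_timedelta(days - 1.0, unit="D")
    return pd.DataFrame(
        {
            "day": days,
            "timestamp": ts.round("s"),
            "temp_c": temp,
            "wind_ms": wind,
            "rad_wm2": rad,
            "rh_pct": hum,
        }
    )


@dataclass
class SyntheticCounts:
    """Noisy scheduled counts plus the generating truth."""

    frame: pd.DataFrame  # day, adults, chicks, total (noisy)
    truth: pd.DataFrame  # same days, noiseless expectations
    params: PhenologyParams
    start_year: int

    def adults_series(self) -> CountSeries:
        return CountSeries(
            days=self.frame["day"].to_numpy(),
            counts=self.frame["adults"].to_numpy(),
            kind="adults_only",
            start_year=self.start_year,
        )

    def total_series(self) -> CountSeries:
        return CountSeries(
            days=self.frame["day"].to_numpy(),
            counts=self.frame["total"].to_numpy(),
            kind="total",
            start_year=self.start_year,
        )


def weekly_schedule(start: float = 61.0, stop: float = 420.0, step: float = 7.0) -> np.ndarray:
    """Default weekly census schedule across the season."""
    return np.arange(start, stop + step / 2, step)


def generate_counts(
    spec: GeneratorSpec,
    days: np.ndarray | None = None,
    agent_mode: bool = False,
    n_agent_pairs: int | None = None,
) -> SyntheticCounts:
    """Scheduled counts with lognormal noise and the underlying truth.

    With ``agent_mode`` the expectations are replaced by one individual-based
    realisation (integer counts) before noise is applied.
    """
    if days is None:
        days = weekly_schedule()
    days = np.asarray(days, dtype=float)
    sched = build_event_schedule(spec.phenology)
    if agent_mode:
        n = n_agent_pairs if n_agent_pairs is not None else int(spec.phenology.bp)
        curve = agent_oracle(spec.phenology, n, seed=spec.seed, days=days)
    else:
        curve = occupancy(sched, days)
    truth = pd.DataFrame(
        {
            "day": days,
            "adults": curve.adults,
            "chicks": curve.chicks,
            "total": curve.total,
        }
    )
    rng = np.random.default_rng(spec.seed + 1)
    noisy = truth.copy()
    for col in ("adults", "chicks", "total"):
        factors = np.exp(rng.normal(0.0, spec.count_noise_sd_log, size=days.size))
        noisy[col] = truth[col] * factors
    return SyntheticCounts(
        frame=noisy, truth=truth, params=spec.phenology, start_year=spec.start_year
    )


def generate_areas(
    spec: GeneratorSpec,
    weather: pd.DataFrame,
    true_counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Colony areas that invert the windchill model: A(t) = N_true(t)/rho(t).

    ``weather`` is a frame from :func:`generate_weather`; the true total
    count is evaluated at the same days unless supplied.  Days where the
    predicted density falls below ``spec.density_floor`` are skipped with a
    warning (the colony would be unmeasurably dispersed).  Optional
    lognormal noise ``spec.area_noise_sd_log`` multiplies the areas.
    """
    days = weather["day"].to_numpy(float)
    if true_counts is None:
        sched = build_event_schedule(spec.phenology)
        true_counts = occupancy(sched, days).total
    true_counts = np.asarray(true_counts, dtype=float)
    t_a = apparent_temperature(weather, spec.windchill)
    rho = density_from_apparent_temperature(t_a, spec.windchill)
    keep = rho >= spec.density_floor
    if not np.all(keep):
        warnings.warn(
            f"skipped {int(np.sum(~keep))} area dates with predicted density "
            f"below {spec.density_floor} animals/m^2",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed + 2)
    area = true_counts[keep] / rho[keep]
    if spec.area_noise_sd_log > 0:
        area = area * np.exp(rng.normal(0.0, spec.area_noise_sd_log, size=area.size))
    return pd.DataFrame(
        {
            "day": days[keep],
            "timestamp": weather["timestamp"].to_numpy()[keep],
            "area_m2": area,
        }
    )
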