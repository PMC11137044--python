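"""Windchill model: meteorology -> apparent temperature -> colony density.

Huddling emperor penguins pack more tightly the colder they feel.  The
apparent temperature is a linear combination of air temperature, wind speed,
solar radiation and relative humidity; colony density follows a falling
sigmoid of the apparent temperature that saturates at the hexagonal packing
limit of 12.8 animals/m^2 (circles of 0.3 m diameter).  The five model
parameters are calibrated from paired density/weather observations by
ensemble MCMC under a lognormal observation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .mcmc import MCMCConfig, Posterior, run_ensemble
from .metrics import mean_geometric_error, r_squared

__all__ = [
    "RHO_MAX",
    "MeteoRecord",
    "WindchillParams",
    "DensityObservation",
    "apparent_temperature",
    "density_from_apparent_temperature",
    "density_from_weather",
    "hexagonal_packing_density",
    "counts_from_area",
    "interpolate_counts",
    "daily_average_counts",
    "fit_windchill",
    "WINDCHILL_PRIOR_BOUNDS",
]

#: Maximum colony density: hexagonal packing of 0.3 m circles, 3 sig. figs.
RHO_MAX = 12.8

#: Uniform prior boxes for calibration; signs follow the physics (wind and
#: humidity can only cool or mildly modulate, sunshine warms).
WINDCHILL_PRIOR_BOUNDS = {
    "c_w": (-5.0, 0.0),  # degC per (m/s)
    "c_r": (0.0, 0.1),  # degC per (W/m^2)
    "c_h": (-0.5, 0.5),  # degC per %RH
    "t_c": (-60.0, 10.0),  # degC
    "b_0": (1e-3, 20.0),  # degC
}

WINDCHILL_PARAM_NAMES = ("c_w", "c_r", "c_h", "t_c", "b_0", "sigma_log")


@dataclass(frozen=True)
class MeteoRecord:
    """One timestamped weather observation."""

    timestamp: pd.Timestamp
    temp_c: float  # air temperature, degC
    wind_ms: float  # wind speed, m/s
    rad_wm2: float  # downward solar radiation, W/m^2
    rh_pct: float  # relative humidity, percent

    def __post_init__(self) -> None:
        if self.wind_ms < 0:
            raise ValueError("wind speed must be >= 0")
        if self.rad_wm2 < 0:
            raise ValueError("solar radiation must be >= 0")
        if not 0.0 <= self.rh_pct <= 100.0:
            raise ValueError("relative humidity must be within [0, 100] %")


@dataclass(frozen=True)
class WindchillParams:
    """Apparent-temperature coefficients and the density sigmoid.

    c_w, c_r, c_h convert wind (m/s), radiation (W/m^2) and humidity (%)
    into equivalent degrees Celsius; t_c is the critical apparent
    temperature at which density is half of rho_max; b_0 > 0 sets the
    steepness of the huddling response.
    """

    c_w: float
    c_r: float
    c_h: float
    t_c: float
    b_0: float
    rho_max: float = RHO_MAX

    def __post_init__(self) -> None:
        if self.b_0 <= 0:
            raise ValueError("b_0 must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DensityObservation:
    """A colony area paired with an (interpolated) individual count."""

    timestamp: pd.Timestamp
    area_m2: float
    count: float  # adults + chicks

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError("area must be positive")
        if self.density > RHO_MAX * 1.1:
            raise ValueError(
                f"density {self.density:.2f} exceeds the packing bound "
                f"{RHO_MAX * 1.1:.2f} animals/m^2"
            )

    @property
    def density(self) -> float:
        return self.count / self.area_m2


def apparent_temperature(weather, p: WindchillParams):
    """Apparent temperature T_a = T + c_w*W + c_r*R + c_h*H (degC).

    ``weather`` may be a MeteoRecord or a DataFrame with columns
    temp_c, wind_ms, rad_wm2, rh_pct.
    """
    if isinstance(weather, MeteoRecord):
        return (
            weather.temp_c
            + p.c_w * weather.wind_ms
            + p.c_r * weather.rad_wm2
            + p.c_h * weather.rh_pct
        )
    t = np.asarray(weather["temp_c"], dtype=float)
    w = np.asarray(weather["wind_ms"], dtype=float)
    r = np.asarray(weather["rad_wm2"], dtype=float)
    h = np.asarray(weather["rh_pct"], dtype=float)
    return t + p.c_w * w + p.c_r * r + p.c_h * h


def density_from_apparent_temperature(t_a, p: WindchillParams):
    """Colony density rho = rho_max / (1 + exp((T_a - t_c)/b_0)).

    Strictly decreasing in T_a; rho(t_c) = rho_max/2; saturates at rho_max
    for very cold and 0 for very warm apparent temperatures.
    """
    t_a = np.asarray(t_a, dtype=float)
    z = (t_a - p.t_c) / p.b_0
    out = p.rho_max / (1.0 + np.exp(np.clip(z, -700, 700)))
    return float(out) if out.ndim == 0 else out


def density_from_weather(weather, p: WindchillParams):
    """Convenience composition of the two windchill equations."""
    return density_from_apparent_temperature(apparent_temperature(weather, p), p)


def hexagonal_packing_density(diameter: float) -> float:
    """Maximum animals/m^2 for hexagonal packing of circles, 3 sig. figs.

    Packing fraction pi/(2*sqrt(3)) divided by the circle area; for 0.3 m
    circles this gives the 12.8 animals/m^2 density ceiling.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    rho = (math.pi / (2.0 * math.sqrt(3.0))) / (math.pi * (diameter / 2.0) ** 2)
    return float(f"{rho:.3g}")


def counts_from_area(area_m2, density):
    """Total individuals N = rho * A."""
    area_m2 = np.asarray(area_m2, dtype=float)
    density = np.asarray(density, dtype=float)
    if np.any(area_m2 < 0) or np.any(density < 0):
        raise ValueError("area and density must be >= 0")
    out = area_m2 * density
    return float(out) if out.ndim == 0 else out


def interpolate_counts(count_days, counts, query_days):
    """Piecewise-linear interpolation of counts at query times.

    Queries outside the observed span raise rather than extrapolate.
    """
    count_days = np.asarray(count_days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    query_days = np.asarray(query_days, dtype=float)
    if count_days.size < 2:
        raise ValueError("need at least two count observations to interpolate")
    order = np.argsort(count_days)
    count_days, counts = count_days[order], counts[order]
    if np.any(query_days < count_days[0]) or np.any(query_days > count_days[-1]):
        raise ValueError(
            "query outside the observed count span "
            f"[{count_days[0]}, {count_days[-1]}]: extrapolation refused"
        )
    out = np.interp(query_days, count_days, counts)
    return float(out) if out.ndim == 0 else out


def daily_average_counts(frame: pd.DataFrame, value_col: str = "count") -> pd.DataFrame:
    """Average multiple same-day values into one value per civil day.

    ``frame`` needs a ``timestamp`` column (datetime-like) and a value
    column; single observations pass through unchanged.
    """
    f = frame.copy()
    f["date"] = pd.to_datetime(f["timestamp"]).dt.normalize()
    out = f.groupby("date", as_index=False)[value_col].mean()
    return out


def _windchill_log_prob(theta, t, w, r, h, density):
    c_w, c_r, c_h, t_c, b_0, sigma = theta
    for name, val in zip(WINDCHILL_PARAM_NAMES[:5], theta[:5]):
        lo, hi = WINDCHILL_PRIOR_BOUNDS[name]
        if not lo <= val <= hi:
            return -np.inf
    if sigma <= 0:
        return -np.inf
    lp = -0.5 * (sigma / 0.5) ** 2  # half-normal(0.5) prior on sigma_log
    t_a = t + c_w * w + c_r * r + c_h * h
    z = np.clip((t_a - t_c) / b_0, -700, 700)
    rho = RHO_MAX / (1.0 + np.exp(z))
    resid = np.log(density) - np.log(rho + 1e-12)
    n = density.size
    ll = -0.5 * np.sum(resid**2) / sigma**2 - n * np.log(sigma)
    return lp + ll


def _regression_start(t, w, r, h, density):
    """Initial guess from the multivariate log-linear regression.

    In the warm tail of the sigmoid, ln rho ~ ln rho_max - (T_a - t_c)/b_0,
    so the regression slopes of ln rho on (T, W, R, H) identify -1/b_0 and
    the coefficient ratios, and the intercept identifies t_c.
    """
    X = np.column_stack([np.ones_like(t), t, w, r, h])
    beta, *_ = np.linalg.lstsq(X, np.log(density), rcond=None)
    slope_t = beta[1]
    if slope_t >= -1e-6:  # no cooling response resolvable; fall back
        b_0, c_w, c_r, c_h = 5.0, -1.0, 0.01, -0.05
        t_c = np.median(t) - b_0
    else:
        b_0 = min(-1.0 / slope_t, 20.0)
        c_w = beta[2] / slope_t
        c_r = beta[3] / slope_t
        c_h = beta[4] / slope_t
        t_c = (beta[0] - math.log(RHO_MAX)) * b_0
    clip = lambda name, v: float(
        np.clip(v, WINDCHILL_PRIOR_BOUNDS[name][0] + 1e-6, WINDCHILL_PRIOR_BOUNDS[name][1] - 1e-6)
    )
    return np.array(
        [clip("c_w", c_w), clip("c_r", c_r), clip("c_h", c_h), clip("t_c", t_c), clip("b_0", b_0), 0.3]
    )


def fit_windchill(
    obs: pd.DataFrame,
    config: MCMCConfig | None = None,
    seed: int = 0,
) -> Posterior:
    """Calibrate the windchill parameters from paired density/weather data.

    ``obs`` needs columns temp_c, wind_ms, rad_wm2, rh_pct and density
    (animals/m^2, > 0).  The likelihood is lognormal in density with a
    jointly estimated log-scale noise ``sigma_log`` (half-normal prior);
    point estimates are posterior means.  The returned posterior's
    diagnostics include the training-set R^2 and mean geometric error of the
    density prediction at the posterior mean.
    """
    if config is None:
        config = MCMCConfig()
    required = {"temp_c", "wind_ms", "rad_wm2", "rh_pct", "density"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"missing columns in observations: {sorted(missing)}")
    if len(obs) < 20:
        raise ValueError("need at least 20 paired observations")
    t = obs["temp_c"].to_numpy(float)
    w = obs["wind_ms"].to_numpy(float)
    r = obs["rad_wm2"].to_numpy(float)
    h = obs["rh_pct"].to_numpy(float)
    density = obs["density"].to_numpy(float)
    if np.any(density <= 0):
        raise ValueError("densities must be positive")
    for name, arr in [("temp_c", t), ("wind_ms", w), ("rad_wm2", r), ("rh_pct", h)]:
        if np.ptp(arr) < 1e-9:
            import warnings

            warnings.warn(
                f"weather variable {name} is constant: its coefficient is "
                "not identifiable",
                RuntimeWarning,
                stacklevel=2,
            )

    def log_prob(theta):
        return _windchill_log_prob(theta, t, w, r, h, density)

    def sample_prior(rng, n):
        cols = [
            rng.uniform(*WINDCHILL_PRIOR_BOUNDS[name], size=n)
            for name in WINDCHILL_PARAM_NAMES[:5]
        ]
        cols.append(np.abs(rng.randn(n)) * 0.5 + 1e-3)
        return np.column_stack(cols)

    start = _regression_start(t, w, r, h, density)
    post = run_ensemble(
        log_prob,
        sample_prior,
        ndim=6,
        param_names=WINDCHILL_PARAM_NAMES,
        config=config,
        seed=seed,
        start=start,
    )
    mean = post.means
    fitted = WindchillParams(
        c_w=mean["c_w"], c_r=mean["c_r"], c_h=mean["c_h"],
        t_c=mean["t_c"], b_0=mean["b_0"],
    )
    rho_hat = density_from_weather(obs, fitted)
    post.diagnostics["train_r2"] = r_squared(rho_hat, density)
    post.diagnostics["train_geometric_error_pct"] = mean_geometric_error(rho_hat, density)
    return post


def assemble_density_observations(
    weather: pd.DataFrame,
    areas: pd.DataFrame,
    counts: pd.DataFrame,
    match_window_minutes: float = 30.0,
) -> pd.DataFrame:
    """Pair area measurements with weather and interpolated counts.

    ``counts`` has columns date, n_adults, n_chicks (weekly censuses of
    adults plus chicks); the total count at each area timestamp is linearly
    interpolated between the two nearest censuses.  Each area timestamp is
    matched to the nearest weather record within the window.  Returns a
    frame with the weather columns plus area_m2, count and density, ready
    for :func:`fit_windchill`.
    """
    c = counts.copy()
    total = c["n_adults"].fillna(0).to_numpy(float) + c["n_chicks"].fillna(0).to_numpy(float)
    count_t = pd.to_datetime(c["date"]).astype("int64") / 1e9 / 86400.0
    a = areas.sort_values("timestamp").reset_index(drop=True).copy()
    area_t = pd.to_datetime(a["timestamp"]).astype("int64") / 1e9 / 86400.0
    a["count"] = interpolate_counts(count_t, total, area_t)
    merged = pd.merge_asof(
        a,
        weather.sort_values("timestamp"),
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(minutes=match_window_minutes),
    )
    merged = merged.dropna(subset=["temp_c"])
    merged["density"] = merged["count"] / merged["area_m2"]
    return merged


def params_from_posterior(post: Posterior) -> WindchillParams:
    """Posterior-mean point estimate as a WindchillParams."""
    m = post.means
    return WindchillParams(c_w=m["c_w"], c_r=m["c_r"], c_h=m["c_h"], t_c=m["t_c"], b_0=m["b_0"])
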