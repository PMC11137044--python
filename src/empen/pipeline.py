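"""End-to-end census recipe: areas + weather -> density -> counts -> BP, F.

The four steps for a reliable breeding-pair estimate from late-season
imagery: (1) measure the colony area A on several dates between October and
December; (2) predict colony density rho from local weather at image time
with the windchill model; (3) convert to total individuals N = rho * A,
averaging multiple images per day; (4) fit the satellite-mode phenological
model to N(t) and read off the number of breeding pairs BP and the fledging
success F.  A conversion factor CF = BP / mean(A) summarises the season for
comparison with area-only censuses.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .astro import ColonySite
from .inference import (
    SUNRISE_RETURN_OFFSET_DAYS,
    CountSeries,
    MCMCConfig,
    fit_satellite,
    summarize,
)
from .phenology import PhenologyParams
from .windchill import WindchillParams, density_from_weather, interpolate_counts

logger = logging.getLogger("empen.pipeline")

__all__ = ["PipelineConfig", "areas_to_counts", "conversion_factor", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and settings for one end-to-end season run."""

    site: ColonySite
    windchill: WindchillParams
    defaults: PhenologyParams
    weather: pd.DataFrame  # timestamp, temp_c, wind_ms, rad_wm2, rh_pct
    areas: pd.DataFrame  # timestamp, area_m2
    start_year: int
    seed: int
    out_dir: Path | str | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    match_window_minutes: float = 30.0
    offset_days: float = SUNRISE_RETURN_OFFSET_DAYS
    cf_window: tuple[float, float] | None = None  # season-day window for CF areas
    exclude_area_dates: tuple[str, ...] = ()  # explicit outlier exclusion


def areas_to_counts(
    areas: pd.DataFrame,
    weather: pd.DataFrame,
    wp: WindchillParams,
    start_year: int,
    match_window_minutes: float = 30.0,
) -> tuple[CountSeries, list]:
    """Windchill-convert colony areas to a daily total-count series.

    Each area timestamp is matched to the nearest weather record within the
    matching window; unmatched timestamps are listed and skipped with a
    warning.  Same-day counts are averaged.  Returns the count series and
    the list of skipped timestamps.
    """
    if len(weather) == 0:
        raise ValueError("weather stream is empty: cannot predict colony density")
    if len(areas) == 0:
        raise ValueError("area stream is empty: nothing to convert")
    a = areas.sort_values("timestamp").reset_index(drop=True).copy()
    w = weather.sort_values("timestamp").reset_index(drop=True)
    merged = pd.merge_asof(
        a,
        w,
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(minutes=match_window_minutes),
        suffixes=("", "_wx"),
    )
    unmatched = merged["temp_c"].isna()
    skipped = merged.loc[unmatched, "timestamp"].tolist()
    if skipped:
        warnings.warn(
            f"{len(skipped)} area timestamps had no weather record within "
            f"{match_window_minutes:g} min and were skipped: "
            + ", ".join(str(t) for t in skipped[:5]),
            RuntimeWarning,
            stacklevel=2,
        )
    merged = merged[~unmatched]
    rho = density_from_weather(merged, wp)
    counts = rho * merged["area_m2"].to_numpy(float)
    day_dates = pd.to_datetime(merged["timestamp"]).dt.normalize()
    daily = (
        pd.DataFrame({"date": day_dates, "count": counts})
        .groupby("date", as_index=False)["count"]
        .mean()
    )
    from .io import timestamps_to_season_days

    days = timestamps_to_season_days(daily["date"], start_year)
    series = CountSeries(
        days=days, counts=daily["count"].to_numpy(float), kind="total", start_year=start_year
    )
    return series, skipped


def conversion_factor(bp: float, areas) -> float:
    """Breeding pairs per square meter: CF = BP / mean(A)."""
    areas = np.asarray(areas, dtype=float)
    if bp <= 0:
        raise ValueError("BP must be positive")
    if areas.size == 0:
        raise ValueError("no areas supplied")
    mean_area = float(np.mean(areas))
    if mean_area <= 0:
        raise ValueError("mean area must be positive")
    return float(bp) / mean_area


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the four-step recipe; deterministic given ``cfg.seed``.

    Returns a report dict (BP and fledged chicks with 1-sigma errors, CF,
    diagnostics) and, if ``cfg.out_dir`` is set, writes counts.csv,
    posterior.csv, summary.json and report.md plus a run manifest.
    """
    logger.info(
        "pipeline start: site=%s start_year=%d seed=%d n_areas=%d n_weather=%d",
        cfg.site.name, cfg.start_year, cfg.seed, len(cfg.areas), len(cfg.weather),
    )
    areas = cfg.areas
    if cfg.exclude_area_dates:
        excl = pd.to_datetime(pd.Series(list(cfg.exclude_area_dates))).dt.normalize()
        mask = pd.to_datetime(areas["timestamp"]).dt.normalize().isin(set(excl))
        logger.info("excluding %d area rows by configured dates", int(mask.sum()))
        areas = areas[~mask]

    series, skipped = areas_to_counts(
        areas, cfg.weather, cfg.windchill, cfg.start_year, cfg.match_window_minutes
    )
    logger.info("areas_to_counts: %d daily points (%d skipped)", len(series), len(skipped))

    post = fit_satellite(
        series,
        site=cfg.site,
        fixed=cfg.defaults,
        config=cfg.mcmc,
        seed=cfg.seed,
        year=cfg.start_year,
        offset_days=cfg.offset_days,
    )
    logger.info(
        "satellite fit: BP=%.0f +/- %.0f, F=%.3f +/- %.3f",
        post.means["bp"], post.sds["bp"], post.means["f"], post.sds["f"],
    )

    window = cfg.cf_window
    if window is None:
        window = (cfg.defaults.t0, cfg.defaults.t0 + cfg.defaults.m + cfg.defaults.b)
    from .io import timestamps_to_season_days

    area_days = timestamps_to_season_days(areas["timestamp"], cfg.start_year)
    in_window = (area_days >= window[0]) & (area_days <= window[1])
    if not np.any(in_window):
        warnings.warn(
            "no area measurements inside the CF reference window "
            f"[{window[0]:.0f}, {window[1]:.0f}]; using all areas",
            RuntimeWarning,
            stacklevel=2,
        )
        in_window = np.ones(area_days.size, dtype=bool)
    cf = conversion_factor(float(post.means["bp"]), areas["area_m2"].to_numpy(float)[in_window])

    report = {
        "site": cfg.site.name,
        "start_year": cfg.start_year,
        "seed": cfg.seed,
        "n_count_days": len(series),
        "skipped_area_timestamps": [str(t) for t in skipped],
        "bp_mean": float(post.means["bp"]),
        "bp_sd": float(post.sds["bp"]),
        "f_mean": float(post.means["f"]),
        "f_sd": float(post.sds["f"]),
        "fledged_mean": float(post.derived["fledged"].mean()),
        "fledged_sd": float(post.derived["fledged"].std(ddof=1)),
        "conversion_factor_bp_per_m2": cf,
        "diagnostics": dict(post.diagnostics),
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"day": series.days, "count": series.counts}).to_csv(
            out / "counts.csv", index=False
        )
        post.samples.to_csv(out / "posterior.csv", index=False)
        summary = summarize(post, data=series, fixed=cfg.defaults)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "report": {k: v for k, v in report.items() if k != "diagnostics"},
                    "coverage_1sd": summary.get("coverage_1sd"),
                    "r2": summary.get("r2"),
                    "mean_geometric_error_pct": summary.get("mean_geometric_error_pct"),
                    "diagnostics": report["diagnostics"],
                },
                indent=2,
                default=str,
            )
        )
        _write_report_md(out / "report.md", report)
        from .io import write_manifest

        write_manifest(out, "run-pipeline", cfg.seed, report)
        logger.info("pipeline outputs written to %s", out)
    return report


def _write_report_md(path: Path, report: dict) -> None:
    lines = [
        f"# Season report: {report['site']} {report['start_year']}",
        "",
        f"- breeding pairs (BP): {report['bp_mean']:.0f} +/- {report['bp_sd']:.0f}",
        f"- fledging success (F): {report['f_mean']:.3f} +/- {report['f_sd']:.3f}",
        f"- fledged chicks: {report['fledged_mean']:.0f} +/- {report['fledged_sd']:.0f}",
        f"- conversion factor CF: {report['conversion_factor_bp_per_m2']:.3f} pairs/m^2",
        f"- daily count points used: {report['n_count_days']}",
        f"- seed: {report['seed']}",
        "",
    ]
    path.write_text("\n".join(lines))
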