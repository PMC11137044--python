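"""CSV/YAML readers and writers, season-day conversion, run manifests.

All CSV dialects are plain ISO-8601 text with a leading ``#`` comment line
stating the season-day convention: day-of-year counted from January 1 of
the season's starting calendar year, with the season running March 1
(day 60) to February 28 (day 424).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .astro import ColonySite
from .inference import CountSeries
from .phenology import PhenologyParams
from .windchill import WindchillParams

__all__ = [
    "read_counts",
    "read_weather",
    "read_areas",
    "write_counts",
    "write_weather",
    "write_areas",
    "counts_to_series",
    "timestamps_to_season_days",
    "infer_season_start_year",
    "load_site",
    "load_phenology_params",
    "load_windchill_params",
    "save_params",
    "RunManifest",
    "write_manifest",
]

_HEADER = (
    "# season days count from Jan 1 of the season's starting year; "
    "the season runs Mar 1 (day 60) to Feb 28 (day 424)\n"
)

WEATHER_COLUMNS = ["timestamp", "temp_c", "wind_ms", "rad_wm2", "rh_pct"]
AREA_COLUMNS = ["timestamp", "area_m2"]
COUNT_COLUMNS = ["date", "n_adults", "n_chicks"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _named_row_error(path, df: pd.DataFrame, bad: pd.Series, message: str) -> None:
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(f"{path}: {message} in rows {rows}")


def read_counts(path) -> pd.DataFrame:
    """Read a counts CSV (date, n_adults, n_chicks; chicks may be empty)."""
    df = _read_csv(path, COUNT_COLUMNS[:2])
    if "n_chicks" not in df.columns:
        df["n_chicks"] = np.nan
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable dates ({exc})") from exc
    _named_row_error(path, df, df["n_adults"] < 0, "negative adult count")
    _named_row_error(path, df, df["n_chicks"].fillna(0) < 0, "negative chick count")
    return df.sort_values("date").reset_index(drop=True)


def read_weather(path) -> pd.DataFrame:
    """Read a weather CSV (timestamp, temp_c, wind_ms, rad_wm2, rh_pct)."""
    df = _read_csv(path, WEATHER_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    _named_row_error(path, df, df["wind_ms"] < 0, "negative wind speed")
    _named_row_error(path, df, df["rad_wm2"] < 0, "negative solar radiation")
    _named_row_error(
        path, df, (df["rh_pct"] < 0) | (df["rh_pct"] > 100), "humidity outside [0, 100] %"
    )
    return df.sort_values("timestamp").reset_index(drop=True)


def read_areas(path) -> pd.DataFrame:
    """Read an areas CSV (timestamp, area_m2)."""
    df = _read_csv(path, AREA_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    _named_row_error(path, df, df["area_m2"] <= 0, "non-positive area")
    return df.sort_values("timestamp").reset_index(drop=True)


def _write_csv(df: pd.DataFrame, path, columns: list[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False, columns=columns, lineterminator="\n")


def write_counts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    _write_csv(out, path, COUNT_COLUMNS)


def write_weather(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    _write_csv(out, path, WEATHER_COLUMNS)


def write_areas(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    _write_csv(out, path, AREA_COLUMNS)


def infer_season_start_year(timestamps) -> int:
    """Season starting year: the year of March 1 preceding the first record."""
    first = pd.to_datetime(pd.Series(timestamps)).min()
    return int(first.year if first.month >= 3 else first.year - 1)


def timestamps_to_season_days(timestamps, start_year: int) -> np.ndarray:
    """Continuous day-of-year of the season's starting calendar year."""
    ts = pd.to_datetime(pd.Series(timestamps))
    origin = pd.Timestamp(start_year, 1, 1)
    return ((ts - origin) / pd.Timedelta(days=1)).to_numpy() + 1.0


def counts_to_series(
    df: pd.DataFrame, kind: str = "adults_only", start_year: int | None = None
) -> CountSeries:
    """Turn a counts frame into the series the fitting modes consume.

    ``adults_only`` uses n_adults; ``total`` uses n_adults + n_chicks
    (missing chick entries count as zero).
    """
    if start_year is None:
        start_year = infer_season_start_year(df["date"])
    days = timestamps_to_season_days(df["date"], start_year)
    if kind == "adults_only":
        counts = df["n_adults"].to_numpy(float)
    else:
        counts = (df["n_adults"].fillna(0) + df["n_chicks"].fillna(0)).to_numpy(float)
    return CountSeries(days=days, counts=counts, kind=kind, start_year=start_year)


def load_site(path) -> ColonySite:
    """Site YAML: keys name, lat_deg, lon_deg."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ColonySite(name=cfg["name"], latitude=float(cfg["lat_deg"]), longitude=float(cfg["lon_deg"]))


def load_phenology_params(path) -> PhenologyParams:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(PhenologyParams)}
    return PhenologyParams(**{k: float(v) for k, v in cfg.items() if k in fields})


def load_windchill_params(path) -> WindchillParams:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(WindchillParams)}
    return WindchillParams(**{k: float(v) for k, v in cfg.items() if k in fields})


def save_params(params, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


def packaged_satellite_defaults() -> PhenologyParams:
    """The shipped colony-typical parameter set for satellite mode."""
    from importlib.resources import files

    path = files("empen").joinpath("data/satellite_defaults.yaml")
    cfg = yaml.safe_load(path.read_text())
    fields = {f.name for f in dataclasses.fields(PhenologyParams)}
    return PhenologyParams(**{k: float(v) for k, v in cfg.items() if k in fields})


@dataclasses.dataclass
class RunManifest:
    """Provenance record written for every CLI run."""

    command: str
    seed: int | None
    package_version: str
    started_utc: str
    config_hash: str
    input_checksums: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, seed: int | None, config: dict, inputs=()) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        seed=seed,
        package_version=__version__,
        started_utc=dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        input_checksums={str(p): _sha256(p) for p in inputs if Path(p).exists()},
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json() + "\n")
    return path
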