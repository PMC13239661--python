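"""Data interchange: track CSV dialects, projection, configuration, fixtures.

Two track formats are supported:

* planar CSV with header ``individual,t,x,y[,error_sd]`` (seconds, meters);
* Movebank-dialect CSV with ``timestamp,location-long,location-lat,
  individual-local-identifier`` and UTC ISO-8601 timestamps, projected to
  planar meters with an azimuthal-equidistant projection about the dataset
  centroid (adequate for the sub-continental extents of home-range data).

Configuration is YAML (or the JSON equivalent) with strict key checking:
unknown keys are errors so typos fail fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import CorruptionSpec
from .models import (
    ModelKind,
    MovementModel,
    PopulationModel,
    SamplingSchedule,
    Track,
    simulate_track,
    true_area,
    true_mean_speed,
)
from .units import DAY, HOUR, MINUTE, parse_duration

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_movebank_csv",
    "write_movebank_csv",
    "project_lonlat",
    "unproject_xy",
    "ProjectConfig",
    "load_config",
    "make_fixtures",
]

EARTH_RADIUS = 6_371_008.8  # mean Earth radius (m)

MOVEBANK_COLUMNS = (
    "timestamp",
    "location-long",
    "location-lat",
    "individual-local-identifier",
)


# ----------------------------------------------------------------------
# planar CSV


def write_tracks(tracks: Sequence[Track], path) -> None:
    """Write tracks as planar CSV ``individual,t,x,y[,error_sd]``."""
    frames = []
    with_err = any(t.error_sd is not None for t in tracks)
    for t in tracks:
        d = {"individual": t.individual_id, "t": t.times, "x": t.x, "y": t.y}
        if with_err:
            d["error_sd"] = t.error_sd if t.error_sd is not None else np.zeros(len(t))
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    """Read planar CSV tracks (see :func:`write_tracks`)."""
    df = pd.read_csv(path)
    for col in ("individual", "t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    tracks = []
    for ind, grp in df.groupby("individual", sort=True):
        grp = grp.sort_values("t")
        if grp["t"].duplicated().any():
            rows = grp.index[grp["t"].duplicated()].tolist()
            raise ValueError(f"duplicate times for individual {ind!r} at rows {rows}")
        err = grp["error_sd"].to_numpy() if "error_sd" in grp.columns else None
        tracks.append(
            Track(
                str(ind),
                grp["t"].to_numpy(float),
                grp["x"].to_numpy(float),
                grp["y"].to_numpy(float),
                error_sd=err,
            )
        )
    return tracks


# ----------------------------------------------------------------------
# Movebank dialect with local projection


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical azimuthal-equidistant projection about (lon0, lat0) -> meters."""
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cosc, -1.0, 1.0))
    with np.errstate(invalid="ignore"):
        k = np.where(c > 1e-12, c / np.sin(c), 1.0)
    x = EARTH_RADIUS * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def unproject_xy(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_lonlat`."""
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            rho > 1e-9,
            np.arcsin(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / rho),
            phi0,
        )
        lam = lam0 + np.where(
            rho > 1e-9,
            np.arctan2(
                x * np.sin(c),
                rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
            ),
            0.0,
        )
    return np.degrees(lam), np.degrees(phi)


def read_movebank_csv(path, origin_lonlat: Optional[tuple[float, float]] = None) -> list[Track]:
    """Read Movebank-dialect CSV and project to planar meters.

    Timestamps must be timezone-aware UTC ISO-8601 (naive timestamps are
    rejected: silent timezone drift corrupts sampling intervals).  The
    projection origin defaults to the dataset centroid (which then maps to
    (0, 0)); pass ``origin_lonlat`` to reuse a known origin, e.g. for exact
    round-trips with :func:`write_movebank_csv`.
    """
    df = pd.read_csv(path)
    for col in MOVEBANK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=False, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamp: {exc}") from exc
    if ts.dt.tz is None:
        raise ValueError(
            "naive timestamps rejected: use UTC ISO-8601 with offset (e.g. "
            "2020-01-01T00:00:00+00:00)"
        )
    ts = ts.dt.tz_convert("UTC")
    seconds = ts.astype("int64").to_numpy() / 1e9

    lon = df["location-long"].to_numpy(float)
    lat = df["location-lat"].to_numpy(float)
    if origin_lonlat is None:
        lon0, lat0 = float(np.mean(lon)), float(np.mean(lat))
    else:
        lon0, lat0 = origin_lonlat
    x, y = project_lonlat(lon, lat, lon0, lat0)

    work = pd.DataFrame(
        {
            "individual": df["individual-local-identifier"].astype(str),
            "t": seconds,
            "x": x,
            "y": y,
            "row": np.arange(len(df)),
        }
    )
    if "dop" in df.columns:
        work["dop"] = df["dop"].to_numpy(float)
    tracks = []
    for ind, grp in work.groupby("individual", sort=True):
        grp = grp.sort_values(["t", "row"])
        dup = grp["t"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate timestamps for individual {ind!r} at input rows "
                f"{grp.loc[dup, 'row'].tolist()}"
            )
        tracks.append(
            Track(str(ind), grp["t"].to_numpy(), grp["x"].to_numpy(), grp["y"].to_numpy())
        )
    return tracks


def write_movebank_csv(
    tracks: Sequence[Track], path, origin_lonlat: tuple[float, float] = (0.0, 0.0)
) -> None:
    """Export tracks as Movebank-dialect CSV about a lon/lat origin."""
    lon0, lat0 = origin_lonlat
    rows = []
    for t in tracks:
        lon, lat = unproject_xy(t.x, t.y, lon0, lat0)
        ts = pd.to_datetime(t.times, unit="s", utc=True)
        rows.append(
            pd.DataFrame(
                {
                    "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
                    "location-long": lon,
                    "location-lat": lat,
                    "individual-local-identifier": t.individual_id,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ----------------------------------------------------------------------
# configuration


@dataclass
class ProjectConfig:
    """Validated study-design configuration."""

    population: PopulationModel
    durations: list[float]  # seconds
    intervals: list[float]  # seconds
    m_values: list[int]
    replicates: int = 10
    seed: int = 0
    targets: tuple[str, ...] = ("area",)
    error_threshold: float = 5.0
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    output_dir: Path = Path("trackdesign-output")


_POP_KEYS = {"kind", "tau_p", "tau_v", "sigma", "var_log", "center_dispersion"}
_CORR_KEYS = {"fix_success", "failure_hazard", "storage_cap", "error_rms"}
_TOP_KEYS = {"population", "design", "corruption", "output_dir"}
_DESIGN_KEYS = {"durations", "intervals", "m", "replicates", "seed", "targets", "threshold"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def load_config(path) -> ProjectConfig:
    """Load and validate a YAML/JSON study configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    if "population" not in cfg or "design" not in cfg:
        raise ValueError("config requires 'population' and 'design' blocks")

    p = cfg["population"]
    _check_keys(p, _POP_KEYS, "population")
    kind = ModelKind(p.get("kind", "OUF"))
    tau_p = parse_duration(p.get("tau_p", 0.0))
    tau_v = parse_duration(p.get("tau_v", 0.0))
    sigma = float(p.get("sigma", 1.0))
    if kind is ModelKind.OUF:
        proto = MovementModel(kind, tau_p=tau_p, tau_v=tau_v, sigma=sigma)
    elif kind is ModelKind.OU:
        proto = MovementModel(kind, tau_p=tau_p, sigma=sigma)
    else:
        proto = MovementModel(kind, sigma=sigma)
    var = p.get("var_log", 0.0)
    cov = np.diag(np.broadcast_to(np.asarray(var, float), (3,)))
    pop = PopulationModel.from_prototype(
        proto, cov, center_dispersion=float(p.get("center_dispersion", 0.0))
    )

    d = cfg["design"]
    _check_keys(d, _DESIGN_KEYS, "design")
    durations = [parse_duration(v) for v in d["durations"]]
    intervals = [parse_duration(v) for v in d["intervals"]]
    m_values = [int(v) for v in d["m"]]
    targets = tuple(d.get("targets", ["area"]))

    corr = CorruptionSpec()
    if "corruption" in cfg:
        c = cfg["corruption"]
        _check_keys(c, _CORR_KEYS, "corruption")
        corr = CorruptionSpec(
            fix_success=float(c.get("fix_success", 1.0)),
            failure_hazard=float(c.get("failure_hazard", 0.0)),
            storage_cap=c.get("storage_cap"),
            error_rms=float(c.get("error_rms", 0.0)),
        )

    return ProjectConfig(
        population=pop,
        durations=durations,
        intervals=intervals,
        m_values=m_values,
        replicates=int(d.get("replicates", 10)),
        seed=int(d.get("seed", 0)),
        targets=targets,
        error_threshold=float(d.get("threshold", 5.0)),
        corruption=corr,
        output_dir=Path(cfg.get("output_dir", "trackdesign-output")),
    )


# ----------------------------------------------------------------------
# fixture generator


def make_fixtures(seed: int, outdir) -> dict:
    """Write the seeded fixture bundle; returns the manifest.

    (a) a homogeneous 10-individual OUF population (tau_p = 1 day, tau_v =
    30 min, sigma = 1 km**2) sampled on a 16-day, 30-minute schedule;
    (b) a heterogeneous variant with log-parameter variances of 0.25;
    (c) a Movebank-dialect export of (a).  The manifest records the
    closed-form true area and mean speed for both populations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proto = MovementModel(ModelKind.OUF, tau_p=1 * DAY, tau_v=30 * MINUTE, sigma=1e6)
    schedule = SamplingSchedule(duration=16 * DAY, interval=30 * MINUTE)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2025]))

    homogeneous = [
        simulate_track(proto, schedule, rng, individual_id=f"homog{i:02d}")
        for i in range(10)
    ]
    write_tracks(homogeneous, outdir / "homogeneous_tracks.csv")
    write_movebank_csv(
        homogeneous, outdir / "homogeneous_movebank.csv", origin_lonlat=(31.5, -24.0)
    )

    from .models import sample_population  # local import to avoid cycle confusion

    pop_het = PopulationModel.from_prototype(proto, np.diag([0.25, 0.25, 0.25]))
    models = sample_population(pop_het, 10, rng)
    heterogeneous = [
        simulate_track(m, schedule, rng, individual_id=f"heterog{i:02d}")
        for i, m in enumerate(models)
    ]
    write_tracks(heterogeneous, outdir / "heterogeneous_tracks.csv")

    from .design import population_truth

    pop_hom = PopulationModel.from_prototype(proto)
    manifest = {
        "seed": seed,
        "prototype": {
            "kind": "OUF",
            "tau_p_s": proto.tau_p,
            "tau_v_s": proto.tau_v,
            "sigma_m2": proto.sigma,
        },
        "schedule": {"duration_s": schedule.duration, "interval_s": schedule.interval},
        "homogeneous": {
            "true_area_m2": true_area(proto),
            "true_mean_speed_mps": true_mean_speed(proto),
        },
        "heterogeneous": {
            "var_log": 0.25,
            "true_mean_area_m2": population_truth(pop_het, "area"),
            "true_mean_speed_mps": population_truth(pop_het, "speed"),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
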