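"""Domain types and file I/O: sample tables, trajectory endpoints, results.

A *sample table* is delimited text with one row per site-day:
``date,site,pm25,Nap,...,IcdP[,temp,pressure,rh]`` — PM2.5 in ug/m3,
species concentrations in ng/m3.  Values below the per-species method
detection limit (MDL) are substituted according to a censoring policy
and flagged.

Back-trajectories are consumed in the HYSPLIT ``tdump`` endpoint layout
(header block, then one endpoint per line).  A sidecar CSV
(``traj,date,site``) maps trajectory numbers to arrival site-days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .species import SPECIES_ORDER, SpeciesCatalog

__all__ = [
    "SchemaError",
    "ValidationError",
    "SampleRecord",
    "TrajectorySet",
    "CENSOR_POLICIES",
    "apply_censoring",
    "load_samples",
    "records_to_frame",
    "frame_to_records",
    "save_samples",
    "load_trajectories",
    "write_tdump",
    "write_results",
]

log = logging.getLogger(__name__)

_META_COLS = ("date", "site", "pm25")
_OPT_COLS = ("temp", "pressure", "rh")


class SchemaError(ValueError):
    """The input file does not have the documented column layout."""


class ValidationError(ValueError):
    """A row violates a value constraint (negative, non-numeric, ...)."""


@dataclass
class SampleRecord:
    """One site-day of PM2.5 mass and 16 PAH concentrations.

    ``conc`` holds censor-substituted values for species flagged in
    ``censored``; meteorology fields are optional.
    """

    date: pd.Timestamp
    site: str
    pm25: float
    conc: dict[str, float]
    censored: dict[str, bool] = field(default_factory=dict)
    temp: float | None = None
    pressure: float | None = None
    rh: float | None = None

    def __post_init__(self) -> None:
        if self.pm25 < 0:
            raise ValidationError(f"{self.date} {self.site}: pm25 < 0")
        missing = set(SPECIES_ORDER) - set(self.conc)
        if missing:
            raise SchemaError(f"record missing species {sorted(missing)}")
        for code, v in self.conc.items():
            if v < 0:
                raise ValidationError(
                    f"{self.date} {self.site}: negative concentration for {code}"
                )
        if not self.censored:
            self.censored = {c: False for c in SPECIES_ORDER}

    def total_pah(self) -> float:
        """Sum of the 16 species concentrations (ng/m3)."""
        return float(sum(self.conc[c] for c in SPECIES_ORDER))


# censoring policy -> substitution value for a below-MDL observation
CENSOR_POLICIES = ("substitute-mdl", "substitute-half-mdl", "leave-zero")


def _substitution(policy: str, mdl: float) -> float:
    if policy == "substitute-mdl":
        return mdl
    if policy == "substitute-half-mdl":
        return mdl / 2.0
    if policy == "leave-zero":
        return 0.0
    raise ValueError(f"unknown censoring policy {policy!r}; choose from {CENSOR_POLICIES}")


def apply_censoring(
    conc: Mapping[str, float],
    catalog: SpeciesCatalog,
    policy: str = "substitute-mdl",
    censored: Mapping[str, bool] | None = None,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Substitute below-MDL values per *policy*; idempotent.

    A value already flagged keeps its flag; an unflagged value strictly
    below the MDL is replaced by the policy's substitution constant and
    flagged.  Applying the same policy twice changes nothing.
    """
    out_c: dict[str, float] = {}
    out_f: dict[str, bool] = {}
    for code in SPECIES_ORDER:
        v = float(conc[code])
        mdl = catalog[code].mdl
        flag = bool(censored[code]) if censored is not None else False
        if flag or v < mdl:
            sub = _substitution(policy, mdl)
            # an already-substituted value is left alone
            out_c[code] = v if flag else sub
            out_f[code] = True
        else:
            out_c[code] = v
            out_f[code] = False
    return out_c, out_f


def load_samples(
    path: str | Path,
    catalog: SpeciesCatalog,
    censor_policy: str = "substitute-mdl",
) -> list[SampleRecord]:
    """Read a sample table, validate it, and apply the censoring policy.

    Raises :class:`SchemaError` when a species column is missing and
    :class:`ValidationError` (naming row number and species) for
    negative or non-numeric concentrations.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (*_META_COLS, *SPECIES_ORDER) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        conc: dict[str, float] = {}
        for code in SPECIES_ORDER:
            try:
                v = float(row[code])
            except (TypeError, ValueError):
                raise ValidationError(f"row {rowno}: non-numeric value for {code}")
            if not np.isfinite(v):
                raise ValidationError(f"row {rowno}: non-finite value for {code}")
            if v < 0:
                raise ValidationError(f"row {rowno}: negative concentration for {code}")
            conc[code] = v
        conc, flags = apply_censoring(conc, catalog, censor_policy)
        try:
            pm25 = float(row["pm25"])
        except (TypeError, ValueError):
            raise ValidationError(f"row {rowno}: non-numeric pm25")
        if pm25 < 0:
            raise ValidationError(f"row {rowno}: negative pm25")
        opt = {
            k: (float(row[k]) if k in df.columns and pd.notna(row[k]) else None)
            for k in _OPT_COLS
        }
        records.append(
            SampleRecord(
                date=pd.Timestamp(row["date"]),
                site=str(row["site"]),
                pm25=pm25,
                conc=conc,
                censored=flags,
                temp=opt["temp"],
                pressure=opt["pressure"],
                rh=opt["rh"],
            )
        )
    return records


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabular view of sample records with the documented column order."""
    rows = []
    any_met = any(r.temp is not None for r in records)
    for r in records:
        row: dict[str, object] = {
            "date": r.date.strftime("%Y-%m-%d"),
            "site": r.site,
            "pm25": r.pm25,
        }
        row.update({c: r.conc[c] for c in SPECIES_ORDER})
        if any_met:
            row["temp"] = r.temp
            row["pressure"] = r.pressure
            row["rh"] = r.rh
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, catalog: SpeciesCatalog,
                     censor_policy: str = "substitute-mdl") -> list[SampleRecord]:
    """Inverse of :func:`records_to_frame` (re-applies the censoring policy)."""
    records = []
    for _, row in df.iterrows():
        conc = {c: float(row[c]) for c in SPECIES_ORDER}
        conc, flags = apply_censoring(conc, catalog, censor_policy)
        records.append(SampleRecord(
            date=pd.Timestamp(row["date"]), site=str(row["site"]),
            pm25=float(row["pm25"]), conc=conc, censored=flags,
            temp=float(row["temp"]) if "temp" in df.columns and pd.notna(row.get("temp")) else None,
            pressure=float(row["pressure"]) if "pressure" in df.columns and pd.notna(row.get("pressure")) else None,
            rh=float(row["rh"]) if "rh" in df.columns and pd.notna(row.get("rh")) else None,
        ))
    return records


def save_samples(records: Sequence[SampleRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectorySet:
    """Parsed back-trajectory endpoints keyed to arrival site-days.

    ``endpoints`` columns: traj (id), date (arrival day), site, step,
    age_h, lat, lon.
    """

    endpoints: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ep = self.endpoints
        if len(ep):
            if not ((ep["lat"] >= -90) & (ep["lat"] <= 90)).all():
                raise ValidationError("latitude outside [-90, 90]")
            if not ((ep["lon"] >= -180) & (ep["lon"] <= 180)).all():
                raise ValidationError("longitude outside [-180, 180]")
            for tid, grp in ep.groupby("traj"):
                steps = grp["step"].to_numpy()
                if not np.array_equal(steps, np.arange(len(steps))):
                    raise ValidationError(f"trajectory {tid}: step indices not consecutive")

    def __len__(self) -> int:
        return int(self.endpoints["traj"].nunique()) if len(self.endpoints) else 0

    @property
    def n_endpoints(self) -> int:
        return len(self.endpoints)


_EP_COLS = ["traj", "date", "site", "step", "age_h", "lat", "lon"]


def _tdump_year(y: int) -> int:
    return 2000 + y if y < 70 else 1900 + y


def load_trajectories(
    path: str | Path,
    arrivals: str | Path | pd.DataFrame | None = None,
) -> TrajectorySet:
    """Parse a HYSPLIT tdump endpoint file.

    *arrivals* is an optional sidecar CSV (or frame) with columns
    ``traj,date,site`` fixing the arrival site-day of each trajectory;
    without it the arrival date is taken from the age-0 endpoint
    timestamp and the site is left blank.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        log.warning("%s: empty trajectory file", path)
        return TrajectorySet(pd.DataFrame(columns=_EP_COLS))

    def toks(i: int) -> list[str]:
        return lines[i].split()

    try:
        ngrids = int(toks(0)[0])
        pos = 1 + ngrids
        ntraj = int(toks(pos)[0])
        pos += 1 + ntraj
        pos += 1  # diagnostic-variable record
    except (IndexError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed tdump header") from exc

    rows = []
    counters: dict[int, int] = {}
    for lineno in range(pos, len(lines)):
        t = lines[lineno].split()
        if not t:
            continue
        if len(t) < 12:
            raise ValidationError(f"{path}: truncated endpoint line {lineno + 1}")
        tid = int(t[0])
        y, mo, d = int(t[2]), int(t[3]), int(t[4])
        age = float(t[8])
        lat, lon = float(t[9]), float(t[10])
        step = counters.get(tid, 0)
        counters[tid] = step + 1
        rows.append((tid, pd.Timestamp(_tdump_year(y), mo, d), "", step, age, lat, lon))

    if not rows:
        log.warning("%s: tdump file has an empty endpoint section", path)
        return TrajectorySet(pd.DataFrame(columns=_EP_COLS))

    ep = pd.DataFrame(rows, columns=_EP_COLS)
    # arrival day = age-0 endpoint's day, per trajectory
    arrival = ep.loc[ep["age_h"].abs().groupby(ep["traj"]).idxmin(), ["traj", "date"]]
    ep = ep.drop(columns="date").merge(arrival, on="traj")[_EP_COLS]
    if arrivals is not None:
        amap = arrivals if isinstance(arrivals, pd.DataFrame) else pd.read_csv(arrivals)
        amap = amap.assign(date=pd.to_datetime(amap["date"]), site=amap["site"].astype(str))
        ep = ep.drop(columns=["date", "site"]).merge(amap[["traj", "date", "site"]], on="traj")
        ep = ep[_EP_COLS]
    meta = {"n_trajectories": int(ep["traj"].nunique()),
            "run_length_h": float(ep["age_h"].abs().max())}
    return TrajectorySet(ep.sort_values(["traj", "step"]).reset_index(drop=True), meta)


def write_tdump(traj: TrajectorySet, path: str | Path,
                arrivals_path: str | Path | None = None,
                height_m: float = 500.0) -> None:
    """Write endpoints in tdump layout (plus optional arrival sidecar CSV)."""
    ep = traj.endpoints
    ntraj = int(ep["traj"].nunique()) if len(ep) else 0
    out = [f"{1:6d}{1:6d}", f"{'SYNT':>8}{0:6d}{1:6d}{1:6d}{0:6d}",
           f"{ntraj:6d} BACKWARD OMEGA"]
    starts = ep.sort_values(["traj", "step"]).groupby("traj").first()
    for tid, s in starts.iterrows():
        d = s["date"]
        out.append(f"{d.year % 100:6d}{d.month:6d}{d.day:6d}{0:6d}"
                   f"{s['lat']:9.3f}{s['lon']:9.3f}{height_m:9.1f}")
    out.append(f"{1:6d} PRESSURE")
    for _, r in ep.sort_values(["traj", "step"]).iterrows():
        d = r["date"]
        out.append(
            f"{int(r['traj']):6d}{1:6d}{d.year % 100:6d}{d.month:6d}{d.day:6d}"
            f"{0:6d}{0:6d}{0:6d}{r['age_h']:8.1f}"
            f"{r['lat']:9.3f}{r['lon']:9.3f}{height_m:9.1f}{850.0:9.1f}"
        )
    Path(path).write_text("\n".join(out) + "\n")
    if arrivals_path is not None:
        amap = (ep.sort_values(["traj", "step"]).groupby("traj")
                .first().reset_index()[["traj", "date", "site"]])
        amap["date"] = pd.to_datetime(amap["date"]).dt.strftime("%Y-%m-%d")
        amap.to_csv(arrivals_path, index=False)


# ---------------------------------------------------------------------------
# result writing


def write_results(obj, outdir: str | Path, prefix: str = "") -> list[Path]:
    """Write a pipeline product as delimited-text tables.

    Any object exposing ``to_frames() -> {name: DataFrame}`` (FactorModel,
    RiskResult, PscfGrid, ...) is written as one CSV per frame; a list of
    :class:`SampleRecord` becomes ``samples.csv``; a bare DataFrame becomes
    ``<prefix or 'table'>.csv``.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames: dict[str, pd.DataFrame]
    if hasattr(obj, "to_frames"):
        frames = obj.to_frames()
    elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], SampleRecord):
        frames = {"samples": records_to_frame(obj)}
    elif isinstance(obj, pd.DataFrame):
        frames = {prefix or "table": obj}
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    written = []
    for name, df in frames.items():
        stem = f"{prefix}{name}" if prefix and name != prefix else name
        p = outdir / f"{stem}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
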