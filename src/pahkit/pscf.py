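"""Potential Source Contribution Function (PSCF) on a lat/lon grid.

For each grid cell, PSCF = m / n where n counts the trajectories with
at least one endpoint in the cell and m the subset arriving on
pollution days (receptor PM2.5 strictly above a threshold, default the
35 ug/m3 daily standard).  Each trajectory counts once per cell
regardless of how many endpoints fall inside (an endpoint-count mode is
available).  The weighted variant damps cells crossed by few
trajectories: WPSCF = W(n) * PSCF with a piecewise weight keyed to the
mean count over nonempty cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import SampleRecord, TrajectorySet

__all__ = [
    "PscfGrid",
    "flag_exceedance_days",
    "compute_pscf",
    "weight_pscf",
    "DEFAULT_WEIGHT_SCHEME",
]

log = logging.getLogger(__name__)

#: (multiple-of-mean lower bound, weight); applied top-down
DEFAULT_WEIGHT_SCHEME: tuple[tuple[float, float], ...] = (
    (3.0, 1.0),
    (1.5, 0.7),
    (1.0, 0.42),
    (0.0, 0.05),
)


@dataclass
class PscfGrid:
    """Gridded trajectory counts and (weighted) PSCF values.

    ``pscf`` is NaN (undefined) where n = 0, never 0 by fiat.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    n: np.ndarray
    m: np.ndarray
    pscf: np.ndarray
    threshold: float
    resolution: float
    wpscf: np.ndarray | None = None
    n_dropped: int = 0
    count_unit: str = "trajectory"

    def __post_init__(self) -> None:
        if (self.m > self.n).any():
            raise ValueError("m must not exceed n cellwise")

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def to_frames(self) -> dict[str, pd.DataFrame]:
        la, lo = np.meshgrid(np.arange(len(self.lat_centers)),
                             np.arange(len(self.lon_centers)), indexing="ij")
        df = pd.DataFrame({
            "lat_idx": la.ravel(), "lon_idx": lo.ravel(),
            "lat": np.repeat(self.lat_centers, len(self.lon_centers)),
            "lon": np.tile(self.lon_centers, len(self.lat_centers)),
            "n": self.n.ravel(), "m": self.m.ravel(),
            "pscf": self.pscf.ravel(),
        })
        if self.wpscf is not None:
            df["wpscf"] = self.wpscf.ravel()
        return {"pscf": df}


def flag_exceedance_days(
    records: Sequence[SampleRecord],
    threshold: float = 35.0,
) -> dict[tuple[pd.Timestamp, str], bool]:
    """(date, site) -> PM2.5 strictly above *threshold*."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return {(r.date, r.site): r.pm25 > threshold for r in records}


def compute_pscf(
    traj: TrajectorySet,
    flags: Mapping[tuple[pd.Timestamp, str], bool],
    resolution: float = 0.5,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    threshold: float = 35.0,
    count_unit: str = "trajectory",
) -> PscfGrid:
    """Bin endpoints on a *resolution*-degree grid and form PSCF = m/n.

    *bounds* is ((lat_min, lat_max), (lon_min, lon_max)); by default the
    grid auto-fits the endpoints with a one-cell margin.  Endpoints
    outside the domain are dropped (count logged).  ``count_unit``
    "trajectory" de-duplicates cell visits per trajectory; "endpoint"
    counts raw endpoints.
    """
    ep = traj.endpoints
    if not len(ep):
        raise ValueError("empty trajectory set")
    keys = list(zip(ep["date"], ep["site"]))
    missing = {k for k in keys if k not in flags}
    if missing:
        raise KeyError(f"no exceedance flag for arrival site-days, e.g. {next(iter(missing))}")

    if bounds is None:
        lat_lo = np.floor(ep["lat"].min() / resolution) * resolution - resolution
        lat_hi = np.ceil(ep["lat"].max() / resolution) * resolution + resolution
        lon_lo = np.floor(ep["lon"].min() / resolution) * resolution - resolution
        lon_hi = np.ceil(ep["lon"].max() / resolution) * resolution + resolution
    else:
        (lat_lo, lat_hi), (lon_lo, lon_hi) = bounds
    lat_edges = np.arange(lat_lo, lat_hi + resolution / 2, resolution)
    lon_edges = np.arange(lon_lo, lon_hi + resolution / 2, resolution)
    nlat, nlon = len(lat_edges) - 1, len(lon_edges) - 1

    li = np.searchsorted(lat_edges, ep["lat"].to_numpy(), side="right") - 1
    lj = np.searchsorted(lon_edges, ep["lon"].to_numpy(), side="right") - 1
    inside = (li >= 0) & (li < nlat) & (lj >= 0) & (lj < nlon)
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("dropped %d endpoints outside the grid domain", n_dropped)

    sub = pd.DataFrame({
        "traj": ep["traj"].to_numpy()[inside],
        "li": li[inside], "lj": lj[inside],
        "flag": np.array([flags[k] for k in keys])[inside],
    })
    if count_unit == "trajectory":
        sub = sub.drop_duplicates(["traj", "li", "lj"])
    elif count_unit != "endpoint":
        raise ValueError("count_unit must be 'trajectory' or 'endpoint'")

    n = np.zeros((nlat, nlon), dtype=int)
    m = np.zeros((nlat, nlon), dtype=int)
    np.add.at(n, (sub["li"], sub["lj"]), 1)
    np.add.at(m, (sub["li"][sub["flag"]], sub["lj"][sub["flag"]]), 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        pscf = np.where(n > 0, m / np.maximum(n, 1), np.nan)
    return PscfGrid(lat_edges, lon_edges, n, m, pscf,
                    threshold=threshold, resolution=resolution,
                    n_dropped=n_dropped, count_unit=count_unit)


def weight_pscf(
    grid: PscfGrid,
    scheme: Sequence[tuple[float, float]] = DEFAULT_WEIGHT_SCHEME,
) -> PscfGrid:
    """WPSCF = W(n) * PSCF; W keyed to the mean count over nonempty cells.

    Default scheme: W = 1.0 for n > 3*mean, 0.7 for n in (1.5*mean,
    3*mean], 0.42 for (mean, 1.5*mean], 0.05 for n <= mean.
    """
    nonempty = grid.n[grid.n > 0]
    mean_n = float(nonempty.mean()) if len(nonempty) else 0.0
    w = np.full(grid.n.shape, np.nan)
    for mult, weight in sorted(scheme, key=lambda t: -t[0]):
        sel = np.isnan(w) & (grid.n > mult * mean_n)
        w[sel] = weight
    w[np.isnan(w)] = sorted(scheme, key=lambda t: t[0])[0][1]
    grid.wpscf = w * grid.pscf
    return grid
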