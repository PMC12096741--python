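"""Summary statistics, limit exceedance, MW-class proportions, rank tests.

Quantiles use linear interpolation between order statistics; exceedance
uses the strict ``value > limit`` convention (a day exactly at the limit
does not exceed); rank tests use mid-ranks with tie-corrected variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SampleRecord, records_to_frame
from .species import SPECIES_ORDER, SpeciesCatalog

__all__ = [
    "ExceedanceReport",
    "summarize",
    "exceedance",
    "mw_proportions",
    "correlation_matrix",
    "compare_groups",
]

log = logging.getLogger(__name__)


@dataclass
class ExceedanceReport:
    """Count and rate of strict limit exceedances, by stratum."""

    limit: float
    field: str
    by: str
    table: pd.DataFrame  # columns: stratum, n_total, n_exceed, rate

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"exceedance": self.table.assign(limit=self.limit, field=self.field)}


def _value_series(records: Sequence[SampleRecord], field: str) -> pd.Series:
    df = records_to_frame(records)
    if field == "pm25":
        return df["pm25"]
    if field == "total_pah":
        return df[list(SPECIES_ORDER)].sum(axis=1)
    if field in SPECIES_ORDER or field in df.columns:
        return df[field]
    raise KeyError(f"unknown field {field!r}")


def _stratum(records: Sequence[SampleRecord], by: str) -> pd.Series:
    if by == "all":
        return pd.Series(["all"] * len(records))
    if by == "year":
        return pd.Series([r.date.year for r in records])
    if by == "site":
        return pd.Series([r.site for r in records])
    raise ValueError(f"stratum must be 'year', 'site' or 'all', got {by!r}")


def summarize(
    records: Sequence[SampleRecord],
    field: str = "total_pah",
    by: str = "year",
) -> pd.DataFrame:
    """Median and quartiles (P25, P75) of *field* per stratum.

    Quantile method: linear interpolation between order statistics.
    Empty strata are omitted with a warning.
    """
    values = _value_series(records, field)
    strata = _stratum(records, by)
    rows = []
    for key, grp in values.groupby(strata):
        v = grp.dropna().to_numpy()
        if len(v) == 0:
            log.warning("stratum %r has no observations; omitted", key)
            continue
        rows.append({
            "stratum": key, "n": len(v),
            "median": float(np.quantile(v, 0.5)),
            "p25": float(np.quantile(v, 0.25)),
            "p75": float(np.quantile(v, 0.75)),
        })
    return pd.DataFrame(rows)


def exceedance(
    records: Sequence[SampleRecord],
    limit: float,
    field: str = "pm25",
    by: str = "all",
) -> ExceedanceReport:
    """Strict-exceedance count and percentage rate per stratum.

    ``rate = round(100 * n_exceed / n_total, 2)``; a value exactly at
    the limit is not an exceedance.
    """
    if not limit > 0:
        raise ValueError("limit must be positive")
    values = _value_series(records, field)
    strata = _stratum(records, by)
    rows = []
    for key, grp in values.groupby(strata):
        n = int(len(grp))
        ne = int((grp > limit).sum())
        rows.append({"stratum": key, "n_total": n, "n_exceed": ne,
                     "rate": round(100.0 * ne / n, 2)})
    return ExceedanceReport(limit, field, by, pd.DataFrame(rows))


def mw_proportions(
    records: Sequence[SampleRecord],
    catalog: SpeciesCatalog,
    by: str = "year",
) -> pd.DataFrame:
    """Mass fractions of LMW / MMW / HMW species per stratum (sum to 1)."""
    df = records_to_frame(records)
    classes = catalog.mw_classes()
    strata = _stratum(records, by)
    rows = []
    for key, grp in df.groupby(strata):
        masses = {"LMW": 0.0, "MMW": 0.0, "HMW": 0.0}
        for c in SPECIES_ORDER:
            masses[classes[c]] += float(grp[c].sum())
        total = sum(masses.values())
        rows.append({"stratum": key,
                     **{k: (m / total if total > 0 else np.nan)
                        for k, m in masses.items()}})
    return pd.DataFrame(rows)


def correlation_matrix(
    records: Sequence[SampleRecord],
    variables: Sequence[str] = ("total_pah", "pm25", "temp", "pressure", "rh"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix with significance flags.

    Returns (rho, significant) frames; a constant variable gives NaN
    entries flagged non-significant rather than raising.
    """
    data = pd.DataFrame({v: _value_series(records, v) for v in variables})
    k = len(variables)
    rho = np.eye(k)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            pair = data.iloc[:, [i, j]].dropna()
            if len(pair) < 3 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                rho[i, j] = rho[j, i] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            sig[i, j] = sig[j, i] = bool(p < alpha)
    idx = list(variables)
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(sig, index=idx, columns=idx))


def compare_groups(
    records: Sequence[SampleRecord],
    grouping: str,
    field: str = "pm25",
) -> tuple[float, float]:
    """Rank-based location comparison across strata.

    Two groups: Mann-Whitney U (exact when both n <= 8 and tie-free,
    otherwise tie-corrected normal approximation without continuity
    correction).  More than two: Kruskal-Wallis H.  Returns
    (statistic, two-sided p).
    """
    values = _value_series(records, field)
    strata = _stratum(records, grouping)
    groups = [g.dropna().to_numpy() for _, g in values.groupby(strata)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two nonempty groups")
    if len(groups) == 2:
        a, b = groups
        if min(len(a), len(b)) < 2:
            log.warning("a group has <2 observations; exact small-sample path")
        pooled = np.concatenate([a, b])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (max(len(a), len(b)) <= 8 and tie_free) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=False)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
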