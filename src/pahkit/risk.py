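"""Toxic equivalency and Monte Carlo incremental lifetime cancer risk.

The BaP-equivalent concentration of a sample is

    TEQ = sum_i C_i * TEF_i        [ng/m3]

and the inhalation incremental lifetime cancer risk is

    ILCR = (TEQ * CSF * IR * EF * ED * CF) / (BW * AT)

with the dimensionally closed unit convention: TEQ ng/m3, cancer slope
factor CSF (kg*d)/mg (3.14 for BaP), inhalation rate IR m3/d, exposure
frequency EF d/a, exposure duration ED a, conversion factor CF 1e-6
mg/ng, body weight BW kg, averaging time AT d (25550 = 70 a).

The Monte Carlo assessment resamples daily TEQ values and draws the
exposure factors from configurable distributions (default: zero-
truncated normals for IR and BW with CV 0.2, fixed EF and ED), reports
the percentile summary, and scores per-input sensitivity by Spearman
rank correlation with a normalized variance-contribution share.  The
shipped adult/child exposure defaults are substitutable placeholders,
not authoritative handbook values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SampleRecord
from .species import SPECIES_ORDER, SpeciesCatalog

__all__ = [
    "Dist",
    "ExposureProfile",
    "RiskResult",
    "default_exposure_profile",
    "teq",
    "ilcr_point",
    "ilcr_mc",
    "sensitivity",
    "species_risk_shares",
    "ACCEPTABLE_RISK",
]

log = logging.getLogger(__name__)

#: EPA acceptable-risk reference line
ACCEPTABLE_RISK = 1e-6

PERCENTILE_KEYS = ("min", "P5", "P25", "median", "P75", "P95", "max")
_PCT = {"min": 0, "P5": 5, "P25": 25, "median": 50, "P75": 75, "P95": 95, "max": 100}


@dataclass(frozen=True)
class Dist:
    """A distribution spec for one exposure factor.

    kinds: ``point`` (value), ``truncnorm`` (mean, cv; truncated at 0),
    ``lognormal`` (mean, cv).
    """

    kind: str
    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "truncnorm", "lognormal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.mean <= 0:
            raise ValueError("distribution mean/value must be positive")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    @property
    def is_point(self) -> bool:
        return self.kind == "point" or self.cv == 0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.is_point:
            return np.full(n, self.mean)
        if self.kind == "truncnorm":
            sd = self.cv * self.mean
            a = (0.0 - self.mean) / sd
            return stats.truncnorm.rvs(a, np.inf, loc=self.mean, scale=sd,
                                       size=n, random_state=rng)
        sigma = np.sqrt(np.log(1 + self.cv**2))
        return rng.lognormal(np.log(self.mean) - 0.5 * sigma**2, sigma, n)


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor exposure factors (see module docstring for units)."""

    receptor: str
    ir: Dist
    ef: Dist
    ed: Dist
    bw: Dist
    csf: float = 3.14
    cf: float = 1e-6
    at: float = 25550.0

    def point_values(self) -> dict[str, float]:
        return {"ir": self.ir.mean, "ef": self.ef.mean,
                "ed": self.ed.mean, "bw": self.bw.mean}


def default_exposure_profile(receptor: str) -> ExposureProfile:
    """Placeholder adult/child profiles (configurable, not authoritative)."""
    if receptor == "adult":
        return ExposureProfile("adult",
                               ir=Dist("truncnorm", 15.7, 0.2),
                               ef=Dist("point", 350.0),
                               ed=Dist("point", 24.0),
                               bw=Dist("truncnorm", 60.6, 0.2))
    if receptor == "child":
        return ExposureProfile("child",
                               ir=Dist("truncnorm", 8.7, 0.2),
                               ef=Dist("point", 350.0),
                               ed=Dist("point", 6.0),
                               bw=Dist("truncnorm", 21.7, 0.2))
    raise ValueError("receptor must be 'adult' or 'child'")


@dataclass
class RiskResult:
    """Monte Carlo ILCR draws with percentile and sensitivity summaries."""

    receptor: str
    draws: np.ndarray
    percentiles: dict[str, float]
    sensitivity: pd.DataFrame
    n_iter: int
    seed: int | None
    inputs: pd.DataFrame = field(repr=False, default=None)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        pct = pd.DataFrame({
            "percentile": list(PERCENTILE_KEYS),
            "ilcr": [self.percentiles[k] for k in PERCENTILE_KEYS],
        })
        pct["receptor"] = self.receptor
        return {"risk_percentiles": pct, "risk_sensitivity": self.sensitivity}


def teq(record: SampleRecord, catalog: SpeciesCatalog) -> float:
    """BaP-equivalent concentration (ng/m3), linear in concentrations."""
    total = 0.0
    for code in SPECIES_ORDER:
        if code not in record.conc:
            raise KeyError(f"record lacks species {code}")
        total += record.conc[code] * catalog[code].tef
    return total


def ilcr_point(teq_value: float, *, csf: float = 3.14, ir: float = 15.7,
               ef: float = 350.0, ed: float = 24.0, bw: float = 60.6,
               cf: float = 1e-6, at: float = 25550.0) -> float:
    """Exact risk-formula evaluation at point values."""
    if bw <= 0 or at <= 0:
        raise ValueError("BW and AT must be strictly positive")
    return (teq_value * csf * ir * ef * ed * cf) / (bw * at)


def ilcr_mc(
    teq_samples: Sequence[float],
    profile: ExposureProfile,
    n_iter: int = 10_000,
    seed: int | None = 0,
    teq_mode: str = "empirical",
) -> RiskResult:
    """Monte Carlo ILCR: per iteration, draw a daily TEQ (resampled
    empirically, or from a fitted lognormal) and each exposure factor,
    then evaluate the risk formula.  Deterministic under a fixed seed.
    """
    teq_arr = np.asarray(teq_samples, dtype=float)
    if teq_arr.size == 0:
        raise ValueError("teq_samples must be nonempty")
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    rng = np.random.default_rng(seed)
    if not teq_arr.any():
        log.warning("all TEQ samples are zero; risk is identically zero")
        t = np.zeros(n_iter)
    elif teq_mode == "empirical":
        t = rng.choice(teq_arr, size=n_iter, replace=True)
    elif teq_mode == "lognormal":
        pos = teq_arr[teq_arr > 0]
        mu, sigma = np.log(pos).mean(), np.log(pos).std()
        t = rng.lognormal(mu, sigma, n_iter)
    else:
        raise ValueError("teq_mode must be 'empirical' or 'lognormal'")

    inputs = pd.DataFrame({
        "TEQ": t,
        "IR": profile.ir.draw(rng, n_iter),
        "EF": profile.ef.draw(rng, n_iter),
        "ED": profile.ed.draw(rng, n_iter),
        "BW": profile.bw.draw(rng, n_iter),
    })
    draws = (inputs["TEQ"] * profile.csf * inputs["IR"] * inputs["EF"]
             * inputs["ED"] * profile.cf) / (inputs["BW"] * profile.at)
    draws = draws.to_numpy()
    percentiles = {k: float(np.percentile(draws, p)) for k, p in _PCT.items()}
    result = RiskResult(profile.receptor, draws, percentiles,
                        sensitivity=pd.DataFrame(), n_iter=n_iter, seed=seed,
                        inputs=inputs)
    result.sensitivity = sensitivity(result)
    return result


def sensitivity(result: RiskResult, inputs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-input Spearman rank correlation with ILCR and normalized
    variance contribution 100 * rho_k^2 / sum(rho^2); constant inputs
    are excluded (noted in the frame)."""
    inputs = result.inputs if inputs is None else inputs
    rows = []
    for name in inputs.columns:
        col = inputs[name].to_numpy()
        if np.ptp(col) == 0 or np.ptp(result.draws) == 0:
            rows.append({"input": name, "rho": np.nan,
                         "variance_contribution_pct": np.nan, "constant": True})
            continue
        rho, _ = stats.spearmanr(col, result.draws)
        rows.append({"input": name, "rho": float(rho),
                     "variance_contribution_pct": np.nan, "constant": False})
    df = pd.DataFrame(rows)
    varying = ~df["constant"]
    ssq = float((df.loc[varying, "rho"] ** 2).sum())
    if ssq > 0:
        df.loc[varying, "variance_contribution_pct"] = (
            100.0 * df.loc[varying, "rho"] ** 2 / ssq
        )
    return df


def species_risk_shares(
    records: Sequence[SampleRecord],
    catalog: SpeciesCatalog,
) -> pd.DataFrame:
    """Percent of the summed TEQ attributable to each species (sums to 100)."""
    if not records:
        raise ValueError("need at least one record")
    num = {c: 0.0 for c in SPECIES_ORDER}
    for r in records:
        for c in SPECIES_ORDER:
            num[c] += r.conc[c] * catalog[c].tef
    total = sum(num.values())
    if total <= 0:
        raise ValueError("total TEQ is zero; shares undefined")
    return pd.DataFrame({
        "species": list(SPECIES_ORDER),
        "teq_share_pct": [100.0 * num[c] / total for c in SPECIES_ORDER],
    })
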