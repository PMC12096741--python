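"""Molecular diagnostic ratios (MDR) for PAH source identification.

Four isomer-pair ratios of the form a/(a+b) discriminate petrogenic
from combustion origins:

=============  ======================  =======================================
ratio          pair                    class bands
=============  ======================  =======================================
AntPhe         Ant/(Ant+Phe)           <0.1 petrogenic; >=0.1 combustion
FluaPyr        Flua/(Flua+Pyr)         <0.4 petrogenic/unburned petroleum;
                                       [0.4,0.5] fossil fuel combustion;
                                       >0.5 biomass and coal combustion
BaAChr         BaA/(BaA+Chr)           <0.2 petrogenic; [0.2,0.35] petroleum
                                       combustion; >0.35 biomass and coal
                                       combustion
IcdPBghiP      IcdP/(IcdP+BghiP)       <0.2 petrogenic; [0.2,0.5] petroleum
                                       combustion; >0.5 biomass and coal
                                       combustion
=============  ======================  =======================================

Boundary convention: exact lower cut-offs fall in the higher class,
band endpoints belong to the closed middle band.  Ratios computed on
censor-substituted values are flagged low-confidence, since the
substitution constants can dominate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import SampleRecord

__all__ = ["RATIO_PAIRS", "RatioResult", "compute_ratios", "classify", "annual_fraction"]

RATIO_PAIRS: dict[str, tuple[str, str]] = {
    "AntPhe": ("Ant", "Phe"),
    "FluaPyr": ("Flua", "Pyr"),
    "BaAChr": ("BaA", "Chr"),
    "IcdPBghiP": ("IcdP", "BghiP"),
}

# per ratio: ordered (upper-exclusive bound, label); middle bands closed above
_BANDS: dict[str, tuple[tuple[float, bool, str], ...]] = {
    # (bound, bound_belongs_to_lower_class, label-below)
    "AntPhe": ((0.1, False, "petrogenic"),
               (np.inf, False, "combustion")),
    "FluaPyr": ((0.4, False, "petrogenic/unburned petroleum"),
                (0.5, True, "fossil fuel combustion"),
                (np.inf, False, "biomass and coal combustion")),
    "BaAChr": ((0.2, False, "petrogenic"),
               (0.35, True, "petroleum combustion"),
               (np.inf, False, "biomass and coal combustion")),
    "IcdPBghiP": ((0.2, False, "petrogenic"),
                  (0.5, True, "petroleum combustion"),
                  (np.inf, False, "biomass and coal combustion")),
}


@dataclass
class RatioResult:
    """Diagnostic ratios and source classes for one sample."""

    date: pd.Timestamp
    site: str
    ratios: dict[str, float | None]
    low_confidence: dict[str, bool] = field(default_factory=dict)
    classes: dict[str, str | None] = field(default_factory=dict)


def compute_ratios(record: SampleRecord) -> RatioResult:
    """a/(a+b) for each isomer pair; ``None`` when a+b = 0 or both
    components are censor-substituted."""
    ratios: dict[str, float | None] = {}
    lowconf: dict[str, bool] = {}
    for name, (num, den) in RATIO_PAIRS.items():
        a, b = record.conc[num], record.conc[den]
        both_cens = record.censored.get(num, False) and record.censored.get(den, False)
        if a + b == 0 or both_cens:
            ratios[name] = None
            lowconf[name] = True
        else:
            ratios[name] = a / (a + b)
            lowconf[name] = record.censored.get(num, False) or record.censored.get(den, False)
    return RatioResult(record.date, record.site, ratios, lowconf)


def classify_value(ratio_name: str, value: float | None) -> str | None:
    """Source label for one ratio value; total on [0,1] + undefined."""
    if value is None:
        return None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{ratio_name}: ratio {value} outside [0, 1]")
    for bound, closed, label in _BANDS[ratio_name]:
        if value < bound or (closed and value == bound):
            return label
    raise AssertionError("unreachable: bands cover [0, 1]")


def classify(result: RatioResult) -> RatioResult:
    """Fill the source class for each defined ratio (in place, returned)."""
    result.classes = {name: classify_value(name, v) for name, v in result.ratios.items()}
    return result


def _parse_predicate(predicate: str | Callable[[float], bool]) -> Callable[[float], bool]:
    if callable(predicate):
        return predicate
    op, _, rest = predicate.strip().partition(" ")
    thr = float(rest)
    return {
        ">": lambda v: v > thr, ">=": lambda v: v >= thr,
        "<": lambda v: v < thr, "<=": lambda v: v <= thr,
    }[op]


def annual_fraction(
    results: Sequence[RatioResult],
    ratio_name: str,
    predicate: str | Callable[[float], bool],
) -> pd.DataFrame:
    """Per-year percentage of samples (among defined ratios) satisfying
    *predicate*, e.g. ``"> 0.1"``.  Years with no defined ratio get
    ``n=0`` and a blank rate."""
    pred = _parse_predicate(predicate)
    years = sorted({r.date.year for r in results})
    rows = []
    for y in years:
        vals = [r.ratios[ratio_name] for r in results
                if r.date.year == y and r.ratios[ratio_name] is not None]
        n = len(vals)
        rate = round(100.0 * sum(pred(v) for v in vals) / n, 2) if n else np.nan
        rows.append({"year": y, "n": n, "rate": rate})
    return pd.DataFrame(rows)
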