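"""Positive matrix factorization (PMF) receptor model, from scratch.

PMF decomposes a sample x species concentration matrix X into
nonnegative factor contributions G (samples x factors) and factor
profiles F (factors x species),

    x_ij = sum_k g_ik f_kj + e_ij,

by minimizing the uncertainty-weighted objective

    Q = sum_ij (e_ij / s_ij)^2,

where s_ij is the per-cell measurement uncertainty.  The uncertainty
matrix follows the standard error-fraction construction: censored cells
get s = (5/6) * MDL, observed cells s = sqrt((EF * x)^2 + (0.5 * MDL)^2)
with error fraction EF.

Solver: multi-start weighted multiplicative updates (monotone in Q)
followed by an alternating nonnegativity-constrained weighted
least-squares polish of the best start.  Scale indeterminacy is fixed
by normalizing each profile row to sum to 1 and absorbing the scale
into G; factors are ordered by contribution percentage, descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_model import SampleRecord, records_to_frame
from .species import SPECIES_ORDER, SpeciesCatalog

__all__ = [
    "UncertaintyMatrix",
    "FactorModel",
    "build_uncertainty",
    "compute_q",
    "fit_pmf",
    "contribution_percentages",
    "label_factors",
    "DEFAULT_MARKERS",
]

_EPS = 1e-12

#: marker species per candidate source label (urban PAH mix)
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "biomass burning": ("Chr", "BaA", "BaP"),
    "gasoline traffic": ("Flu", "BkF", "BaP", "BghiP", "IcdP"),
    "steel industry": ("Ace", "DahA", "IcdP"),
    "coal combustion": ("Phe", "Flua", "Pyr", "Chr"),
    "diesel traffic": ("Ant", "BaA", "BghiP"),
}


@dataclass
class UncertaintyMatrix:
    """Per-cell uncertainties s_ij (> 0), same units as concentrations."""

    s: np.ndarray
    error_fraction: float
    mdls: dict[str, float]

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not (self.s > 0).all():
            raise ValueError("all uncertainties must be strictly positive")


def build_uncertainty(
    records: Sequence[SampleRecord],
    error_fraction: float = 0.10,
    catalog: SpeciesCatalog | None = None,
) -> UncertaintyMatrix:
    """EPA-style uncertainty matrix from records and detection limits."""
    if not 0 < error_fraction < 1:
        raise ValueError("error_fraction must lie in (0, 1)")
    from .species import default_catalog
    catalog = catalog or default_catalog()
    mdls = dict(catalog.mdls())
    for c, m in mdls.items():
        if not m > 0:
            raise ValueError(f"nonpositive MDL for {c}")
    n = len(records)
    s = np.empty((n, len(SPECIES_ORDER)))
    for i, r in enumerate(records):
        for j, c in enumerate(SPECIES_ORDER):
            mdl = mdls[c]
            if r.censored.get(c, False):
                s[i, j] = (5.0 / 6.0) * mdl
            else:
                s[i, j] = np.sqrt((error_fraction * r.conc[c]) ** 2 + (0.5 * mdl) ** 2)
    return UncertaintyMatrix(s, error_fraction, mdls)


@dataclass
class FactorModel:
    """A fitted PMF solution."""

    f: np.ndarray                     # factors x species, rows sum to 1
    g: np.ndarray                     # samples x factors
    q: float
    q_expected: float                 # nm - k(n+m), degrees-of-freedom reference
    contribution_pct: np.ndarray      # percent of reconstructed mass per factor
    n_starts: int
    seed: int | None
    converged: bool
    x: np.ndarray = field(repr=False, default=None)
    s: np.ndarray = field(repr=False, default=None)
    q_per_start: np.ndarray = field(repr=False, default=None)

    def reconstruction(self) -> np.ndarray:
        return self.g @ self.f

    def to_frames(self) -> dict[str, pd.DataFrame]:
        k = self.f.shape[0]
        profiles = pd.DataFrame(self.f, columns=list(SPECIES_ORDER))
        profiles.insert(0, "factor", np.arange(1, k + 1))
        contrib = pd.DataFrame(self.g, columns=[f"factor_{i}" for i in range(1, k + 1)])
        summary = pd.DataFrame({
            "factor": np.arange(1, k + 1),
            "contribution_pct": self.contribution_pct,
        })
        summary.loc[len(summary)] = ["Q", self.q]
        summary.loc[len(summary)] = ["Q_expected", self.q_expected]
        return {"profiles": profiles, "contributions": contrib, "summary": summary}


def compute_q(x: np.ndarray, s: np.ndarray, g: np.ndarray, f: np.ndarray) -> float:
    """The weighted objective recomputed from its definition."""
    return float((((x - g @ f) / s) ** 2).sum())


def _mu_step(x, w, wx, g, f):
    """One pair of weighted multiplicative updates (monotone in Q)."""
    gf = g @ f
    g = g * (wx @ f.T) / ((w * gf) @ f.T + _EPS)
    gf = g @ f
    f = f * (g.T @ wx) / (g.T @ (w * gf) + _EPS)
    return g, f


def _anls_step(x, s, g, f):
    """One sweep of alternating weighted NNLS (rows of G, then columns of F)."""
    n, m = x.shape
    for i in range(n):
        a = (f / s[i]).T            # m x k
        g[i], _ = nnls(a, x[i] / s[i])
    for j in range(m):
        a = g / s[:, [j]]           # n x k
        f[:, j], _ = nnls(a, x[:, j] / s[:, j])
    return g, f


def fit_pmf(
    x: np.ndarray,
    s: UncertaintyMatrix | np.ndarray,
    n_factors: int,
    n_starts: int = 20,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    polish_iter: int = 1500,
    polish_starts: int = 3,
    init: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> FactorModel:
    """Fit PMF by multi-start minimization of Q.

    Each start runs multiplicative updates until the relative Q change
    drops below *tol* (or *max_iter*); the *polish_starts* best starts
    are then polished with alternating weighted NNLS at a 1000x tighter
    relative tolerance (near-tied rotational basins differ by tiny Q
    margins, so the polish must run deep), and the lowest-Q polished
    solution wins.  *init* may supply explicit (G0, F0) pairs,
    overriding the random starts.
    """
    x = np.asarray(x, dtype=float)
    s_arr = s.s if isinstance(s, UncertaintyMatrix) else np.asarray(s, dtype=float)
    n, m = x.shape
    if s_arr.shape != x.shape:
        raise ValueError("uncertainty matrix shape must match x")
    if (x < 0).any():
        raise ValueError("concentrations must be nonnegative")
    if not n_factors < min(n, m):
        raise ValueError(f"n_factors={n_factors} must be < min(n_samples, n_species)")

    w = 1.0 / s_arr**2
    wx = w * x
    rng = np.random.default_rng(seed)
    scale = np.sqrt(4.0 * x.mean() / n_factors)

    if init is not None:
        starts = [(np.asarray(g0, float).copy(), np.asarray(f0, float).copy())
                  for g0, f0 in init]
    else:
        starts = [(rng.uniform(0, 1, (n, n_factors)) * scale,
                   rng.uniform(0, 1, (n_factors, m)) * scale)
                  for _ in range(n_starts)]

    candidates = []
    q_per_start = []
    for g, f in starts:
        q_prev = compute_q(x, s_arr, g, f)
        for _ in range(max_iter):
            g, f = _mu_step(x, w, wx, g, f)
            q_now = compute_q(x, s_arr, g, f)
            if q_prev - q_now < tol * max(q_prev, _EPS):
                q_prev = q_now
                break
            q_prev = q_now
        q_per_start.append(q_prev)
        candidates.append((q_prev, g, f))
    candidates = [c for c in candidates if np.isfinite(c[0])]
    if not candidates:
        raise RuntimeError("all PMF starts diverged; check uncertainties and data scale")
    candidates.sort(key=lambda c: c[0])

    tol_polish = tol * 1e-3
    best = None
    for q_now, g, f in candidates[: max(1, polish_starts)]:
        hit_tol = False
        for _ in range(polish_iter):
            q_prev = q_now
            g, f = _anls_step(x, s_arr, g, f)
            q_now = compute_q(x, s_arr, g, f)
            if q_prev - q_now < tol_polish * max(q_prev, _EPS) or q_now < 1e-12:
                hit_tol = True
                break
        if best is None or q_now < best[0]:
            best = (q_now, g, f, hit_tol)
    q_now, g, f, converged = best

    # fix scale: profile rows sum to 1, scale absorbed into contributions
    row_sum = f.sum(axis=1)
    keep = row_sum > 0
    f = f[keep]
    g = g[:, keep]
    row_sum = row_sum[keep]
    f = f / row_sum[:, None]
    g = g * row_sum[None, :]

    pct = _contribution_pct(g, f)
    order = np.argsort(-pct)
    model = FactorModel(
        f=f[order], g=g[:, order], q=compute_q(x, s_arr, g, f),
        q_expected=float(n * m - n_factors * (n + m)),
        contribution_pct=pct[order], n_starts=len(starts), seed=seed,
        converged=converged, x=x, s=s_arr,
        q_per_start=np.asarray(q_per_start),
    )
    return model


def _contribution_pct(g: np.ndarray, f: np.ndarray) -> np.ndarray:
    mass = g.sum(axis=0) * f.sum(axis=1)   # sum_ij g_ik f_kj per factor
    total = mass.sum()
    if total <= 0:
        raise ValueError("all-zero reconstruction; contribution shares undefined")
    return 100.0 * mass / total


def contribution_percentages(model: FactorModel) -> dict[int, float]:
    """Percent of total reconstructed mass per factor (1-based keys);
    sums to 100."""
    pct = _contribution_pct(model.g, model.f)
    return {k + 1: float(p) for k, p in enumerate(pct)}


def label_factors(
    model: FactorModel,
    markers: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Assign each factor the source label whose marker species carry the
    highest mean normalized loading.

    Loadings are normalized per species (each species' profile column
    sums to 1 across factors) so abundant species do not dominate.  Ties
    are reported as ambiguous with all tied candidates.  The assignment
    is a heuristic annotation, not ground truth.
    """
    markers = dict(markers) if markers is not None else dict(DEFAULT_MARKERS)
    col_sum = model.f.sum(axis=0)
    norm = model.f / np.where(col_sum > 0, col_sum, 1.0)
    idx = {c: j for j, c in enumerate(SPECIES_ORDER)}
    rows = []
    for k in range(model.f.shape[0]):
        scores = {}
        for label, specs in markers.items():
            cols = [idx[c] for c in specs]
            scores[label] = float(norm[k, cols].mean())
        smax = max(scores.values())
        tied = sorted(lbl for lbl, v in scores.items() if abs(v - smax) <= 1e-12)
        rows.append({
            "factor": k + 1,
            "label": tied[0] if len(tied) == 1 else "; ".join(tied),
            "score": smax,
            "ambiguous": len(tied) > 1,
        })
    return pd.DataFrame(rows)


def factor_scan(
    x: np.ndarray,
    s: UncertaintyMatrix | np.ndarray,
    k_range: Sequence[int] = range(3, 8),
    seed: int | None = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Q versus number of factors, for choosing/justifying the dimension.

    Returns a frame with columns ``n_factors``, ``q``, ``q_expected``,
    ``q_over_expected``; a ratio near 1 indicates the uncertainty model
    explains the residuals at that dimension.
    """
    rows = []
    for k in k_range:
        m = fit_pmf(x, s, k, seed=seed, **fit_kwargs)
        rows.append({"n_factors": k, "q": m.q, "q_expected": m.q_expected,
                     "q_over_expected": m.q / m.q_expected})
    return pd.DataFrame(rows)


def records_to_matrix(records: Sequence[SampleRecord]) -> np.ndarray:
    """Sample x species concentration matrix in catalogue order."""
    df = records_to_frame(records)
    return df[list(SPECIES_ORDER)].to_numpy(dtype=float)
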